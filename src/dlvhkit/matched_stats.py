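"""Conditional logistic regression (CLR) for 1:m matched case-control sets
and the bin-wise scan producing a p-value map over the (dose, LETd) plane.

The outcome model is logit P(fracture) = alpha_i + beta * V(d, l), with a
per-set intercept alpha_i absorbing the matched clinical factors.
Conditioning on one case per set eliminates alpha_i, leaving the
conditional log-likelihood

    l(beta) = sum_i [ beta x_case,i - log sum_{j in set i} exp(beta x_j) ]

which is concave in beta and is maximised here by Newton-Raphson.  A
separate model is fitted at every (d, l) grid node with x = V(d, l),
yielding a map of Wald p-values for beta.

Sets whose members all share one covariate value carry no information and
are dropped (the conditional probability is constant in beta).  If the case
has the extreme value in every informative set the likelihood is monotone
and beta diverges; such fits are flagged, not reported as numbers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .dlvh import DLVHSurface
from .grids import FormatError, ValidationError

__all__ = [
    "STATUS_OK",
    "STATUS_NON_INFORMATIVE",
    "STATUS_MONOTONE",
    "STATUS_NO_CONVERGENCE",
    "MatchedSet",
    "CLRFit",
    "PValueMap",
    "conditional_loglik",
    "fit_clr",
    "matched_sets_at",
    "scan_pvalue_map",
    "export_pvalue_map",
    "import_pvalue_map",
]

STATUS_OK = "ok"
STATUS_NON_INFORMATIVE = "non_informative"
STATUS_MONOTONE = "monotone_likelihood"
STATUS_NO_CONVERGENCE = "no_convergence"

# Newton-Raphson controls (covariates are standardized internally, so the
# score and beta are O(1) regardless of the covariate scale).
_SCORE_TOL = 1e-8
_MAX_ITER = 50
_BETA_DIVERGENCE = 15.0


@dataclass(frozen=True)
class MatchedSet:
    """One case value plus its matched controls' values of V(d, l)."""

    set_id: str
    case_value: float
    control_values: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "control_values",
                           tuple(float(v) for v in self.control_values))
        object.__setattr__(self, "case_value", float(self.case_value))
        if len(self.control_values) < 1:
            raise ValidationError(f"set {self.set_id!r} has no controls")
        values = (self.case_value, *self.control_values)
        if not all(np.isfinite(values)):
            raise ValidationError(f"set {self.set_id!r} has non-finite values")

    @property
    def all_values(self) -> np.ndarray:
        return np.array((self.case_value, *self.control_values))

    @property
    def informative(self) -> bool:
        return len(set(self.all_values.tolist())) > 1


@dataclass(frozen=True)
class CLRFit:
    """Result of a single conditional-logistic fit.

    ``beta_hat``/``se``/``p_value`` are on the covariate's original scale
    and are present iff ``status == "ok"``.
    """

    beta_hat: float | None
    se: float | None
    p_value: float | None
    status: str
    n_informative_sets: int
    n_dropped_sets: int = 0


def conditional_loglik(beta: float, sets: Sequence[MatchedSet]) -> float:
    """Conditional log-likelihood at ``beta`` (overflow-safe log-sum-exp).

    Invariant to adding a constant to every value within a set.  At
    beta = 0 it equals -sum_i log(1 + m_i) for sets of 1 case and m_i
    controls.
    """
    if len(sets) == 0:
        raise ValidationError("need at least one matched set")
    total = 0.0
    for s in sets:
        x = s.all_values
        total += beta * s.case_value - logsumexp(beta * x)
    return float(total)


def _score_info(beta: float, sets: Sequence[MatchedSet]) -> tuple[float, float]:
    """Score and observed information of the conditional log-likelihood."""
    score = 0.0
    info = 0.0
    for s in sets:
        x = s.all_values
        z = beta * x
        z -= z.max()
        w = np.exp(z)
        w /= w.sum()
        mean = float(w @ x)
        score += s.case_value - mean
        info += float(w @ (x - mean) ** 2)
    return score, info


def _monotone_direction(sets: Sequence[MatchedSet], strict: bool) -> int:
    """+1/-1 if the case is the (strict) max/min in every set, else 0."""
    op_hi = np.greater if strict else np.greater_equal
    op_lo = np.less if strict else np.less_equal
    if all(op_hi(s.case_value, max(s.control_values)) for s in sets):
        return 1
    if all(op_lo(s.case_value, min(s.control_values)) for s in sets):
        return -1
    return 0


def fit_clr(sets: Sequence[MatchedSet], p_method: str = "wald") -> CLRFit:
    """Maximise the conditional likelihood by Newton-Raphson from beta = 0.

    Covariates are standardized internally (divided by the pooled standard
    deviation across informative sets) for numerical stability; the
    reported ``beta_hat`` and ``se`` are transformed back to the original
    scale.  ``p_method`` selects the two-sided Wald test (default, matching
    the conventional clogit summary) or the likelihood-ratio test.
    """
    if p_method not in ("wald", "lr"):
        raise ValidationError(f"unknown p_method {p_method!r}")
    sets = list(sets)
    if len(sets) == 0:
        raise ValidationError("need at least one matched set")
    informative = [s for s in sets if s.informative]
    n_dropped = len(sets) - len(informative)
    if not informative:
        return CLRFit(None, None, None, STATUS_NON_INFORMATIVE, 0, n_dropped)

    # the MLE diverges iff the case is >= (or <=) every control in each
    # informative set: the score sum_i (x_case,i - E_beta[x]) then keeps one
    # sign for every finite beta, so the likelihood is monotone
    if _monotone_direction(informative, strict=False) != 0:
        return CLRFit(None, None, None, STATUS_MONOTONE,
                      len(informative), n_dropped)

    pooled = np.concatenate([s.all_values for s in informative])
    scale = float(pooled.std())
    std_sets = [
        MatchedSet(s.set_id, s.case_value / scale,
                   tuple(v / scale for v in s.control_values))
        for s in informative
    ]

    beta = 0.0
    converged = False
    for _ in range(_MAX_ITER):
        score, info = _score_info(beta, std_sets)
        if abs(score) < _SCORE_TOL:
            converged = True
            break
        step = score / info
        # concave likelihood: cap the step to stay in a sane region
        beta += float(np.clip(step, -5.0, 5.0))
        if abs(beta) > _BETA_DIVERGENCE:
            if _monotone_direction(informative, strict=False) != 0:
                return CLRFit(None, None, None, STATUS_MONOTONE,
                              len(informative), n_dropped)
    else:
        score, info = _score_info(beta, std_sets)
        converged = abs(score) < _SCORE_TOL
    if not converged:
        return CLRFit(None, None, None, STATUS_NO_CONVERGENCE,
                      len(informative), n_dropped)

    _, info = _score_info(beta, std_sets)
    se_std = 1.0 / np.sqrt(info)
    if p_method == "wald":
        z = beta / se_std
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        lr = 2.0 * (conditional_loglik(beta, std_sets)
                    - conditional_loglik(0.0, std_sets))
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return CLRFit(
        beta_hat=beta / scale, se=float(se_std / scale), p_value=p,
        status=STATUS_OK, n_informative_sets=len(informative),
        n_dropped_sets=n_dropped,
    )


# ---------------------------------------------------------------------------
# Bin-wise scan over the (dose, LETd) grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PValueMap:
    """Per-(d, l)-node CLR p-value, coefficient sign, and status.

    ``p`` and ``beta_sign`` are NaN/0 and masked exactly where
    ``status != "ok"`` (no imputation: masked nodes carry no evidence).
    """

    dose_grid: np.ndarray
    let_grid: np.ndarray
    p: np.ndarray          # float, NaN where masked
    beta_sign: np.ndarray  # int in {-1, 0, +1}, 0 where masked
    status: np.ndarray     # str codes
    p_method: str = "wald"
    adjust: str = "none"

    @property
    def ok(self) -> np.ndarray:
        return self.status == STATUS_OK

    def __post_init__(self):
        shape = (len(self.dose_grid), len(self.let_grid))
        for name in ("p", "beta_sign", "status"):
            if getattr(self, name).shape != shape:
                raise ValidationError(f"{name} shape does not match grids")


def matched_sets_at(values: Mapping[str, float],
                    cohort: pd.DataFrame) -> list[MatchedSet]:
    """Assemble MatchedSets from per-patient covariate values.

    ``values`` maps patient_id -> V(d, l); ``cohort`` supplies outcome and
    set membership (one case per set).
    """
    sets = []
    for set_id, grp in cohort.groupby("set_id", sort=True):
        case = grp.loc[grp["outcome"] == 1, "patient_id"].iloc[0]
        controls = grp.loc[grp["outcome"] == 0, "patient_id"]
        sets.append(MatchedSet(
            set_id=str(set_id),
            case_value=values[case],
            control_values=tuple(values[pid] for pid in controls),
        ))
    return sets


def scan_pvalue_map(surfaces: Mapping[str, DLVHSurface], cohort: pd.DataFrame,
                    p_method: str = "wald", adjust: str = "none") -> PValueMap:
    """Fit a separate CLR model at every (d, l) grid node.

    ``surfaces`` maps patient_id to that patient's DLVH surface; all
    surfaces must share one grid.  ``adjust`` optionally applies a
    Benjamini-Hochberg ("bh") or Benjamini-Yekutieli ("by") correction
    across the ok nodes (off by default: the raw map is the primary
    output).
    """
    if adjust not in ("none", "bh", "by"):
        raise ValidationError(f"unknown adjust {adjust!r}")
    ids = set(cohort["patient_id"])
    if missing := ids - set(surfaces):
        raise ValidationError(f"no DLVH surface for patient(s) {sorted(missing)}")
    ref = surfaces[next(iter(ids))]
    for pid in ids:
        if not ref.same_grid(surfaces[pid]):
            raise ValidationError(
                f"patient {pid!r} DLVH grid differs from the common grid"
            )
    nd, nl = len(ref.dose_grid), len(ref.let_grid)
    p = np.full((nd, nl), np.nan)
    sign = np.zeros((nd, nl), dtype=int)
    status = np.full((nd, nl), STATUS_NON_INFORMATIVE, dtype=object)
    for a in range(nd):
        for b in range(nl):
            values = {pid: float(surfaces[pid].volume[a, b]) for pid in ids}
            fit = fit_clr(matched_sets_at(values, cohort), p_method=p_method)
            status[a, b] = fit.status
            if fit.status == STATUS_OK:
                p[a, b] = fit.p_value
                sign[a, b] = int(np.sign(fit.beta_hat))
    if adjust != "none":
        ok = status == STATUS_OK
        method = {"bh": "bh", "by": "by"}[adjust]
        p[ok] = stats.false_discovery_control(p[ok], method=method)
    return PValueMap(ref.dose_grid, ref.let_grid, p, sign,
                     status.astype(str), p_method=p_method, adjust=adjust)


_PMAP_MAGIC = "# dlvhkit-pmap v1"


def export_pvalue_map(pmap: PValueMap, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_PMAP_MAGIC}\n")
        fh.write(f"# p_method={pmap.p_method}\n")
        fh.write(f"# adjust={pmap.adjust}\n")
        fh.write("d,l,p,beta_sign,status\n")
        for a, d in enumerate(pmap.dose_grid):
            for b, l in enumerate(pmap.let_grid):
                pv = pmap.p[a, b]
                fh.write(
                    f"{float(d)!r},{float(l)!r},"
                    f"{'' if np.isnan(pv) else repr(float(pv))},"
                    f"{pmap.beta_sign[a, b]},{pmap.status[a, b]}\n"
                )


def import_pvalue_map(path) -> PValueMap:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _PMAP_MAGIC:
        raise FormatError(f"{path}: not a dlvhkit p-value map CSV")
    meta = {}
    body = 0
    for n, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
        else:
            body = n
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body:])))
    dose_grid = np.unique(df["d"].to_numpy())
    let_grid = np.unique(df["l"].to_numpy())
    if len(df) != len(dose_grid) * len(let_grid):
        raise FormatError(f"{path}: incomplete (d, l) grid")
    df = df.sort_values(["d", "l"])
    shape = (len(dose_grid), len(let_grid))
    return PValueMap(
        dose_grid=dose_grid, let_grid=let_grid,
        p=df["p"].to_numpy(dtype=float).reshape(shape),
        beta_sign=df["beta_sign"].to_numpy(dtype=int).reshape(shape),
        status=df["status"].to_numpy(dtype=str).reshape(shape),
        p_method=meta.get("p_method", "wald"),
        adjust=meta.get("adjust", "none"),
    )
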
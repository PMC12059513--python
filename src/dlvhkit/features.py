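"""Feature extraction from the CLR p-value map.

Outcome-associated DLVH features are the 4-connected components of
sub-threshold grid nodes, split by the sign of the regression coefficient:
risk-increasing regions (beta > 0, larger V(d, l) in cases) and
risk-decreasing regions (beta < 0).  Regions at a stricter threshold nest
inside regions at a looser one.  By convention the map is summarised at
p < 0.1 and p < 0.2, with p < 0.05 as the formal significance line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours

from .dlvh import ContourLine, DLVHSurface, iso_volume_lines
from .grids import ValidationError
from .matched_stats import PValueMap

__all__ = [
    "DEFAULT_ISO_P_LEVELS",
    "RISK_INCREASING",
    "RISK_DECREASING",
    "FeatureRegion",
    "iso_p_contours",
    "extract_feature_regions",
    "regions_to_json",
    "render_report",
]

DEFAULT_ISO_P_LEVELS = (0.1, 0.2, 0.5)
RISK_INCREASING = "risk_increasing"
RISK_DECREASING = "risk_decreasing"

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class FeatureRegion:
    """A 4-connected sub-threshold region of the p-value map."""

    bins: tuple[tuple[float, float], ...]  # (dose, letd) grid nodes
    bin_indices: tuple[tuple[int, int], ...]
    direction: str  # risk_increasing (+beta) or risk_decreasing (-beta)
    p_threshold: float
    min_p: float
    bounding_box: tuple[float, float, float, float]  # d_min, d_max, l_min, l_max
    representative_index: tuple[float, float]  # the (d, l) with minimal p

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def iso_p_contours(pmap: PValueMap,
                   levels=DEFAULT_ISO_P_LEVELS) -> list[ContourLine]:
    """Iso-p-value polylines over the ok nodes of the map.

    Masked nodes (non-ok status) are excluded from the marching-squares
    interpolation, so contours never cross into them.
    """
    ok = pmap.ok
    if not ok.any():
        raise ValidationError("p-value map has no ok node to contour")
    lines: list[ContourLine] = []
    for level in levels:
        for contour in find_contours(pmap.p, level, mask=ok):
            vertices = np.column_stack([
                np.interp(contour[:, 0], np.arange(len(pmap.dose_grid)),
                          pmap.dose_grid),
                np.interp(contour[:, 1], np.arange(len(pmap.let_grid)),
                          pmap.let_grid),
            ])
            lines.append(ContourLine(level=float(level), vertices=vertices))
    return lines


def extract_feature_regions(pmap: PValueMap,
                            p_threshold: float = 0.1) -> list[FeatureRegion]:
    """4-connected components of {ok nodes : p < threshold}, split by sign.

    Returned sorted by minimal p (ties broken by direction then location),
    each with its bounding box and minimum-p representative index.  An
    empty list means no sub-threshold structure.
    """
    regions: list[FeatureRegion] = []
    below = pmap.ok & (pmap.p < p_threshold)
    for sign, direction in ((1, RISK_INCREASING), (-1, RISK_DECREASING)):
        labels, n = ndimage.label(below & (pmap.beta_sign == sign),
                                  structure=_FOUR_CONNECTED)
        for lab in range(1, n + 1):
            ai, bi = np.nonzero(labels == lab)
            ds = pmap.dose_grid[ai]
            ls = pmap.let_grid[bi]
            ps = pmap.p[ai, bi]
            best = int(np.argmin(ps))  # first minimum in C order: deterministic
            regions.append(FeatureRegion(
                bins=tuple(zip(ds.tolist(), ls.tolist())),
                bin_indices=tuple(zip(ai.tolist(), bi.tolist())),
                direction=direction,
                p_threshold=float(p_threshold),
                min_p=float(ps[best]),
                bounding_box=(float(ds.min()), float(ds.max()),
                              float(ls.min()), float(ls.max())),
                representative_index=(float(ds[best]), float(ls[best])),
            ))
    regions.sort(key=lambda r: (r.min_p, r.direction, r.bounding_box))
    return regions


def regions_to_json(regions: list[FeatureRegion], path=None) -> str:
    """Serialise feature regions to JSON (optionally writing to ``path``)."""
    payload = [
        {
            "direction": r.direction,
            "p_threshold": r.p_threshold,
            "min_p": r.min_p,
            "representative_index": {"dose": r.representative_index[0],
                                     "letd": r.representative_index[1]},
            "bounding_box": {"dose_min": r.bounding_box[0],
                             "dose_max": r.bounding_box[1],
                             "letd_min": r.bounding_box[2],
                             "letd_max": r.bounding_box[3]},
            "n_bins": r.n_bins,
            "bins": [{"dose": d, "letd": l} for d, l in r.bins],
        }
        for r in regions
    ]
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def render_report(surfaces: dict[str, DLVHSurface], pmap: PValueMap,
                  regions: list[FeatureRegion], path) -> Path:
    """Write a self-contained Markdown report with figures.

    Contains the p-value map with iso-p lines, per-patient iso-volume
    plots, and a table of the extracted feature regions.  Deterministic
    given fixed inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    outdir = path.parent
    outdir.mkdir(parents=True, exist_ok=True)

    # p-value map figure
    fig, ax = plt.subplots(figsize=(6, 4.5))
    masked = np.ma.masked_invalid(pmap.p)
    mesh = ax.pcolormesh(pmap.dose_grid, pmap.let_grid, masked.T,
                         shading="nearest", cmap="viridis", vmin=0, vmax=1)
    fig.colorbar(mesh, ax=ax, label="p-value")
    try:
        for line in iso_p_contours(pmap):
            ax.plot(line.vertices[:, 0], line.vertices[:, 1], "w-", lw=0.8)
    except ValidationError:
        pass
    ax.set_xlabel("Dose (Gy[RBE])")
    ax.set_ylabel("LETd (keV/µm)")
    ax.set_title(f"CLR p-value map ({pmap.p_method})")
    pmap_png = outdir / "pvalue_map.png"
    fig.savefig(pmap_png, dpi=120, metadata={"Software": None})
    plt.close(fig)

    # per-patient iso-volume plots
    dlvh_pngs = []
    for pid in sorted(surfaces):
        fig, ax = plt.subplots(figsize=(5, 4))
        for line in iso_volume_lines(surfaces[pid]):
            ax.plot(line.vertices[:, 0], line.vertices[:, 1],
                    label=f"DL{line.level:g}%")
        ax.set_xlabel("Dose (Gy[RBE])")
        ax.set_ylabel("LETd (keV/µm)")
        ax.set_title(f"DLVH iso-volume lines — {pid}")
        handles, labels = ax.get_legend_handles_labels()
        seen = dict(zip(labels, handles))
        ax.legend(seen.values(), seen.keys(), fontsize=7)
        png = outdir / f"dlvh_{pid}.png"
        fig.savefig(png, dpi=120, metadata={"Software": None})
        plt.close(fig)
        dlvh_pngs.append(png)

    lines = ["# DLVH outcome-analysis report", ""]
    lines += ["## p-value map", "", f"![p-value map]({pmap_png.name})", ""]
    lines += ["## Feature regions", ""]
    if regions:
        lines += [
            "| # | direction | p threshold | min p | representative (d, l) | "
            "bounding box (d, l) | bins |",
            "|---|-----------|-------------|-------|-----------------------|"
            "---------------------|------|",
        ]
        for k, r in enumerate(regions, 1):
            d0, d1, l0, l1 = r.bounding_box
            lines.append(
                f"| {k} | {r.direction} | {r.p_threshold:g} | {r.min_p:.4g} "
                f"| ({r.representative_index[0]:g}, {r.representative_index[1]:g}) "
                f"| [{d0:g}, {d1:g}] × [{l0:g}, {l1:g}] | {r.n_bins} |"
            )
    else:
        lines.append("No feature region found below the threshold.")
    lines += ["", "## Per-patient DLVH iso-volume lines", ""]
    for png in dlvh_pngs:
        lines.append(f"![{png.stem}]({png.name})")
    path.write_text("\n".join(lines) + "\n")
    return path
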
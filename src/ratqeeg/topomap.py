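"""Topographic maps: thin-plate-spline interpolation over the skull plane
with pointwise statistical overlays.

Per-electrode statistics are interpolated exactly (smoothing 0) onto a
regular grid over the flattened (anterior, lateral) skull coordinates by
a thin-plate spline with a linear polynomial tail — exact at the
electrodes and reproducing affine fields exactly.  Points outside the
electrode convex hull plus a margin are masked.

The pointwise significance map interpolates every subject's electrode
values to the grid and runs the mixed RM-ANOVA at each grid point,
binning p into the conventional three display levels (p<0.05, p<0.01,
p<0.001).  No multiplicity correction is applied across grid points by
default: corrections apply across planned comparisons, not map pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay

from .montage import ElectrodeLayout
from . import stats as _stats

__all__ = ["GridSpec", "TopoMap", "spline_interpolate", "pointwise_significance",
            "plot_topomap"]

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice over the electrode bounding box plus a margin (mm)."""

    resolution: float = 0.25
    margin: float = 1.0


@dataclass
class TopoMap:
    anterior: np.ndarray  # (ny,) grid coordinates, mm
    lateral: np.ndarray   # (nx,)
    values: np.ndarray    # (ny, nx), NaN outside the hull + margin
    significance: np.ndarray | None = None  # (ny, nx) int: 0 none, 1/2/3 levels
    band: str = ""
    epoch: str = ""
    contrast: str = ""


def _grid(layout: ElectrodeLayout, spec: GridSpec):
    pts = np.array(layout.positions())
    a0, a1 = pts[:, 0].min() - spec.margin, pts[:, 0].max() + spec.margin
    l0, l1 = pts[:, 1].min() - spec.margin, pts[:, 1].max() + spec.margin
    ant = np.arange(a0, a1 + spec.resolution / 2, spec.resolution)
    lat = np.arange(l0, l1 + spec.resolution / 2, spec.resolution)
    return ant, lat, pts


def _hull_mask(pts, ant, lat, margin):
    """True for grid nodes within ``margin`` of the electrode convex hull."""
    tri = Delaunay(pts)
    A, L = np.meshgrid(ant, lat, indexing="ij")
    q = np.column_stack([A.ravel(), L.ravel()])
    inside = tri.find_simplex(q) >= 0
    if margin > 0:
        # distance to the closest electrode as a cheap, exact-enough buffer
        d = np.min(np.linalg.norm(q[:, None, :] - pts[None, :, :], axis=-1), axis=1)
        inside |= d <= margin
    return inside.reshape(A.shape)


def spline_interpolate(electrode_values, layout: ElectrodeLayout,
                       grid_spec: GridSpec | None = None, band: str = "",
                       epoch: str = "", contrast: str = "") -> TopoMap:
    """Exact thin-plate-spline map of 12 per-electrode scalars."""
    if grid_spec is None:
        grid_spec = GridSpec()
    vals = np.asarray(electrode_values, dtype=float)
    if vals.shape != (layout.n_channels,):
        raise ValueError(f"expected {layout.n_channels} electrode values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("electrode values must be finite")
    ant, lat, pts = _grid(layout, grid_spec)
    interp = RBFInterpolator(pts, vals, kernel="thin_plate_spline", smoothing=0.0,
                             degree=1)
    A, L = np.meshgrid(ant, lat, indexing="ij")
    grid_vals = interp(np.column_stack([A.ravel(), L.ravel()])).reshape(A.shape)
    mask = _hull_mask(pts, ant, lat, grid_spec.margin)
    grid_vals = np.where(mask, grid_vals, np.nan)
    return TopoMap(ant, lat, grid_vals, band=band, epoch=epoch, contrast=contrast)


def _bin_significance(p: np.ndarray) -> np.ndarray:
    level = np.zeros(p.shape, dtype=int)
    for i, a in enumerate(SIGNIFICANCE_LEVELS, start=1):
        level[p < a] = i
    return level


def pointwise_significance(values, groups, layout: ElectrodeLayout,
                           grid_spec: GridSpec | None = None,
                           effect: str = "treatment:time",
                           band: str = "", contrast: str = "") -> TopoMap:
    """Grid-wise mixed RM-ANOVA on interpolated per-subject maps.

    Parameters
    ----------
    values : ndarray, (n_subjects, n_times, n_channels)
        Per-subject, per-time electrode statistics (already normalised).
    groups : sequence of length n_subjects
        Between-factor level per subject.
    effect : str
        Which ANOVA effect drives the significance overlay
        (``treatment``, ``time`` or ``treatment:time``).

    Returns a map whose ``values`` are the group-contrast mean difference
    field (first group minus last group, averaged over time) and whose
    ``significance`` bins the pointwise GG-corrected p at the three
    conventional display levels.
    """
    if grid_spec is None:
        grid_spec = GridSpec()
    values = np.asarray(values, dtype=float)
    n_subj, n_times, n_ch = values.shape
    if n_ch != layout.n_channels:
        raise ValueError("channel axis does not match the layout")
    uniq = list(dict.fromkeys(groups))
    codes = np.array([uniq.index(g) for g in groups])
    if len(uniq) < 2 or np.any(np.bincount(codes) < 2):
        raise ValueError("pointwise testing needs >= 2 groups of >= 2 subjects")

    ant, lat, pts = _grid(layout, grid_spec)
    A, L = np.meshgrid(ant, lat, indexing="ij")
    q = np.column_stack([A.ravel(), L.ravel()])
    # interpolate all subject x time maps in one linear solve per map
    maps = np.empty((n_subj, n_times, len(q)))
    for i in range(n_subj):
        for j in range(n_times):
            interp = RBFInterpolator(pts, values[i, j], kernel="thin_plate_spline",
                                     smoothing=0.0, degree=1)
            maps[i, j] = interp(q)

    Y = np.moveaxis(maps, -1, 0)  # (n_points, n_subj, n_times)
    res = _stats.mixed_anova_arrays(Y, codes)
    e = res[effect]
    p = np.asarray(e.get("p_gg", e["p"]))
    mask = _hull_mask(pts, ant, lat, grid_spec.margin).ravel()
    p = np.where(mask, p, np.nan)

    mean_a = maps[codes == 0].mean(axis=(0, 1))
    mean_b = maps[codes == len(uniq) - 1].mean(axis=(0, 1))
    diff = np.where(mask, mean_a - mean_b, np.nan)

    sig = np.where(np.isnan(p), 0, _bin_significance(np.nan_to_num(p, nan=1.0)))
    return TopoMap(
        ant, lat, diff.reshape(A.shape),
        significance=sig.reshape(A.shape).astype(int),
        band=band, contrast=contrast or f"{uniq[0]} vs {uniq[-1]} ({effect})",
    )


def plot_topomap(topo: TopoMap, path=None, cmap: str = "RdBu_r"):
    """Render a map with its three-level significance overlay to PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    extent = [topo.lateral[0], topo.lateral[-1], topo.anterior[0], topo.anterior[-1]]
    vmax = np.nanmax(np.abs(topo.values)) or 1.0
    im = ax.imshow(topo.values, origin="lower", extent=extent, cmap=cmap,
                   vmin=-vmax, vmax=vmax, aspect="equal")
    if topo.significance is not None and (topo.significance > 0).any():
        for level, alpha in ((1, 0.15), (2, 0.30), (3, 0.45)):
            m = np.where(topo.significance >= level, 1.0, np.nan)
            ax.imshow(m, origin="lower", extent=extent, cmap="Greys",
                      vmin=0, vmax=1, alpha=alpha, aspect="equal")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("anterior (mm)")
    title = " ".join(s for s in (topo.contrast, topo.band, topo.epoch) if s)
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
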
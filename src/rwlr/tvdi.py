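"""NDVI/LST triangle space: edge fitting and the dryness index.

The scatter of land-surface temperature against NDVI is bounded above by a
"dry edge" ``T_d = a + b * NDVI`` (maximal water stress) and below by a
"wet edge" ``T_w = c + d * NDVI``.  The dryness index for an observed
temperature is the position between the two envelopes::

    TVDI = (T_obs - T_w) / (T_d - T_w)

which is 0 on the wet edge, 1 on the dry edge, and is clipped into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rwlr.errors import DegenerateTriangleError, FitError, InterfaceError, ParameterError
from rwlr.grids import GridSpec

__all__ = [
    "TriangleEdges",
    "TvdiScene",
    "fit_triangle_edges",
    "compute_tvdi",
    "resample_nearest",
]


@dataclass(frozen=True)
class TriangleEdges:
    """Linear dry/wet envelopes of the NDVI/LST scatter.

    ``a``/``b`` are intercept (K) and slope (K per NDVI unit) of the dry
    edge, ``c``/``d`` of the wet edge.  The fit is only valid over
    ``ndvi_range``; the dry edge must lie strictly above the wet edge there.
    """

    a: float
    b: float
    c: float
    d: float
    ndvi_range: tuple[float, float] = (0.0, 1.0)
    fit_r2_dry: float = float("nan")
    fit_r2_wet: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.ndvi_range
        if not lo < hi:
            raise ParameterError(f"invalid ndvi_range {self.ndvi_range}")
        # Both edges are linear, so checking the endpoints suffices.
        for x in (lo, hi):
            if self.t_dry(x) <= self.t_wet(x):
                raise DegenerateTriangleError(
                    f"dry edge not above wet edge at NDVI={x:.3f} "
                    f"(T_d={self.t_dry(x):.3f}, T_w={self.t_wet(x):.3f})"
                )

    def t_dry(self, ndvi):
        return self.a + self.b * np.asarray(ndvi, dtype=float)

    def t_wet(self, ndvi):
        return self.c + self.d * np.asarray(ndvi, dtype=float)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "ndvi_range": list(self.ndvi_range),
            "fit_r2_dry": self.fit_r2_dry, "fit_r2_wet": self.fit_r2_wet,
        }


@dataclass
class TvdiScene:
    """Per-pixel dryness index for one composite timestamp.

    ``qc_mask`` is True where the value is trustworthy; invalid pixels carry
    NaN.  ``clip_fraction`` is the share of valid pixels whose raw ratio fell
    outside [0, 1] before clipping.
    """

    tvdi: np.ndarray
    time: float | None = None
    qc_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    clip_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.qc_mask is None:
            self.qc_mask = np.isfinite(self.tvdi)


def _edge_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line through (x, y); returns (intercept, slope, r2)."""
    if x.size < 2:
        raise FitError(f"only {x.size} usable bins; need at least 2")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(intercept), float(slope), r2


def fit_triangle_edges(
    ndvi: np.ndarray,
    lst: np.ndarray,
    n_bins: int = 20,
    edge_percentile: float = 1.0,
    min_pixels_per_bin: int = 5,
    ndvi_min: float = 0.05,
    ndvi_range: tuple[float, float] | None = None,
) -> TriangleEdges:
    """Fit dry and wet edges from the NDVI/LST scatter of one scene.

    NDVI is split into ``n_bins`` equal-width bins over ``ndvi_range``
    (observed range of valid pixels when None).  Per bin, the
    ``edge_percentile`` quantile of LST (default 1.0 = max) gives a dry-edge
    point at the bin centre and the ``1 - edge_percentile`` quantile the
    wet-edge point; each envelope is an OLS line through its points.  Bins
    with fewer than ``min_pixels_per_bin`` valid pixels are skipped, as are
    pixels with NDVI below ``ndvi_min`` (bare/water guard).
    """
    if n_bins < 5:
        raise ParameterError("n_bins must be >= 5")
    if not 0.5 < edge_percentile <= 1.0:
        raise ParameterError("edge_percentile must lie in (0.5, 1]")
    ndvi = np.asarray(ndvi, dtype=float).ravel()
    lst = np.asarray(lst, dtype=float).ravel()
    if ndvi.shape != lst.shape:
        raise InterfaceError("ndvi and lst must be co-registered (same shape)")
    ok = np.isfinite(ndvi) & np.isfinite(lst) & (ndvi >= ndvi_min)
    ndvi, lst = ndvi[ok], lst[ok]
    if ndvi.size == 0:
        raise FitError("no valid pixels for edge fitting")
    if ndvi_range is None:
        lo, hi = float(ndvi.min()), float(ndvi.max())
    else:
        lo, hi = map(float, ndvi_range)
    if not lo < hi:
        raise FitError("degenerate NDVI range")
    edges_x = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges_x[:-1] + edges_x[1:])
    idx = np.clip(np.digitize(ndvi, edges_x[1:-1]), 0, n_bins - 1)

    xs, tops, bots = [], [], []
    for j in range(n_bins):
        vals = lst[idx == j]
        if vals.size < min_pixels_per_bin:
            continue
        xs.append(centers[j])
        tops.append(np.quantile(vals, edge_percentile))
        bots.append(np.quantile(vals, 1.0 - edge_percentile))
    x = np.asarray(xs)
    a, b, r2_dry = _edge_line(x, np.asarray(tops))
    c, d, r2_wet = _edge_line(x, np.asarray(bots))
    return TriangleEdges(a=a, b=b, c=c, d=d, ndvi_range=(lo, hi),
                         fit_r2_dry=r2_dry, fit_r2_wet=r2_wet)


def compute_tvdi(
    ndvi: np.ndarray,
    lst: np.ndarray,
    edges: TriangleEdges,
    time: float | None = None,
) -> TvdiScene:
    """Per-pixel ``(T_obs - T_w) / (T_d - T_w)`` clipped into [0, 1].

    Pixels with missing NDVI or LST, or NDVI outside ``edges.ndvi_range``,
    are flagged invalid and carry NaN.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    lst = np.asarray(lst, dtype=float)
    if ndvi.shape != lst.shape:
        raise InterfaceError("ndvi and lst must be co-registered (same shape)")
    lo, hi = edges.ndvi_range
    valid = np.isfinite(ndvi) & np.isfinite(lst) & (ndvi >= lo) & (ndvi <= hi)
    t_d = edges.t_dry(ndvi)
    t_w = edges.t_wet(ndvi)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (lst - t_w) / (t_d - t_w)
    clipped = np.clip(raw, 0.0, 1.0)
    out = np.where(valid, clipped, np.nan)
    n_valid = int(valid.sum())
    tol = 1e-12  # boundary pixels are not "clipped" up to float jitter
    clip_frac = 0.0 if n_valid == 0 else float(
        np.sum(valid & ((raw < -tol) | (raw > 1 + tol))) / n_valid
    )
    return TvdiScene(tvdi=out, time=time, qc_mask=valid, clip_fraction=clip_frac)


def resample_nearest(
    raster: np.ndarray, src: GridSpec, dst: GridSpec
) -> np.ndarray:
    """Nearest-neighbour resampling between two regular grids.

    Every target cell takes the value of the source cell whose centre is
    closest to the target cell centre; no new values are introduced.
    """
    src.check_compatible(dst)
    raster = np.asarray(raster)
    if raster.shape != src.shape:
        raise InterfaceError(f"raster shape {raster.shape} != grid {src.shape}")
    xt = dst.origin_x + (np.arange(dst.ncols) + 0.5) * dst.dx
    yt = dst.origin_y - (np.arange(dst.nrows) + 0.5) * dst.dy
    # index of the nearest source centre along each axis
    jx = np.clip(np.round((xt - src.origin_x) / src.dx - 0.5).astype(int),
                 0, src.ncols - 1)
    iy = np.clip(np.round((src.origin_y - yt) / src.dy - 0.5).astype(int),
                 0, src.nrows - 1)
    return raster[np.ix_(iy, jx)]
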
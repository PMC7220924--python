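"""Generators for every input the analysis chain consumes.

All generators are pure functions of their parameters and a seed: calling
twice with identical arguments yields bit-identical output.  Each returned
container keeps the ground truth used to build it (latent moisture, path
coefficients, planted correlations) so downstream estimators can be tested
against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rwlr.errors import InputError, ParameterError
from rwlr.grids import GridSpec
from rwlr.tvdi import TriangleEdges

__all__ = [
    "PrecipSeries",
    "SceneStack",
    "CzuTable",
    "GlobalGrid",
    "CZU_COLUMNS",
    "default_betas",
    "gen_precip",
    "gen_scene_stack",
    "gen_czu_table",
    "gen_global_grid",
]

CZU_COLUMNS = [
    "czu_id", "rwlr", "npp", "mat", "ap", "sd", "pdsi", "soil_n",
    "br_si", "br_ca", "br_mg", "br_fe", "br_al",
]


# ---------------------------------------------------------------------------
# daily precipitation

@dataclass
class PrecipSeries:
    """Daily station precipitation: gap-free calendar dates, depths in mm."""

    station_id: str
    dates: pd.DatetimeIndex
    precip_mm: np.ndarray

    def __post_init__(self) -> None:
        self.precip_mm = np.asarray(self.precip_mm, dtype=float)
        if len(self.dates) != len(self.precip_mm):
            raise InputError("dates and precip_mm differ in length")
        if len(self.dates) < 365:
            raise InputError("series must span at least 365 days")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if deltas.size and not np.all(deltas == 1):
            raise InputError("dates must be strictly daily with no gaps")
        if np.any(self.precip_mm < 0) or not np.all(np.isfinite(self.precip_mm)):
            raise InputError("precip_mm must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.dates)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"date": self.dates.strftime("%Y-%m-%d"), "precip_mm": self.precip_mm}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, station_id: str = "station") -> "PrecipSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(station_id=station_id,
                   dates=pd.DatetimeIndex(df["date"]),
                   precip_mm=df["precip_mm"].to_numpy())


def gen_precip(
    n_days: int,
    p_wet_to_wet: float = 0.60,
    p_dry_to_wet: float = 0.25,
    mean_depth: float = 8.0,
    seed: int = 0,
    start: str = "2001-01-01",
    station_id: str = "CZU00",
    start_wet: bool = False,
) -> PrecipSeries:
    """Two-state Markov rainfall occurrence with exponential wet-day depths.

    Dry-run lengths are geometric with parameter ``p_dry_to_wet``, so the
    frequency and length of dry spells is directly controllable.
    """
    for name, p in (("p_wet_to_wet", p_wet_to_wet), ("p_dry_to_wet", p_dry_to_wet)):
        if not 0.0 < p <= 1.0:
            raise ParameterError(f"{name} must lie in (0, 1]; got {p}")
    if n_days < 365:
        raise ParameterError("n_days must be >= 365")
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    wet = np.empty(n_days, dtype=bool)
    wet[0] = start_wet
    u = rng.random(n_days)
    for t in range(1, n_days):
        p_wet = p_wet_to_wet if wet[t - 1] else p_dry_to_wet
        wet[t] = u[t] < p_wet
    depths = np.where(wet, rng.exponential(mean_depth, size=n_days), 0.0)
    dates = pd.date_range(start, periods=n_days, freq="D")
    return PrecipSeries(station_id=station_id, dates=dates, precip_mm=depths)


# ---------------------------------------------------------------------------
# NDVI / LST composite stacks

@dataclass
class SceneStack:
    """Co-registered NDVI/LST composites with latent moisture ground truth.

    ``moisture_truth`` holds the bucket-model soil-moisture state used to
    place each pixel between the wet and dry edges; it exists only so tests
    can compare retrieved dryness against truth.  ``anchor_dry``/``anchor_wet``
    mark sentinel pixels pinned at moisture 0 (bare rock) and 1 (open water)
    that tie down the scatter envelopes; they are exempt from the bucket
    recursion.
    """

    times: np.ndarray                 # days since series start
    ndvi: np.ndarray                  # (T, rows, cols), static + jitter
    lst: np.ndarray                   # (T, rows, cols), Kelvin
    moisture_truth: np.ndarray        # (T, rows, cols) in [0, 1]
    grid: GridSpec
    edges_truth: TriangleEdges
    anchor_dry: np.ndarray            # (rows, cols) bool
    anchor_wet: np.ndarray            # (rows, cols) bool
    params: dict = field(default_factory=dict)

    @property
    def regular_mask(self) -> np.ndarray:
        return ~(self.anchor_dry | self.anchor_wet)


def bucket_step(s: float, infiltration: float, et_rate: float, leakage: float) -> float:
    """One day of the soil-moisture bucket: fill (capped), then drain."""
    s_next = s + min(infiltration, 1.0 - s) - (et_rate + leakage) * s
    return min(max(s_next, 0.0), 1.0)


def simulate_bucket(
    precip_mm: np.ndarray,
    leakage: float,
    et_rate: float,
    infil_per_mm: float = 0.2,
    s0: float = 0.9,
) -> np.ndarray:
    """Daily bucket trajectory S_t in [0, 1] driven by precipitation."""
    s = np.empty(len(precip_mm))
    state = s0
    for t, p in enumerate(precip_mm):
        state = bucket_step(state, infil_per_mm * p, et_rate, leakage)
        s[t] = state
    return s


def gen_scene_stack(
    precip: PrecipSeries,
    leakage: float = 0.05,
    et_rate: float = 0.02,
    edges_truth: TriangleEdges | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (24, 24),
    composite_interval: int = 5,
    infil_per_mm: float = 0.2,
    s0: float = 0.9,
    n_ndvi_levels: int = 20,
    ndvi_jitter: float = 1e-4,
) -> SceneStack:
    """Forward model from rainfall to NDVI/LST composites.

    A single bucket ``dS = infiltration - (et_rate + leakage) * S`` drives the
    latent moisture shared by all vegetated pixels; each pixel's LST is placed
    linearly between the planted triangle edges::

        LST = T_d(NDVI) - moisture * (T_d(NDVI) - T_w(NDVI)) + noise

    so ground-truth dryness equals ``1 - moisture``.  NDVI is static per pixel:
    one of ``n_ndvi_levels`` grid values (the bin centres of the planted
    ``ndvi_range``) plus a tiny jitter.  The first two rows are sentinel
    pixels pinned at moisture 0 and 1 on those exact grid values, so the
    per-bin extremes of every scene lie exactly on the planted edges.
    """
    if leakage < 0 or et_rate < 0:
        raise ParameterError("leakage and et_rate must be >= 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if edges_truth is None:
        edges_truth = TriangleEdges(a=320.0, b=-15.0, c=290.0, d=0.0,
                                    ndvi_range=(0.1, 0.9))
    # TriangleEdges already guarantees T_d > T_w over its range.
    rows, cols = shape
    if rows < 3 or cols < n_ndvi_levels:
        raise ParameterError("shape must be at least (3, n_ndvi_levels)")
    rng = np.random.default_rng(seed)

    lo, hi = edges_truth.ndvi_range
    width = (hi - lo) / n_ndvi_levels
    levels = lo + (np.arange(n_ndvi_levels) + 0.5) * width

    ndvi_static = np.empty(shape)
    anchor_dry = np.zeros(shape, dtype=bool)
    anchor_wet = np.zeros(shape, dtype=bool)
    anchor_dry[0, :] = True
    anchor_wet[1, :] = True
    cyc = levels[np.arange(cols) % n_ndvi_levels]
    ndvi_static[0, :] = cyc
    ndvi_static[1, :] = cyc
    pick = rng.integers(0, n_ndvi_levels, size=(rows - 2, cols))
    jit = rng.uniform(-ndvi_jitter, ndvi_jitter, size=(rows - 2, cols))
    ndvi_static[2:, :] = levels[pick] + jit

    times = np.arange(0, len(precip), composite_interval)
    s_daily = simulate_bucket(precip.precip_mm, leakage, et_rate,
                              infil_per_mm=infil_per_mm, s0=s0)
    s_comp = s_daily[times]

    nt = len(times)
    moisture = np.broadcast_to(
        s_comp[:, None, None], (nt, rows, cols)
    ).copy()
    moisture[:, anchor_dry] = 0.0
    moisture[:, anchor_wet] = 1.0

    t_d = edges_truth.t_dry(ndvi_static)
    t_w = edges_truth.t_wet(ndvi_static)
    lst = t_d[None, :, :] - moisture * (t_d - t_w)[None, :, :]
    if noise_sd > 0:
        lst = lst + rng.normal(0.0, noise_sd, size=lst.shape)
    ndvi = np.broadcast_to(ndvi_static[None, :, :], lst.shape).copy()

    grid = GridSpec(nrows=rows, ncols=cols, dx=1.0, dy=1.0,
                    origin_x=0.0, origin_y=float(rows))
    return SceneStack(
        times=times, ndvi=ndvi, lst=lst, moisture_truth=moisture, grid=grid,
        edges_truth=edges_truth, anchor_dry=anchor_dry, anchor_wet=anchor_wet,
        params={
            "leakage": leakage, "et_rate": et_rate, "noise_sd": noise_sd,
            "infil_per_mm": infil_per_mm, "s0": s0, "seed": seed,
            "composite_interval": composite_interval,
            "n_ndvi_levels": n_ndvi_levels,
        },
    )


# ---------------------------------------------------------------------------
# critical-zone-unit covariate table

def default_betas() -> dict[str, float]:
    """Raw-scale structural coefficients giving paper-like standardized
    effects (BR_Ca→RWLR strongly positive, RWLR→NPP negative, MAT→NPP
    positive, BR_Si ≈ mirror of BR_Ca)."""
    return {
        "br_si_alpha": 62.0,     # br_si = alpha - gamma * br_ca + e
        "br_si_gamma": 0.90,
        "rwlr_intercept": 1.0,   # rwlr = b0 + b1 * br_ca + e
        "rwlr_br_ca": 0.1386,
        "npp_intercept": 450.0,  # npp = b0 + b2 * rwlr + b3 * mat + e
        "npp_rwlr": -48.75,
        "npp_mat": 22.5,
    }


# residual standard deviations at noise_sd = 1 (scaled linearly)
_EQ_SD = {"br_si": 3.0, "rwlr": 0.872, "npp": 104.7}
_INDEP = {  # mean, sd of covariates generated as independent Gaussians
    "mat": (15.0, 2.0), "ap": (1150.0, 180.0), "sd": (1300.0, 150.0),
    "pdsi": (0.0, 1.0), "soil_n": (0.25, 0.08),
    "br_mg": (3.0, 1.2), "br_fe": (4.0, 1.5), "br_al": (8.0, 3.0),
}


@dataclass
class CzuTable:
    """Per-unit covariate table plus the generating ground truth."""

    frame: pd.DataFrame
    betas: dict[str, float]
    noise_sd: float
    seed: int

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, columns=CZU_COLUMNS)

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"betas": self.betas, "noise_sd": self.noise_sd,
                       "seed": self.seed}, fh, indent=2)

    @staticmethod
    def read_csv(path: str | Path) -> pd.DataFrame:
        df = pd.read_csv(path)
        missing = set(CZU_COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"CZU table missing columns: {sorted(missing)}")
        return df


def gen_czu_table(
    n: int = 23,
    betas: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> CzuTable:
    """Recursive structural system behind the covariate table.

    ``br_ca ~ U(5, 50)``; ``br_si`` is a strongly negative linear function of
    ``br_ca``; ``rwlr`` responds to ``br_ca``; ``npp`` responds to ``rwlr``
    (negatively, by default) and ``mat``; all remaining covariates are
    independent noise.  ``noise_sd`` scales every equation's residual sd
    (0 gives an exact linear system).
    """
    if n < 10:
        raise ParameterError("n must be >= 10")
    b = default_betas()
    if betas:
        unknown = set(betas) - set(b)
        if unknown:
            raise ParameterError(f"unknown beta names: {sorted(unknown)}")
        b.update(betas)
    if not all(np.isfinite(v) for v in b.values()):
        raise ParameterError("betas must be finite")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    br_ca = rng.uniform(5.0, 50.0, size=n)
    indep = {k: mu + sd * rng.standard_normal(n) for k, (mu, sd) in _INDEP.items()}
    eps = {k: noise_sd * s * rng.standard_normal(n) for k, s in _EQ_SD.items()}

    br_si = b["br_si_alpha"] - b["br_si_gamma"] * br_ca + eps["br_si"]
    rwlr = b["rwlr_intercept"] + b["rwlr_br_ca"] * br_ca + eps["rwlr"]
    npp = (b["npp_intercept"] + b["npp_rwlr"] * rwlr
           + b["npp_mat"] * indep["mat"] + eps["npp"])

    frame = pd.DataFrame({
        "czu_id": [f"CZU{i:02d}" for i in range(n)],
        "rwlr": rwlr, "npp": npp,
        "mat": indep["mat"], "ap": indep["ap"], "sd": indep["sd"],
        "pdsi": indep["pdsi"], "soil_n": indep["soil_n"],
        "br_si": br_si, "br_ca": br_ca,
        "br_mg": indep["br_mg"], "br_fe": indep["br_fe"],
        "br_al": indep["br_al"],
    })[CZU_COLUMNS]
    return CzuTable(frame=frame, betas=b, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# global karst grid

@dataclass
class GlobalGrid:
    """Karst mask plus annual growing-season NDVI/temperature series."""

    karst_mask: np.ndarray      # (rows, cols) bool
    ndvi_series: np.ndarray     # (years, rows, cols)
    temp_series: np.ndarray     # (years, rows, cols)
    grid: GridSpec
    params: dict = field(default_factory=dict)


def _blob_mask(shape: tuple[int, int], mask_blob) -> np.ndarray:
    rows, cols = shape
    if mask_blob is None:
        r0, r1 = rows // 3, rows - rows // 3
        c0, c1 = cols // 3, cols - cols // 3
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        return mask
    if isinstance(mask_blob, np.ndarray):
        if mask_blob.shape != shape:
            raise ParameterError("mask_blob shape mismatch")
        return mask_blob.astype(bool)
    r0, r1, c0, c1 = mask_blob
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def gen_global_grid(
    shape: tuple[int, int] = (40, 40),
    mask_blob=None,
    r_inside: float = -0.2,
    r_outside: float = 0.3,
    years: int = 30,
    seed: int = 0,
    temp_mean: float = 15.0,
    temp_sd: float = 2.0,
) -> GlobalGrid:
    """Plant a per-pixel NDVI–temperature correlation contrast across a mask.

    For each pixel, the standardized annual NDVI anomaly is
    ``r * z_temp + sqrt(1 - r^2) * z_noise`` with ``r`` chosen by mask
    membership, so the expected sample correlation matches the target.
    """
    for name, r in (("r_inside", r_inside), ("r_outside", r_outside)):
        if not -1.0 < r < 1.0:
            raise ParameterError(f"{name} must lie in (-1, 1); got {r}")
    if years < 10:
        raise ParameterError("years must be >= 10")
    rows, cols = shape
    mask = _blob_mask(shape, mask_blob)
    rng = np.random.default_rng(seed)
    z_t = rng.standard_normal((years, rows, cols))
    z_n = rng.standard_normal((years, rows, cols))
    r = np.where(mask, r_inside, r_outside)
    x = r[None] * z_t + np.sqrt(1.0 - r[None] ** 2) * z_n
    temp = temp_mean + temp_sd * z_t
    ndvi = np.clip(0.5 + 0.08 * x, -1.0, 1.0)
    grid = GridSpec(nrows=rows, ncols=cols, dx=1.0, dy=1.0,
                    origin_x=0.0, origin_y=float(rows))
    return GlobalGrid(karst_mask=mask, ndvi_series=ndvi, temp_series=temp,
                      grid=grid,
                      params={"r_inside": r_inside, "r_outside": r_outside,
                              "years": years, "seed": seed})
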
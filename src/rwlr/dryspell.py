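"""Dry-spell detection and the regolith water-loss-rate statistic.

A dry spell is a maximal run of at least ``min_length`` consecutive days with
precipitation at or below a wet threshold (default: exactly zero).  Within
each spell the dryness index is sampled at the composite timestamps that fall
inside it; the water-loss rate is built from the per-spell mean slope

    (TVDI_b - TVDI_a) / dT_ab

over consecutive valid composite pairs, combined across spells and scaled by
100.  The printed formula sums per-spell means while the surrounding text
describes an average; both aggregates are implemented and the choice is an
explicit argument (``mean`` is the default, since a sum confounds the rate
with the spell count, which varies between sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from rwlr.errors import GeometryError, InputError, ParameterError
from rwlr.grids import GridSpec
from rwlr.synthetic import PrecipSeries
from rwlr.tvdi import TvdiScene

__all__ = [
    "DrySpell",
    "SpellTrace",
    "RwlrResult",
    "SiteSummary",
    "detect_dry_spells",
    "czu_mean_tvdi",
    "compute_rwlr",
    "filter_sites",
]


@dataclass(frozen=True)
class DrySpell:
    """Maximal rain-free run, inclusive endpoints."""

    start_date: pd.Timestamp
    end_date: pd.Timestamp

    @property
    def duration(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def contains(self, when: pd.Timestamp) -> bool:
        return self.start_date <= when <= self.end_date


@dataclass
class SpellTrace:
    """Composite samples and slopes of the dryness index inside one spell."""

    spell: DrySpell
    times: np.ndarray        # day offsets of valid composites inside the spell
    tvdi_values: np.ndarray
    slopes: np.ndarray       # per consecutive pair, per day

    def __post_init__(self) -> None:
        # consecutive pairing gives len(times) - 1 slopes; endpoint mode one
        if not 1 <= len(self.slopes) <= max(len(self.times) - 1, 0):
            raise InputError("slopes must pair composites inside the spell")


@dataclass
class RwlrResult:
    """Water-loss rate for one unit (x100 scale)."""

    czu_id: str
    rwlr: float
    n_spells_used: int
    per_spell_means: np.ndarray
    traces: list[SpellTrace] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.n_spells_used == 0


def detect_dry_spells(
    precip: PrecipSeries,
    min_length: int = 5,
    wet_threshold: float = 0.0,
) -> list[DrySpell]:
    """All maximal runs of >= ``min_length`` days with precip <= threshold.

    Returned in chronological order; runs are maximal, hence non-overlapping.
    """
    if min_length < 2:
        raise ParameterError("min_length must be >= 2")
    dry = precip.precip_mm <= wet_threshold
    spells: list[DrySpell] = []
    # run-length encode the dry indicator
    padded = np.concatenate(([False], dry, [False]))
    changes = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(changes[::2], changes[1::2]):
        if e - s >= min_length:
            spells.append(DrySpell(start_date=precip.dates[s],
                                   end_date=precip.dates[e - 1]))
    return spells


def czu_mean_tvdi(
    scenes: Sequence[TvdiScene],
    grid: GridSpec,
    center_xy: tuple[float, float],
    radius: float,
    min_valid_fraction: float = 0.5,
    pixel_mask: np.ndarray | None = None,
) -> pd.Series:
    """Disc-mean dryness per composite for one unit.

    The unit is a disc (paper scale: 20 km radius around a station) in grid
    coordinates; pixels whose centres fall inside are averaged.  Composites
    whose valid-pixel fraction inside the disc is below
    ``min_valid_fraction`` are dropped.  ``pixel_mask`` optionally restricts
    the disc to a pixel subset (e.g. to ignore sentinel pixels in synthetic
    scenes).
    """
    xs, ys = grid.cell_centers()
    cx, cy = center_xy
    disc = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    if pixel_mask is not None:
        disc &= pixel_mask
    if not disc.any():
        raise GeometryError("disc does not intersect the grid")
    out_t, out_v = [], []
    for scene in scenes:
        vals = scene.tvdi[disc]
        ok = np.isfinite(vals)
        if ok.mean() < min_valid_fraction:
            continue
        out_t.append(scene.time)
        out_v.append(float(vals[ok].mean()))
    return pd.Series(out_v, index=pd.Index(out_t, name="time"), name="tvdi")


def _spell_slopes(
    times: np.ndarray, values: np.ndarray, pairs: str
) -> np.ndarray:
    if pairs == "consecutive":
        dt = np.diff(times).astype(float)
        return np.diff(values) / dt
    if pairs == "endpoints":
        span = float(times[-1] - times[0])
        return np.array([(values[-1] - values[0]) / span])
    raise ParameterError(f"unknown slope pairing {pairs!r}")


def compute_rwlr(
    tvdi_series: pd.Series,
    spells: Iterable[DrySpell],
    start_date: pd.Timestamp | None = None,
    aggregate: Literal["mean", "sum"] = "mean",
    min_composites: int = 2,
    slope_pairs: Literal["consecutive", "endpoints"] = "consecutive",
    czu_id: str = "czu",
) -> RwlrResult:
    """Water-loss rate from a unit-mean dryness series and its dry spells.

    ``tvdi_series`` is indexed either by day offsets (ints/floats) — in which
    case ``start_date`` anchors offset 0 — or directly by timestamps.  For
    each spell with at least ``min_composites`` valid composites inside it,
    slopes over consecutive valid pairs are averaged; per-spell means are
    combined by ``aggregate`` and scaled by 100.  With no usable spell the
    result is empty (``rwlr`` is NaN, not 0).
    """
    if min_composites < 2:
        raise ParameterError("min_composites must be >= 2")
    if aggregate not in ("mean", "sum"):
        raise ParameterError("aggregate must be 'mean' or 'sum'")
    idx = tvdi_series.index
    if isinstance(idx, pd.DatetimeIndex):
        if start_date is None:
            start_date = idx[0]
        day_offsets = (idx - start_date).days.to_numpy()
    else:
        if start_date is None:
            raise ParameterError("start_date required for offset-indexed series")
        day_offsets = np.asarray(idx, dtype=float)
    values = tvdi_series.to_numpy(dtype=float)
    valid = np.isfinite(values)

    traces: list[SpellTrace] = []
    means: list[float] = []
    for spell in spells:
        t0 = (spell.start_date - start_date).days
        t1 = (spell.end_date - start_date).days
        inside = valid & (day_offsets >= t0) & (day_offsets <= t1)
        if inside.sum() < min_composites:
            continue
        t_in = day_offsets[inside]
        v_in = values[inside]
        slopes = _spell_slopes(t_in, v_in, slope_pairs)
        traces.append(SpellTrace(spell=spell, times=t_in, tvdi_values=v_in,
                                 slopes=slopes))
        means.append(float(slopes.mean()))

    per_spell = np.asarray(means)
    if per_spell.size == 0:
        return RwlrResult(czu_id=czu_id, rwlr=float("nan"),
                          n_spells_used=0, per_spell_means=per_spell)
    combined = per_spell.mean() if aggregate == "mean" else per_spell.sum()
    return RwlrResult(czu_id=czu_id, rwlr=float(combined * 100.0),
                      n_spells_used=len(means), per_spell_means=per_spell,
                      traces=traces)


@dataclass(frozen=True)
class SiteSummary:
    """Candidate unit bookkeeping for the inclusion filter."""

    czu_id: str
    years_span: float
    relocated: bool
    n_spells: int


def filter_sites(
    sites: Sequence[SiteSummary],
    min_years: float = 10.0,
    min_spells: int = 10,
) -> tuple[list[SiteSummary], dict[str, str]]:
    """Apply the site-inclusion rules; report a reason per exclusion.

    A site is kept when its record spans the full period, its station was
    never relocated, and it has at least ``min_spells`` identifiable spells.
    """
    kept: list[SiteSummary] = []
    excluded: dict[str, str] = {}
    for site in sites:
        if site.years_span < min_years:
            excluded[site.czu_id] = "record_span"
        elif site.relocated:
            excluded[site.czu_id] = "relocated"
        elif site.n_spells < min_spells:
            excluded[site.czu_id] = "min_spells"
        else:
            kept.append(site)
    return kept, excluded
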
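import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_dry_spells
from rwlr.dryspell import (DrySpell, RwlrResult, SiteSummary, compute_rwlr,
                           czu_mean_tvdi, detect_dry_spells, filter_sites)
from rwlr.errors import GeometryError, ParameterError
from rwlr.grids import GridSpec
from rwlr.synthetic import gen_precip
from rwlr.tvdi import TvdiScene

from conftest import make_precip


def spells_to_tuples(precip, spells):
    start = precip.dates[0]
    return [((s.start_date - start).days, (s.end_date - start).days)
            for s in spells]


class TestDetectDrySpells:
    def test_worked_example(self):
        p = make_precip([0, 0, 0, 0, 0, 2, 0, 0, 0, 0])
        spells = detect_dry_spells(p, min_length=5)
        # trailing dry run is only 4 days followed by wet padding
        assert spells_to_tuples(p, spells) == [(0, 4)]
        assert spells[0].duration == 5

    def test_all_wet(self):
        p = make_precip([1.0] * 365)
        assert detect_dry_spells(p) == []

    def test_trailing_spell_is_maximal(self):
        p = make_precip([1.0] * 358 + [0.0] * 7)
        spells = detect_dry_spells(p)
        assert spells_to_tuples(p, spells) == [(358, 364)]

    def test_wet_threshold(self):
        p = make_precip([0.05] * 6 + [1.0] * 359)
        assert detect_dry_spells(p, wet_threshold=0.0) == []
        assert len(detect_dry_spells(p, wet_threshold=0.1)) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        p = gen_precip(1000, p_dry_to_wet=0.22, seed=seed)
        got = spells_to_tuples(p, detect_dry_spells(p))
        expected = brute_force_dry_spells(p.precip_mm == 0, min_length=5)
        assert got == expected

    @given(pattern=st.lists(st.booleans(), min_size=1, max_size=120),
           min_length=st.integers(2, 8))
    @settings(max_examples=60, deadline=None)
    def test_oracle_property(self, pattern, min_length):
        depths = [0.0 if dry else 1.0 for dry in pattern]
        p = make_precip(depths)
        got = spells_to_tuples(p, detect_dry_spells(p, min_length=min_length))
        expected = brute_force_dry_spells(p.precip_mm == 0, min_length)
        assert got == expected

    def test_min_length_validation(self):
        with pytest.raises(ParameterError):
            detect_dry_spells(make_precip([1.0]), min_length=1)


def _scene(values, time):
    return TvdiScene(tvdi=np.asarray(values, dtype=float), time=time)


class TestCzuMeanTvdi:
    grid = GridSpec(nrows=10, ncols=10, origin_y=10.0)

    def test_uniform_scene(self):
        scenes = [_scene(np.full((10, 10), 0.3), 0.0)]
        s = czu_mean_tvdi(scenes, self.grid, center_xy=(5.0, 5.0), radius=3.0)
        assert s.iloc[0] == pytest.approx(0.3)

    def test_disc_outside_grid(self):
        scenes = [_scene(np.full((10, 10), 0.3), 0.0)]
        with pytest.raises(GeometryError):
            czu_mean_tvdi(scenes, self.grid, center_xy=(100.0, 100.0),
                          radius=2.0)

    def test_half_and_half_scene(self):
        field = np.full((10, 10), 0.2)
        field[:, 5:] = 0.4  # split along x = 5
        scenes = [_scene(field, 0.0)]
        # disc centred on the split covers both halves with equal pixel counts
        s = czu_mean_tvdi(scenes, self.grid, center_xy=(5.0, 5.0), radius=3.2)
        xs, ys = self.grid.cell_centers()
        disc = (xs - 5.0) ** 2 + (ys - 5.0) ** 2 <= 3.2**2
        exact = field[disc].mean()
        assert s.iloc[0] == pytest.approx(exact)
        assert s.iloc[0] == pytest.approx(0.3, abs=0.05)

    def test_low_valid_fraction_composites_dropped(self):
        good = _scene(np.full((10, 10), 0.5), 0.0)
        bad_field = np.full((10, 10), np.nan)
        bad_field[0, 0] = 0.5
        bad = _scene(bad_field, 5.0)
        s = czu_mean_tvdi([good, bad], self.grid, (5.0, 5.0), 3.0,
                          min_valid_fraction=0.5)
        assert list(s.index) == [0.0]


class TestComputeRwlr:
    def make_series(self, times, values):
        return pd.Series(values, index=pd.Index(times, dtype=float))

    def spell(self, d0, d1, start="2001-01-01"):
        base = pd.Timestamp(start)
        return DrySpell(start_date=base + pd.Timedelta(days=d0),
                        end_date=base + pd.Timedelta(days=d1))

    def test_worked_example_two_composites(self):
        series = self.make_series([0, 5], [0.20, 0.40])
        result = compute_rwlr(series, [self.spell(0, 6)],
                              start_date=pd.Timestamp("2001-01-01"))
        assert result.per_spell_means[0] == pytest.approx(0.04)
        assert result.rwlr == pytest.approx(4.0)
        assert result.n_spells_used == 1

    def test_constant_tvdi_gives_zero(self):
        series = self.make_series([0, 5, 10], [0.3, 0.3, 0.3])
        for agg in ("mean", "sum"):
            r = compute_rwlr(series, [self.spell(0, 11)],
                             start_date=pd.Timestamp("2001-01-01"),
                             aggregate=agg)
            assert r.rwlr == pytest.approx(0.0)

    def test_mean_vs_sum_aggregates(self):
        # three spells with per-spell mean slopes 0.01, 0.02, 0.03 per day
        times = [0, 5, 20, 25, 40, 45]
        values = [0.1, 0.1 + 0.05, 0.1, 0.1 + 0.10, 0.1, 0.1 + 0.15]
        series = self.make_series(times, values)
        spells = [self.spell(0, 6), self.spell(20, 26), self.spell(40, 46)]
        start = pd.Timestamp("2001-01-01")
        mean_r = compute_rwlr(series, spells, start_date=start, aggregate="mean")
        sum_r = compute_rwlr(series, spells, start_date=start, aggregate="sum")
        assert np.allclose(mean_r.per_spell_means, [0.01, 0.02, 0.03])
        assert mean_r.rwlr == pytest.approx(2.0)
        assert sum_r.rwlr == pytest.approx(6.0)

    def test_no_usable_spell_is_empty_not_zero(self):
        series = self.make_series([0], [0.5])
        r = compute_rwlr(series, [self.spell(0, 6)],
                         start_date=pd.Timestamp("2001-01-01"))
        assert r.empty and np.isnan(r.rwlr)

    def test_spells_with_too_few_composites_excluded(self):
        series = self.make_series([0, 5, 30], [0.2, 0.4, 0.9])
        spells = [self.spell(0, 6), self.spell(28, 34)]
        r = compute_rwlr(series, spells,
                         start_date=pd.Timestamp("2001-01-01"))
        assert r.n_spells_used == 1

    def test_time_shift_invariance(self):
        times = [0, 5, 20, 25]
        values = [0.1, 0.2, 0.3, 0.45]
        spells = [self.spell(0, 6), self.spell(20, 26)]
        start = pd.Timestamp("2001-01-01")
        base = compute_rwlr(self.make_series(times, values), spells,
                            start_date=start)
        shifted = compute_rwlr(
            self.make_series([t + 100 for t in times], values),
            [self.spell(100, 106), self.spell(120, 126)], start_date=start)
        assert shifted.rwlr == pytest.approx(base.rwlr)

    def test_scaling_property(self):
        times = [0, 5, 10]
        series = self.make_series(times, [0.1, 0.2, 0.25])
        scaled = self.make_series(times, [0.3, 0.6, 0.75])  # differences x3
        spells = [self.spell(0, 11)]
        start = pd.Timestamp("2001-01-01")
        r1 = compute_rwlr(series, spells, start_date=start).rwlr
        r3 = compute_rwlr(scaled, spells, start_date=start).rwlr
        assert r3 == pytest.approx(3 * r1)

    def test_datetime_indexed_series(self):
        idx = pd.DatetimeIndex(["2001-01-01", "2001-01-06"])
        series = pd.Series([0.2, 0.4], index=idx)
        r = compute_rwlr(series, [self.spell(0, 6)])
        assert r.rwlr == pytest.approx(4.0)

    def test_endpoint_slope_mode(self):
        series = self.make_series([0, 5, 10], [0.2, 0.25, 0.4])
        spells = [self.spell(0, 11)]
        start = pd.Timestamp("2001-01-01")
        r = compute_rwlr(series, spells, start_date=start,
                         slope_pairs="endpoints")
        assert r.rwlr == pytest.approx((0.4 - 0.2) / 10 * 100)


class TestFilterSites:
    def test_exclusion_reasons(self):
        sites = [
            SiteSummary("a", years_span=10, relocated=False, n_spells=9),
            SiteSummary("b", years_span=10, relocated=True, n_spells=30),
            SiteSummary("c", years_span=8, relocated=False, n_spells=30),
            SiteSummary("d", years_span=10, relocated=False, n_spells=30),
        ]
        kept, excluded = filter_sites(sites)
        assert [s.czu_id for s in kept] == ["d"]
        assert excluded == {"a": "min_spells", "b": "relocated",
                            "c": "record_span"}

    def test_thirty_candidates_to_twentythree(self):
        # fixture mirroring the 30-station -> 23-unit selection narrative
        rng = np.random.default_rng(8)
        sites = []
        for i in range(30):
            if i < 3:
                sites.append(SiteSummary(f"s{i}", 9.0, False, 20))
            elif i < 5:
                sites.append(SiteSummary(f"s{i}", 10.0, True, 20))
            elif i < 7:
                sites.append(SiteSummary(f"s{i}", 10.0, False,
                                         int(rng.integers(0, 10))))
            else:
                sites.append(SiteSummary(f"s{i}", 10.0, False,
                                         int(rng.integers(10, 40))))
        kept, excluded = filter_sites(sites)
        assert len(kept) == 23
        assert len(excluded) == 7
        assert {s.czu_id for s in kept} == {f"s{i}" for i in range(7, 30)}
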
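"""Spike-in conversion, species selection, standardized merging."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from edmnet.quantify import (
    DEFAULT_MIN_SPIKE_COPIES,
    DEFAULT_MIN_SPIKE_READS,
    StandardizedPanel,
    reads_to_copies,
    select_top_species,
    standardize_merge,
)


def _panel(rows):
    return pd.DataFrame(rows, columns=["site", "time_index", "species", "reads",
                                       "spike_copies_per_uL"])


class TestReadsToCopies:
    def test_unit_conversion(self):
        p = _panel([
            ("s1", 0, "spike", 100, 100.0),
            ("s1", 0, "fish", 50, 100.0),
        ])
        out = reads_to_copies(p, "spike", 0.346, 12)
        assert out.loc[out.species == "fish", "copies"].item() == pytest.approx(50.0)

    def test_zero_spike_copies_uses_default_minimum(self):
        p = _panel([
            ("s1", 0, "spike", 100, 0.0),
            ("s1", 0, "fish", 50, 0.0),
        ])
        out = reads_to_copies(p, "spike", DEFAULT_MIN_SPIKE_COPIES,
                              DEFAULT_MIN_SPIKE_READS)
        conv = 100 / 0.346
        assert out.loc[out.species == "fish", "copies"].item() == pytest.approx(50 / conv)

    def test_zero_spike_reads_uses_default_minimum(self):
        p = _panel([
            ("s1", 0, "spike", 0, 2.0),
            ("s1", 0, "fish", 30, 2.0),
        ])
        out = reads_to_copies(p, "spike", DEFAULT_MIN_SPIKE_COPIES,
                              DEFAULT_MIN_SPIKE_READS)
        conv = DEFAULT_MIN_SPIKE_READS / 2.0
        assert out.loc[out.species == "fish", "copies"].item() == pytest.approx(30 / conv)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.integers(min_value=2, max_value=50),
           reads=st.lists(st.integers(min_value=1, max_value=10_000),
                          min_size=2, max_size=6))
    def test_depth_invariance(self, scale, reads):
        # multiplying every read in a sample (spike included) leaves copies unchanged
        rows = [("s1", 0, "spike", reads[0], 5.0)]
        rows += [("s1", 0, f"f{i}", r, 5.0) for i, r in enumerate(reads[1:])]
        base = reads_to_copies(_panel(rows), "spike", 0.346, 12)
        rows_scaled = [(s, t, sp, r * scale, c) for s, t, sp, r, c in rows]
        scaled = reads_to_copies(_panel(rows_scaled), "spike", 0.346, 12)
        np.testing.assert_allclose(base["copies"], scaled["copies"])

    def test_monotone_in_reads(self, small_survey):
        df, _ = small_survey
        out = reads_to_copies(df, "sp00")
        g = out[out.species != "sp00"].sort_values(["site", "time_index", "reads"])
        for _, sub in g.groupby(["site", "time_index"]):
            assert sub["copies"].is_monotonic_increasing

    def test_missing_spike_sample_raises(self):
        p = _panel([
            ("s1", 0, "spike", 10, 1.0),
            ("s1", 0, "fish", 5, 1.0),
            ("s1", 1, "fish", 5, 1.0),
        ])
        with pytest.raises(ValueError, match="missing from sample"):
            reads_to_copies(p, "spike", 0.346, 12)

    def test_auto_minima_are_observed_nonzero_minima(self):
        p = _panel([
            ("s1", 0, "spike", 0, 0.0),
            ("s1", 0, "fish", 10, 0.0),
            ("s1", 1, "spike", 7, 0.5),
            ("s1", 1, "fish", 10, 0.5),
        ])
        out = reads_to_copies(p, "spike", "auto", "auto")
        # sample 0: conversion = 7 / 0.5 (observed minima substituted)
        assert out.loc[(out.species == "fish") & (out.time_index == 0),
                       "copies"].item() == pytest.approx(10 / (7 / 0.5))


class TestTopSpecies:
    def test_ranked_by_detection_frequency(self):
        rows = []
        for t in range(10):
            rows.append(("s1", t, "a", 1, 1.0))
            rows.append(("s1", t, "b", 5 if t < 5 else 0, 1.0))
            rows.append(("s1", t, "c", 100 if t < 1 else 0, 1.0))
        p = _panel(rows)
        assert select_top_species(p, 2) == ["a", "b"]
        assert select_top_species(p, 3) == ["a", "b", "c"]

    def test_selected_dominate_excluded(self, small_survey):
        df, _ = small_survey
        top = select_top_species(df, 5)
        det = df.assign(d=df.reads > 0).groupby("species")["d"].sum()
        assert det[top].min() >= det.drop(top).max()

    def test_too_many_requested(self, small_survey):
        df, _ = small_survey
        with pytest.raises(ValueError):
            select_top_species(df, 999)


class TestStandardizeMerge:
    def _long(self, series_by_site, species="f"):
        rows = []
        for site, vals in series_by_site.items():
            for t, v in enumerate(vals):
                rows.append({"site": site, "time_index": t, "species": species,
                             "copies": v})
        return pd.DataFrame(rows)

    def test_three_point_series(self):
        p = standardize_merge(self._long({"s1": [1.0, 2.0, 3.0]}), ["f"],
                              env_vars=())
        sd = np.std([1, 2, 3])
        np.testing.assert_allclose(p.values("f"), np.array([-1, 0, 1]) / sd)

    def test_mean_zero_sd_one(self, small_survey):
        df, _ = small_survey
        from edmnet.quantify import reads_to_copies
        q = reads_to_copies(df, "sp00")
        panel = standardize_merge(q, [f"sp{i:02d}" for i in range(8)])
        for sp in panel.species:
            v = panel.values(sp)
            assert abs(np.nanmean(v)) < 1e-8
            assert abs(np.nanstd(v) - 1) < 1e-8

    def test_second_standardization_is_identity(self):
        long = self._long({"s1": list(np.arange(10.0) ** 2)})
        p1 = standardize_merge(long, ["f"], env_vars=())
        long2 = long.copy()
        long2["copies"] = p1.values("f")
        p2 = standardize_merge(long2, ["f"], env_vars=())
        np.testing.assert_allclose(p1.values("f"), p2.values("f"), atol=1e-12)

    def test_boundary_bookkeeping(self):
        long = self._long({"s1": [1.0, 2.0] * 25, "s2": [3.0, 4.0] * 25})
        p = standardize_merge(long, ["f"], env_vars=())
        assert len(p) == 100
        assert p.boundaries == [50]
        assert p.segments == [(0, 50), (50, 100)]

    def test_zero_variance_species_raises(self):
        long = self._long({"s1": [2.0] * 10})
        with pytest.raises(ValueError, match="zero variance"):
            standardize_merge(long, ["f"], env_vars=())

    def test_rank_and_shape_preserved_within_site(self, small_survey):
        df, _ = small_survey
        from edmnet.quantify import reads_to_copies
        q = reads_to_copies(df, "sp00")
        panel = standardize_merge(q, ["sp01"])
        raw = panel.raw["sp01"].to_numpy()
        std = panel.values("sp01")
        for a, b in panel.segments:
            r, s = raw[a:b], std[a:b]
            ok = np.isfinite(r) & np.isfinite(s)
            if ok.sum() > 2 and np.std(r[ok]) > 0:
                assert np.corrcoef(r[ok], s[ok])[0, 1] == pytest.approx(1.0)

    def test_missing_sampling_events_stay_missing(self):
        long = self._long({"s1": [1.0, 2.0, 3.0, 4.0, 5.0]})
        long = long[long.time_index != 2]
        p = standardize_merge(long, ["f"], env_vars=())
        assert len(p) == 5
        assert np.isnan(p.values("f")[2])

    def test_from_arrays_single_site(self):
        p = StandardizedPanel.from_arrays({"x": np.arange(10.0)})
        assert p.segments == [(0, 10)]
        assert abs(p.values("x").mean()) < 1e-12
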
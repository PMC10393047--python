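"""Network assembly, strength tables, gamma-smooth temperature models."""
import numpy as np
import pandas as pd
import pytest

from edmnet.sensitivity import (
    build_network,
    fit_strength_model,
    species_temperature_effects,
    strength_table,
    to_graph,
)
from edmnet.uic import InteractionSet, TEResult


def _iset(te_values, alpha=0.05):
    results = [
        TEResult(cause=f"c{i}", effect=f"e{i}", conditionals=(), tp=-1, E=2,
                 te=te, p_value=0.01, n_boot=100, T=50)
        for i, te in enumerate(te_values)
    ]
    return InteractionSet(results=results, alpha=alpha)


def _is_frame(n_time=30, strength=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_time):
        rows.append({
            "target": "B", "cause": "A", "kind": "cause", "lag": 0,
            "site": "s1", "time_index": t,
            "temperature": 15 + 5 * np.sin(2 * np.pi * t / 24),
            "value": strength[t] if strength is not None else rng.normal(),
        })
    return pd.DataFrame(rows)


def _sample_panel(n_time=30):
    rows = []
    for t in range(n_time):
        for sp, c in [("A", 1.0), ("B", 2.0), ("C", 0.0)]:
            rows.append({"site": "s1", "time_index": t, "species": sp,
                         "copies": c,
                         "temperature": 15 + 5 * np.sin(2 * np.pi * t / 24)})
    return pd.DataFrame(rows)


class TestBuildNetwork:
    def test_eighty_percent_quantile_retains_top_two_of_ten(self):
        edges = build_network(_iset(np.arange(1, 11) / 10), quantile=0.8)
        assert edges["retained"].sum() == 2
        assert set(edges.loc[edges.retained, "te"]) == {0.9, 1.0}

    def test_quantile_zero_retains_all(self):
        edges = build_network(_iset(np.arange(1, 11) / 10), quantile=0.0)
        assert edges["retained"].all()

    def test_retained_set_shrinks_with_quantile(self):
        iset = _iset(np.linspace(0.1, 2.0, 25))
        sizes = [build_network(iset, quantile=q)["retained"].sum()
                 for q in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_no_clear_edges_raises(self):
        results = [TEResult("a", "b", (), 0, 1, 0.1, 0.9, 100, 50)]
        with pytest.raises(ValueError, match="clear"):
            build_network(InteractionSet(results=results))

    def test_graph_export(self):
        g = to_graph(build_network(_iset([0.5, 1.0])), node_copies={"c1": 7.0})
        assert g.number_of_edges() >= 1


class TestStrengthTable:
    def test_one_edge_yields_mirrored_rows(self):
        obs = strength_table(_is_frame(30), _sample_panel(30))
        assert (obs["direction"] == "in").sum() == 30
        assert (obs["direction"] == "out").sum() == 30
        ins = obs[obs.direction == "in"]
        outs = obs[obs.direction == "out"]
        assert set(ins["species"]) == {"B"} and set(outs["species"]) == {"A"}
        # conservation: every record appears exactly once per direction
        assert len(obs) == 2 * 30

    def test_richness_and_totals(self):
        obs = strength_table(_is_frame(10), _sample_panel(10))
        assert (obs["richness"] == 2).all()        # C has zero copies
        assert (obs["total_copies"] == 3.0).all()

    def test_strength_is_absolute_value(self):
        frame = _is_frame(20)
        obs = strength_table(frame, _sample_panel(20))
        ins = obs[obs.direction == "in"].sort_values("time_index")
        np.testing.assert_allclose(ins["strength"].to_numpy(),
                                   np.abs(frame["value"].to_numpy()))

    def test_intercept_and_self_records_excluded(self):
        frame = _is_frame(10)
        extra = frame.copy()
        extra["kind"] = "self"
        obs = strength_table(pd.concat([frame, extra]), _sample_panel(10))
        assert len(obs) == 20


def _gamma_obs(n=400, slope=0.1, seed=0, n_sites=2):
    """Directly simulated gamma strengths with log-mean linear in temperature."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        for t in range(n // n_sites):
            temp = 15 + 8 * rng.random()
            mu = np.exp(-1.0 + slope * temp)
            shape = 2.0
            rows.append({
                "species": rng.choice(["A", "B", "C"]), "direction": "in",
                "partner": "X", "site": f"s{s}", "time_index": t,
                "temperature": temp, "richness": 3, "total_copies": 1.0,
                "strength": rng.gamma(shape, mu / shape),
            })
    return pd.DataFrame(rows)


class TestFitStrengthModel:
    def test_recovers_increasing_temperature_effect(self):
        hits = 0
        for s in range(5):
            fit = fit_strength_model(_gamma_obs(seed=s), "temperature", "in",
                                     seed=s)
            hits += fit.clear and fit.sign_class == "increasing"
        assert hits >= 4

    def test_null_calibration(self):
        clear = 0
        n = 30
        for s in range(n):
            fit = fit_strength_model(_gamma_obs(slope=0.0, seed=s),
                                     "temperature", "in", seed=s)
            clear += fit.clear
        # binomial: P(X > 4 | n=30, p=0.05) < 2%
        assert clear <= 4

    def test_constant_predictor_refused(self):
        obs = _gamma_obs()
        obs["temperature"] = 20.0
        with pytest.raises(ValueError, match="constant"):
            fit_strength_model(obs, "temperature", "in")

    def test_too_few_observations_refused(self):
        with pytest.raises(ValueError, match="observations"):
            fit_strength_model(_gamma_obs(n=40), "temperature", "in")

    def test_zero_strengths_floored_and_counted(self):
        obs = _gamma_obs()
        obs.loc[obs.index[:7], "strength"] = 0.0
        fit = fit_strength_model(obs, "temperature", "in", seed=0)
        assert fit.n_floored == 7


class TestSpeciesEffects:
    def _per_species_obs(self, slopes, n_per=150, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sp, slope in slopes.items():
            for t in range(n_per):
                temp = 12 + 10 * rng.random()
                mu = np.exp(-1.0 + slope * temp)
                rows.append({
                    "species": sp, "direction": "in", "partner": "X",
                    "site": "s1", "time_index": t, "temperature": temp,
                    "richness": 2, "total_copies": 1.0,
                    "strength": rng.gamma(3.0, mu / 3.0),
                })
        return pd.DataFrame(rows)

    def test_sign_classification(self):
        obs = self._per_species_obs({"up": 0.15, "down": -0.15})
        eff = species_temperature_effects(obs, "in").set_index("species")
        assert eff.loc["up", "sign_class"] == "increasing"
        assert eff.loc["down", "sign_class"] == "decreasing"

    def test_highlight_threshold_degenerate(self):
        obs = self._per_species_obs({"up": 0.15, "down": -0.15, "flat": 0.0})
        eff = species_temperature_effects(obs, "in", alpha_highlight=1.0)
        ok = eff[eff.status == "ok"]
        assert ok["highlight"].all()

    def test_small_species_skipped_with_notice(self):
        obs = self._per_species_obs({"up": 0.15})
        rare = obs.head(5).assign(species="rare")
        eff = species_temperature_effects(pd.concat([obs, rare]), "in")
        eff = eff.set_index("species")
        assert eff.loc["rare", "status"] == "skipped"
        assert eff.loc["up", "status"] == "ok"
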
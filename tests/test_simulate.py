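"""Simulator: parameter construction, dynamics, Jacobian oracle, observation."""
import numpy as np
import pytest

from edmnet.simulate import (
    CommunityParams,
    ObservationModel,
    TemperatureForcing,
    jacobian_oracle,
    make_params,
    observe,
    simulate_abundance,
    simulate_dataset,
    simulate_temperature,
    standardize_temperature,
)


def _single_species(r, a, beta=0.0, noise=0.0):
    return CommunityParams(
        n_species=2,
        growth_rate=np.array([r, r]),
        interaction=np.diag([a, a]).astype(float),
        temp_modulation=np.zeros((2, 2)),
        temp_growth=np.array([beta, beta]),
        process_noise_sd=noise,
    )


class TestMakeParams:
    @pytest.mark.parametrize(
        "n, connectance, expected_links",
        [(2, 1.0, 2), (5, 0.0, 0), (10, 0.2, 18)],
    )
    def test_connectance_gives_exact_link_count(self, n, connectance, expected_links):
        params = make_params(n, connectance, seed=1)
        assert params.n_offdiag_links == expected_links
        assert np.all(np.diag(params.interaction) > 0)

    def test_gamma_only_on_links(self):
        params = make_params(6, 0.3, gamma_scale=0.5, seed=3)
        off = ~np.eye(6, dtype=bool)
        no_link = off & (params.interaction == 0)
        assert np.all(params.temp_modulation[no_link] == 0)

    def test_rejects_nonpositive_diagonal(self):
        with pytest.raises(ValueError, match="self-limitation"):
            CommunityParams(
                n_species=2, growth_rate=np.ones(2),
                interaction=np.array([[0.0, 0.1], [0.1, 1.0]]),
                temp_modulation=np.zeros((2, 2)), temp_growth=np.zeros(2),
            )


class TestTemperature:
    def test_constant_when_flat(self):
        f = TemperatureForcing(mean=15.0, amplitude=0.0, gradient=0.0, noise_sd=0.0)
        t = simulate_temperature(f, 2, 30, seed=0)
        assert np.allclose(t, 15.0)

    def test_sinusoid_range_is_twice_amplitude(self):
        f = TemperatureForcing(amplitude=5.0, period=24, gradient=0.0, noise_sd=0.0)
        t = simulate_temperature(f, 1, 48, seed=0)
        assert t.max() - t.min() == pytest.approx(10.0)

    def test_site_mean_span_equals_gradient(self):
        f = TemperatureForcing(amplitude=3.0, gradient=4.0, noise_sd=0.0)
        t = simulate_temperature(f, 11, 48, seed=0)
        means = t.mean(axis=1)
        assert means.max() - means.min() == pytest.approx(4.0)
        assert np.all(np.diff(means) > 0)


class TestAbundance:
    def test_ricker_fixed_point(self):
        # a_ii = r_i and x0 = 1 puts the map exactly at its equilibrium
        params = _single_species(r=1.5, a=1.5)
        temp = np.full((1, 20), 18.0)
        # force x0 = 1 by running the deterministic map from the equilibrium
        lat = simulate_abundance(params, temp, 20, seed=0, burn_in=200)
        assert np.allclose(lat, 1.0, atol=1e-6)

    def test_decoupled_equals_single_species_runs(self):
        params = make_params(3, 0.0, seed=5, process_noise_sd=0.1)
        f = TemperatureForcing(noise_sd=0.3)
        temp = simulate_temperature(f, 2, 40, seed=6)
        full = simulate_abundance(params, temp, 40, seed=7)
        for i in range(3):
            sub = CommunityParams(
                n_species=2,
                growth_rate=params.growth_rate[[i, i]],
                interaction=np.diag(np.diag(params.interaction)[[i, i]]),
                temp_modulation=np.zeros((2, 2)),
                temp_growth=params.temp_growth[[i, i]],
                process_noise_sd=params.process_noise_sd,
            )
            solo = simulate_abundance(
                sub, temp, 40, seed=7, species_ids=np.array([i, 99])
            )
            np.testing.assert_array_equal(full[:, :, i], solo[:, :, 0])

    def test_chaotic_ricker_has_no_short_period(self):
        params = _single_species(r=2.9, a=2.9)
        temp = np.full((1, 500), 18.0)
        lat = simulate_abundance(params, temp, 500, seed=0)[0, :, 0]
        for p in range(1, 9):
            assert np.max(np.abs(lat[p:] - lat[:-p])) > 1e-3

    def test_determinism(self):
        params = make_params(4, 0.2, seed=9, process_noise_sd=0.1)
        temp = simulate_temperature(TemperatureForcing(), 2, 30, seed=1)
        a = simulate_abundance(params, temp, 30, seed=2)
        b = simulate_abundance(params, temp, 30, seed=2)
        np.testing.assert_array_equal(a, b)


class TestJacobian:
    def test_zero_coupling_offdiagonal_zero(self):
        params = make_params(4, 0.0, seed=0)
        jac = jacobian_oracle(params, np.ones(4), 0.3)
        off = ~np.eye(4, dtype=bool)
        assert np.all(jac[off] == 0)

    def test_fixed_point_derivative_is_one_minus_r(self):
        params = _single_species(r=1.8, a=1.8)
        jac = jacobian_oracle(params, np.ones(2), 0.0)
        assert jac[0, 0] == pytest.approx(1 - 1.8)

    def test_matches_central_finite_differences(self):
        params = make_params(3, 0.4, gamma_scale=0.5, seed=11)
        temp = simulate_temperature(TemperatureForcing(), 1, 60, seed=3)
        lat = simulate_abundance(params, temp, 60, seed=4)
        tstd = standardize_temperature(temp)

        def step(x, tt):
            a_eff = params.interaction * (1 + params.temp_modulation * tt)
            return x * np.exp(
                params.growth_rate + params.temp_growth * tt - a_eff @ x
            )

        h = 1e-6
        for t in [10, 30, 50]:
            x = lat[0, t]
            tt = tstd[0, t]
            jac = jacobian_oracle(params, x, tt)
            for j in range(3):
                dx = np.zeros(3)
                dx[j] = h * max(x[j], 1.0)
                fd = (step(x + dx, tt) - step(x - dx, tt)) / (2 * dx[j])
                np.testing.assert_allclose(jac[:, j], fd, rtol=1e-5, atol=1e-8)


class TestObserve:
    def test_equal_abundance_splits_reads_evenly(self):
        ab = np.ones((1, 1, 2))
        obs = ObservationModel(sequencing_depth=1_000_000, qpcr_cv=0.0)
        df = observe(ab, obs, seed=0)
        reads = df["reads"].to_numpy()
        # binomial 99% CI around 500,000 at p = 1/2
        assert abs(reads[0] - 500_000) < 2.58 * np.sqrt(1e6 * 0.25)
        assert reads.sum() == 1_000_000

    def test_below_floor_yields_zero_reads(self):
        ab = np.array([[[1.0, 1e-7]]])
        obs = ObservationModel(sequencing_depth=1000, detection_floor=1e-4)
        df = observe(ab, obs, seed=0)
        assert df.loc[df["species"] == "sp01", "reads"].item() == 0

    def test_read_proportions_converge_to_abundance(self, rng):
        ab = rng.uniform(0.5, 2.0, size=(1, 1, 10))
        obs = ObservationModel(sequencing_depth=1_000_000, qpcr_cv=0.0)
        df = observe(ab, obs, seed=1)
        props = df["reads"].to_numpy() / 1_000_000
        truth = ab[0, 0] / ab[0, 0].sum()
        assert np.max(np.abs(props - truth)) < 0.01

    def test_spike_detection_floor_enforced(self):
        ab = np.full((1, 10, 2), 1e-9)
        obs = ObservationModel(detection_floor=1e-4, spike_species=0)
        with pytest.raises(ValueError, match="internal standard"):
            observe(ab, obs, seed=0)


def test_dataset_determinism_and_shape():
    df1, truth1 = simulate_dataset(n_species=6, n_sites=2, n_steps=20, seed=3)
    df2, _ = simulate_dataset(n_species=6, n_sites=2, n_steps=20, seed=3)
    assert df1.equals(df2)
    assert len(df1) == 2 * 20 * 6
    assert set(df1.columns) >= {
        "site", "time_index", "date", "species", "reads",
        "spike_copies_per_uL", "temperature", "salinity", "wave", "tide",
    }
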
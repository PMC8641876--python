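"""Reaction channels, tau-leaping, noise ensembles and cell classification."""

import numpy as np
import pytest

import yaptaz as yz
from yaptaz.stochastic import (
    STATE_LABELS,
    ReactionChannel,
    StochasticConfig,
    build_channels,
    classify_cell,
    lhs_parameter_ensemble,
    tau_leap,
)


@pytest.fixture(scope="module")
def channels(std):
    return build_channels(std)


@pytest.fixture(scope="module")
def x0_counts(std):
    return np.round(np.asarray(yz.homeostatic_state(std)) * 100.0)


class TestChannels:
    def test_deterministic_limit_identity(self, std, channels, rng):
        """Sum of stoichiometry x propensity / omega equals the ODE right-hand side."""
        stoich = np.array([c.stoichiometry for c in channels])
        for _ in range(100):
            x = rng.uniform(0.0, 3.0, 5)
            props = np.array([c.propensity(x, std, 100.0) for c in channels])
            assert np.all(props >= 0)
            drift = stoich.T @ props / 100.0
            assert np.allclose(drift, yz.full_rhs(x, std), atol=1e-12)

    def test_basal_production_channel_is_state_independent(self, std, channels, rng):
        basal = next(c for c in channels if c.label == "L_basal_production")
        vals = [float(basal.propensity(rng.uniform(0, 2, 5), std, 100.0)) for _ in range(5)]
        assert vals == [pytest.approx(100.0 * std.kL1)] * 5

    def test_dephosphorylation_vanishes_without_ytp(self, std, channels):
        dephos = next(c for c in channels if c.label == "YTp_dephosphorylation")
        x = np.array([0.5, 0.5, 0.0, 0.5, 0.5])
        assert dephos.propensity(x, std, 100.0) == 0.0

    def test_phospho_channels_conserve_yap_taz_pool(self, channels):
        for c in channels:
            if "phospho" in c.label:
                assert c.stoichiometry[1] + c.stoichiometry[2] == 0


class TestTauLeap:
    def test_zero_propensities_freeze_the_state(self, std, x0_counts):
        frozen = [
            ReactionChannel(c.label, c.stoichiometry, lambda x, p, w: np.zeros(np.shape(x[..., 0])))
            for c in build_channels(std)
        ]
        cfg = StochasticConfig(t_end=5.0, seed=3, n_cells=1)
        traj = tau_leap(x0_counts, frozen, std, cfg)
        assert np.all(traj.states == x0_counts)

    def test_seed_reproducibility(self, std, channels, x0_counts):
        cfg = StochasticConfig(t_end=10.0, seed=11, n_cells=1)
        a = tau_leap(x0_counts, channels, std, cfg)
        b = tau_leap(x0_counts, channels, std, cfg)
        assert np.array_equal(a.states, b.states)

    def test_counts_stay_nonnegative(self, std, channels):
        cfg = StochasticConfig(omega=10.0, tau=0.05, t_end=20.0, seed=5)
        traj = tau_leap(np.array([1, 1, 0, 1, 1]), channels, std, cfg)
        assert np.all(traj.states >= 0)

    def test_birth_death_toy_matches_exact_ssa(self, rng):
        """Tau-leap mean/variance of a birth-death process vs exact simulation.

        Exact SSA (Gillespie direct method, test-only oracle) on dX/dt =
        lam - mu*X started at 0; at stationarity X ~ Poisson(lam/mu).
        """
        lam, mu, t_end = 20.0, 0.5, 30.0
        n = 2000

        def ssa(seed):
            r = np.random.default_rng(seed)
            t, x = 0.0, 0
            while True:
                a0 = lam + mu * x
                t += r.exponential(1 / a0)
                if t > t_end:
                    return x
                x += 1 if r.uniform() < lam / a0 else -1

        exact = np.array([ssa(s) for s in range(n)])
        r = np.random.default_rng(1)
        x = np.zeros(n)
        tau = 0.02
        for _ in range(int(t_end / tau)):
            x += r.poisson(lam * tau, n) - r.poisson(mu * x * tau)
            x = np.maximum(x, 0)
        # Poisson(40): sd of the mean over 2000 draws ~ 0.14
        assert abs(x.mean() - exact.mean()) < 0.6
        assert abs(x.var() - exact.var()) / exact.var() < 0.15

    def test_invalid_initial_rejected(self, std, channels):
        cfg = StochasticConfig(t_end=1.0)
        with pytest.raises(ValueError):
            tau_leap(np.array([1.5, 0, 0, 0, 0]), channels, std, cfg)


class TestLhsEnsemble:
    def test_one_value_per_stratum(self, std):
        n = 40
        ens = lhs_parameter_ensemble(std, fraction=0.05, n_cells=n, seed=2)
        for name in ("kL2", "JN", "n"):
            base = getattr(std, name)
            u = np.sort([(getattr(e, name) / base - 0.95) / 0.10 for e in ens])
            # exactly one sample in each of the n equal strata of [0, 1]
            assert np.all(np.floor(u * n) == np.arange(n))

    def test_zero_fraction_returns_standard_set(self, std):
        ens = lhs_parameter_ensemble(std, fraction=0.0, n_cells=5, seed=4)
        assert all(e == std for e in ens)

    def test_mean_close_to_standard(self, std):
        ens = lhs_parameter_ensemble(std, fraction=0.05, n_cells=1000, seed=8)
        m = np.mean([e.kYTup3 for e in ens])
        assert abs(m / std.kYTup3 - 1) < 0.005

    def test_seed_purity(self, std):
        a = lhs_parameter_ensemble(std, 0.05, 10, seed=9)
        b = lhs_parameter_ensemble(std, 0.05, 10, seed=9)
        assert a == b


class TestClassifier:
    def test_monostable_regimes_label_unconditionally(self, std_diagram):
        for y in (0.05, 0.7, 2.5):
            assert classify_cell([0.2, y, 0.1, 0.5, 0.5], std_diagram, 0.007) == "homeostatic"
        assert classify_cell([0.2, 2.0, 0.1, 0.5, 0.5], std_diagram, 0.001) == "degenerative"
        assert classify_cell([0.2, 0.1, 0.1, 0.5, 0.5], std_diagram, 0.025) == "tumorigenic"

    def test_stable_branch_values_get_their_own_label(self, std_diagram, std_sns):
        k = 0.5 * (std_sns.SN1 + std_sns.SN2)
        for b in std_diagram.stable_branches_at(k):
            y = b.y_at(k)
            assert classify_cell([0.2, y, 0.1, 0.5, 0.5], std_diagram, k) == b.label

    def test_recovers_all_labels_on_separated_mixture(self, std_diagram, std_sns):
        k = 0.5 * (std_sns.SN4 + std_sns.SN3)
        branches = sorted(std_diagram.stable_branches_at(k), key=lambda b: b.y_at(k))
        fix = yz.make_population_fixture(
            branch_values=tuple(b.y_at(k) for b in branches),
            spreads=(0.02, 0.02),
            weights=(0.5, 0.5),
            n=200,
            seed=6,
        )
        label_map = dict(zip(("degenerative", "homeostatic"), (b.label for b in branches)))
        hits = sum(
            classify_cell([0.2, v, 0.1, 0.5, 0.5], std_diagram, k) == label_map[l]
            for v, l in zip(fix.values, fix.labels)
        )
        assert hits == len(fix.values)


class TestPopulationExperiment:
    def test_snapshot_contract_and_reproducibility(self, std, std_diagram):
        cfg = StochasticConfig(omega=100, tau=0.02, t_end=20.0, seed=17, n_cells=8)
        a = yz.population_experiment(std, cfg, k_values=(0.007,), diagram=std_diagram)[0]
        b = yz.population_experiment(std, cfg, k_values=(0.007,), diagram=std_diagram)[0]
        assert np.array_equal(a.counts, b.counts)
        assert a.labels == b.labels
        assert a.counts.dtype.kind == "i"
        assert np.all(a.counts >= 0)
        assert set(a.labels) <= set(STATE_LABELS)

    def test_extrinsic_noise_assigns_distinct_cell_parameters(self, std, std_diagram):
        cfg = StochasticConfig(omega=100, tau=0.02, t_end=10.0, seed=23, n_cells=6,
                               extrinsic_fraction=0.05)
        snap = yz.population_experiment(std, cfg, k_values=(0.007,), diagram=std_diagram)[0]
        assert snap.cell_params is not None
        assert len({p.kL2 for p in snap.cell_params}) == 6
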
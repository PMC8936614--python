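import numpy as np
import pytest

from actisense._utils import apply_lag_kernel
from actisense.dataset import EEGTrace
from actisense.pid_interactions import (PredictionTriplet, channelwise_pid,
                                        co_information, copula_normalize,
                                        gaussian_mi, permutation_test, pid_ccs,
                                        pid_mmi)
from actisense.trf_decoding import (LagSpec, to_forward_model, train_decoder)
from tests.test_trf_decoding import FakeTrial


class TestCopulaNormalize:
    def test_gaussian_input_nearly_unchanged(self, rng):
        x = rng.standard_normal(10_000)
        z = copula_normalize(x)
        assert np.corrcoef(x, z)[0, 1] > 0.99

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(500)
        assert np.allclose(copula_normalize(x), copula_normalize(np.exp(x)))

    def test_output_moments(self, rng):
        z = copula_normalize(rng.exponential(size=10_000))
        assert abs(z.mean()) < 0.02
        assert abs(z.var() - 1.0) < 0.05

    def test_rank_preserved(self, rng):
        x = rng.random(1000)
        z = copula_normalize(x)
        assert np.array_equal(np.argsort(x), np.argsort(z))

    def test_massive_ties_warn(self):
        x = np.concatenate([np.zeros(80), np.arange(20.0)])
        with pytest.warns(UserWarning, match="tied"):
            copula_normalize(x)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            copula_normalize(np.arange(5.0))


class TestGaussianMI:
    def test_independent_near_zero(self, rng):
        assert gaussian_mi(rng.standard_normal(100_000),
                           rng.standard_normal(100_000)) < 0.01

    @pytest.mark.parametrize("rho", [0.3, 0.5, 0.8])
    def test_closed_form(self, rho, rng):
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=100_000)
        expected = -0.5 * np.log2(1 - rho ** 2)
        assert gaussian_mi(z[:, 0], z[:, 1]) == pytest.approx(expected, abs=0.01)

    def test_exact_copy_is_singular(self, rng):
        x = rng.standard_normal(1000)
        with pytest.raises(np.linalg.LinAlgError):
            gaussian_mi(x, x)

    def test_pair_argument(self, rng):
        x = rng.standard_normal(50_000)
        pair = np.column_stack([x + rng.standard_normal(50_000),
                                rng.standard_normal(50_000)])
        mi = gaussian_mi(x, pair)
        assert mi > 0.3  # first component is informative


class TestCoInformation:
    def test_irrelevant_third_variable(self, rng):
        V = rng.standard_normal(100_000)
        T = V + rng.standard_normal(100_000)
        H = rng.standard_normal(100_000)
        assert co_information((T, V, H)) == pytest.approx(0.0, abs=0.01)

    def test_additive_target_net_synergy(self, rng):
        # T = V + H + eps: I(T;V) = 0.5*log2(3/2), I(T;[V,H]) = 0.5*log2(3)
        # -> co-information = 2*0.29248 - 0.79248 = -0.20752 bits
        V, H, e = rng.standard_normal((3, 100_000))
        T = V + H + e
        assert co_information((T, V, H)) == pytest.approx(-0.20752, abs=0.01)

    def test_shared_copy_pure_redundancy(self, rng):
        V = rng.standard_normal(100_000)
        T = V + 0.5 * rng.standard_normal(100_000)
        H = V + 1e-4 * rng.standard_normal(100_000)
        ci = co_information((T, V, H))
        assert ci == pytest.approx(gaussian_mi(T, V), abs=0.02)


class TestPIDCCS:
    def test_single_relevant_predictor(self, rng):
        V = rng.standard_normal(100_000)
        H = rng.standard_normal(100_000)
        T = V + 0.8 * rng.standard_normal(100_000)
        atoms = pid_ccs((T, V, H))
        assert atoms.unique_v == pytest.approx(atoms.mi_v, abs=0.02)
        assert abs(atoms.redundancy) < 0.02
        assert abs(atoms.unique_h) < 0.02
        assert abs(atoms.synergy) < 0.02

    def test_duplicated_predictor_symmetry(self, rng):
        V = rng.standard_normal(100_000)
        T = V + 0.8 * rng.standard_normal(100_000)
        H = V + 1e-5 * rng.standard_normal(100_000)
        atoms = pid_ccs((T, V, H))
        assert atoms.redundancy == pytest.approx(atoms.mi_v, abs=0.02)
        assert abs(atoms.unique_v) < 0.02 and abs(atoms.unique_h) < 0.02
        assert abs(atoms.synergy) < 0.02

    def test_lattice_identities_exact(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            cov = r.standard_normal((3, 3))
            cov = cov @ cov.T + np.eye(3)
            z = r.multivariate_normal(np.zeros(3), cov, size=2000)
            atoms = pid_ccs((z[:, 0], z[:, 1], z[:, 2]))
            assert (atoms.redundancy + atoms.unique_v
                    == pytest.approx(atoms.mi_v, abs=1e-9))
            assert (atoms.redundancy + atoms.unique_h
                    == pytest.approx(atoms.mi_h, abs=1e-9))
            assert (atoms.redundancy + atoms.unique_v + atoms.unique_h
                    + atoms.synergy == pytest.approx(atoms.mi_joint, abs=1e-9))

    def test_negatively_correlated_sources_synergy(self, rng):
        # V, H strongly anticorrelated; T their sum: joint observation is far
        # more informative than either alone
        cov = np.array([[1.0, -0.9], [-0.9, 1.0]])
        vh = rng.multivariate_normal([0, 0], cov, size=100_000)
        T = vh.sum(axis=1) + 0.1 * rng.standard_normal(100_000)
        atoms = pid_ccs((T, vh[:, 0], vh[:, 1]))
        assert atoms.synergy > 0.5
        assert atoms.synergy > atoms.redundancy

    def test_monotone_transform_invariance(self, rng):
        V = rng.standard_normal(20_000)
        H = rng.standard_normal(20_000)
        T = V - H + 0.5 * rng.standard_normal(20_000)
        a = pid_ccs((T, V, H))
        b = pid_ccs((np.exp(T), V ** 3, H))
        assert a.redundancy == pytest.approx(b.redundancy, abs=1e-6)
        assert a.synergy == pytest.approx(b.synergy, abs=1e-6)

    def test_mmi_fallback_lattice(self, rng):
        V, H, e = rng.standard_normal((3, 20_000))
        T = V + H + e
        atoms = pid_mmi((T, V, H))
        assert atoms.redundancy == pytest.approx(min(atoms.mi_v, atoms.mi_h))
        assert (atoms.redundancy + atoms.unique_v + atoms.unique_h
                + atoms.synergy == pytest.approx(atoms.mi_joint, abs=1e-12))


def _pid_dataset(rng, n_trials=15, n_samples=220, fs=100.0):
    """VH trials plus V/H models with engineered per-channel structure.

    channel 0: unique-V (H kernel zero there, VH kernel = V kernel)
    channel 1: redundant (V, H and VH kernels identical)
    channel 2: synergy (V and H kernels anticorrelated; VH = their sum)
    channel 3: noise (no kernel anywhere)
    """
    lags = np.arange(-2, 6)
    h1 = np.exp(-0.5 * ((np.arange(8) - 3) / 1.2) ** 2)
    h2 = np.roll(h1, 2) * np.array([1, 1, 1, -1, -1, 1, 1, 1])
    pat_v = np.zeros((4, 8))
    pat_h = np.zeros((4, 8))
    pat_vh = np.zeros((4, 8))
    pat_v[0] = h1
    pat_vh[0] = h1                      # unique-V channel
    pat_v[1] = h1
    pat_h[1] = h1
    pat_vh[1] = h1                      # redundant channel
    pat_v[2] = h1
    pat_h[2] = -0.85 * h1 + 0.5 * h2
    pat_vh[2] = pat_v[2] + pat_h[2]     # synergy channel
    labels = ["uniq_v", "red", "syn", "noise"]

    def make_trials(pattern, n, snr=6.0):
        trials = []
        for k in range(n):
            v = np.convolve(rng.standard_normal(n_samples), np.ones(3) / 3, "same")
            sig = apply_lag_kernel(v, pattern, lags)
            sd = np.sqrt(np.maximum(sig.var(axis=0), 1e-3) / snr)
            data = sig + rng.standard_normal(sig.shape) * sd
            trials.append(FakeTrial(eeg=EEGTrace(data=data, fs=fs, labels=labels),
                                    velocity=v, trial=k))
        return trials

    return (make_trials(pat_v, 10), make_trials(pat_h, 10),
            make_trials(pat_vh, n_trials), LagSpec(fs=fs, lag_min_ms=-20.0,
                                                   lag_max_ms=50.0))


@pytest.fixture(scope="module")
def pid_run():
    rng = np.random.default_rng(404)
    v_tr, h_tr, vh_tr, spec = _pid_dataset(rng)
    v_model = to_forward_model(train_decoder(v_tr, spec, 4.0), v_tr)
    h_model = to_forward_model(train_decoder(h_tr, spec, 4.0), h_tr)
    triplets, atoms, context = channelwise_pid(vh_tr, v_model, h_model,
                                               spec, lam=4.0, seed=5,
                                               return_context=True)
    return triplets, atoms, context


class TestChannelwisePID:

    def test_unique_v_channel(self, pid_run):
        _, atoms, _ = pid_run
        row = atoms.set_index("channel").loc["uniq_v"]
        assert row["unique_v"] > row["unique_h"]
        assert row["unique_v"] > row["synergy"]

    def test_redundant_channel(self, pid_run):
        _, atoms, _ = pid_run
        row = atoms.set_index("channel").loc["red"]
        assert row["redundancy"] > row["unique_v"]
        assert row["redundancy"] > row["unique_h"]
        assert row["redundancy"] > row["synergy"]

    def test_synergy_channel(self, pid_run):
        _, atoms, _ = pid_run
        row = atoms.set_index("channel").loc["syn"]
        assert row["synergy"] > 0.1
        assert row["synergy"] > row["redundancy"]

    def test_missing_models_error(self, pid_run):
        with pytest.raises(ValueError, match="missing"):
            channelwise_pid([], None, None, LagSpec(fs=100.0))

    def test_permutation_positive_control(self, pid_run):
        # calibrated (refit) null: engineered synergy survives, noise does not
        triplets, atoms, context = pid_run
        # BH at q=0.01 over 4 channels needs p < 0.0025: 500 permutations
        res = permutation_test(triplets, observed=atoms, n_perm=500, seed=6,
                               context=context)
        tab = res.table.set_index("channel")
        assert bool(tab.loc["syn", "significant_synergy"])
        assert not bool(tab.loc["noise", "significant_synergy"])
        assert not bool(tab.loc["noise", "significant_redundancy"])

    def test_shuffle_null_flags_coupled_channels(self, pid_run):
        # the literal shuffled-target null detects any velocity coupling
        triplets, atoms, _ = pid_run
        res = permutation_test(triplets, observed=atoms, n_perm=100, seed=7)
        tab = res.table.set_index("channel")
        assert bool(tab.loc["syn", "above_pct_synergy"])
        assert bool(tab.loc["red", "above_pct_redundancy"])

    def test_permutation_determinism(self, pid_run):
        triplets, atoms, _ = pid_run
        a = permutation_test(triplets[:1], observed=atoms, n_perm=100, seed=8)
        b = permutation_test(triplets[:1], observed=atoms, n_perm=100, seed=8)
        assert a.table.equals(b.table)

    def test_triplet_validation(self):
        with pytest.raises(ValueError, match="equal lengths"):
            PredictionTriplet(channel="x",
                              segments=[(np.zeros(120), np.zeros(119),
                                         np.zeros(120))])
        with pytest.raises(ValueError, match="100 samples"):
            PredictionTriplet(channel="x",
                              segments=[(np.zeros(50), np.zeros(50),
                                         np.zeros(50))])
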
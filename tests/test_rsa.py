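import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facesim.rsa import (
    PermutationScheme,
    _rho_maps,
    fisher_z,
    group_t_map,
    make_tf_smoother,
    partial_spearman,
    pattern_cells_over_tf,
    pattern_cells_over_time,
    permutation_correct,
    rsa_scan,
    smooth_tf_map,
    smooth_timecourse,
    spearman_rsa,
    tfce,
)
from facesim.similarity import category_model_matrix


from oracles import pearson_oracle, rank_oracle, spearman_oracle, tfce_oracle

# ---------------------------------------------------------------------------


class TestSpearman:
    def test_self_is_one(self, rng):
        x = rng.normal(0, 1, 20)
        assert spearman_rsa(x, x) == pytest.approx(1.0)

    def test_monotone_transform_is_one(self, rng):
        x = rng.normal(0, 1, 20)
        assert spearman_rsa(x, np.exp(x)) == pytest.approx(1.0)

    def test_matches_oracle_with_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, 10).astype(float)  # heavy ties
            y = rng.normal(0, 1, 10)
            if np.ptp(x) == 0:
                continue
            assert spearman_rsa(x, y) == pytest.approx(
                spearman_oracle(x, y), abs=1e-12
            )

    def test_matches_scipy(self, rng):
        from scipy.stats import spearmanr

        x, y = rng.normal(0, 1, (2, 50))
        assert spearman_rsa(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rsa(np.ones(5), np.arange(5.0))

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_strict_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(0, 1, (2, 15))
        base = spearman_rsa(x, y)
        assert spearman_rsa(x**3, y) == pytest.approx(base, abs=1e-12)
        assert spearman_rsa(x, 2 * y + 5) == pytest.approx(base, abs=1e-12)


class TestPartialSpearman:
    def test_empty_controls_equals_spearman(self, rng):
        x, y = rng.normal(0, 1, (2, 30))
        assert partial_spearman(x, y) == spearman_rsa(x, y)

    def test_orthogonal_control_changes_nothing(self):
        # ranks of control orthogonal (after centering) to both inputs
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 3.0, 2.0, 4.0])
        c = np.array([1.0, 2.0, 2.0, 1.0])  # rank-centered orthogonal to both
        assert partial_spearman(a, b, [c]) == pytest.approx(
            spearman_rsa(a, b), abs=1e-12
        )

    def test_shared_cause_removed(self, rng):
        c = rng.normal(0, 1, 400)
        a = c + rng.normal(0, 0.3, 400)
        b = c + rng.normal(0, 0.3, 400)
        assert spearman_rsa(a, b) > 0.7
        assert abs(partial_spearman(a, b, [c])) < 0.2

    def test_matches_closed_form_single_control(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(0, 1, (3, 25))
            r_ab = spearman_rsa(a, b)
            r_ac = spearman_rsa(a, c)
            r_bc = spearman_rsa(b, c)
            expected = (r_ab - r_ac * r_bc) / np.sqrt(
                (1 - r_ac**2) * (1 - r_bc**2)
            )
            assert partial_spearman(a, b, [c]) == pytest.approx(expected, abs=1e-12)

    def test_matches_lstsq_residual_oracle_two_controls(self, rng):
        a, b, c1, c2 = rng.normal(0, 1, (4, 40))
        ra, rb = rank_oracle(a), rank_oracle(b)
        design = np.column_stack([np.ones(40), rank_oracle(c1), rank_oracle(c2)])
        res_a = ra - design @ np.linalg.lstsq(design, ra, rcond=None)[0]
        res_b = rb - design @ np.linalg.lstsq(design, rb, rcond=None)[0]
        expected = pearson_oracle(res_a, res_b)
        assert partial_spearman(a, b, [c1, c2]) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        a, b, c = rng.normal(0, 1, (3, 30))
        table = pd.DataFrame({"a": a, "b": b, "c": c})
        expected = pingouin.partial_corr(
            table, x="a", y="b", covar="c", method="spearman"
        )["r"].iloc[0]
        assert partial_spearman(a, b, [c]) == pytest.approx(expected, abs=1e-9)

    def test_collinear_control_raises(self):
        a = np.arange(10.0)
        b = np.array([3.0, 1, 4, 1, 5, 9, 2, 6, 5, 3])
        with pytest.raises(ValueError, match="collinear"):
            partial_spearman(a, b, [a])


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_matches_log_formula(self):
        # independent evaluation: z = 0.5 * log((1+r)/(1-r))
        expected = 0.5 * np.log(1.5 / 0.5)
        assert fisher_z(0.5) == pytest.approx(expected, abs=1e-15)

    def test_odd_symmetry(self, rng):
        for r in rng.uniform(-0.99, 0.99, 10):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-15)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5, np.nan])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            fisher_z(bad)


class TestSmoothing:
    def test_butterworth_constant_unchanged(self):
        maps = np.full((3, 200), 2.5)
        out = smooth_timecourse(maps, sfreq=100.0)
        np.testing.assert_allclose(out, 2.5, atol=1e-9)

    def test_butterworth_attenuates_high_frequency(self):
        t = np.arange(500) / 100.0
        x = np.sin(2 * np.pi * 30.0 * t)[None]  # 30 Hz, well above 10 Hz cutoff
        out = smooth_timecourse(x, sfreq=100.0, cutoff=10.0)
        assert np.abs(out[:, 50:-50]).max() < 0.01

    def test_butterworth_reduces_noise_variance(self, rng):
        x = rng.normal(0, 1, (5, 500))
        out = smooth_timecourse(x, sfreq=100.0, cutoff=10.0)
        # 10 Hz low-pass on white noise keeps roughly 1/5 of the band
        ratio = out.var() / x.var()
        assert 0.05 < ratio < 0.45

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            smooth_timecourse(np.zeros((1, 100)), sfreq=100.0, cutoff=50.0)

    def test_gaussian_constant_unchanged(self):
        maps = np.full((4, 30), 1.3)
        out = smooth_tf_map(maps, freq_step=2.0, time_step_ms=10.0)
        np.testing.assert_allclose(out, 1.3, atol=1e-12)

    def test_gaussian_impulse_matches_kernel_formula(self):
        maps = np.zeros((81, 81))
        maps[40, 40] = 1.0
        fwhm_f, fwhm_t = 4.0, 6.0
        out = smooth_tf_map(maps, 1.0, 1.0, fwhm_freq=fwhm_f, fwhm_time_ms=fwhm_t)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)  # mass-preserving
        # independent kernel formula: sigma = FWHM / (2 sqrt(2 ln 2)),
        # separable product of the two 1-D kernels
        k = 2 * np.sqrt(2 * np.log(2))
        offsets = np.arange(-40, 41)

        def kernel(fwhm):
            sigma = fwhm / k
            weights = np.exp(-(offsets**2) / (2 * sigma**2))
            return weights / weights.sum()

        expected = np.outer(kernel(fwhm_f), kernel(fwhm_t))
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_gaussian_separability(self, rng):
        maps = rng.normal(0, 1, (20, 30))
        both = smooth_tf_map(maps, 2.0, 10.0)
        freq_only = smooth_tf_map(maps, 2.0, 10.0, fwhm_time_ms=1e-9)
        then_time = smooth_tf_map(freq_only, 2.0, 10.0, fwhm_freq=1e-9)
        np.testing.assert_allclose(both, then_time, atol=1e-9)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_tf_map(np.zeros((3, 3)), 1.0, 1.0, fwhm_freq=0.0)


class TestGroupT:
    def test_all_zero_maps(self):
        t = group_t_map(np.zeros((5, 10)))
        np.testing.assert_array_equal(t, 0.0)

    def test_identical_positive_maps_give_inf(self):
        t = group_t_map(np.full((4, 3), 2.0))
        assert np.all(np.isposinf(t))

    def test_matches_scipy_oracle(self, rng):
        from scipy.stats import ttest_1samp

        maps = rng.normal(0.2, 1.0, (12, 40))
        t = group_t_map(maps)
        expected = ttest_1samp(maps, 0.0, axis=0).statistic
        np.testing.assert_allclose(t, expected, atol=1e-12)


class TestTFCE:
    def test_zero_map(self):
        np.testing.assert_array_equal(tfce(np.zeros(10)), 0.0)

    def test_negative_values_contribute_nothing(self):
        out = tfce(np.array([-5.0, -1.0, 0.0]))
        np.testing.assert_array_equal(out, 0.0)

    def test_monotonicity(self, rng):
        base = rng.uniform(0, 2, 30)
        bigger = base + rng.uniform(0, 1, 30)
        dh = bigger.max() / 100
        out_base = tfce(base, dh=dh)
        out_big = tfce(bigger, dh=dh)
        assert np.all(out_big >= out_base - 1e-12)

    @pytest.mark.parametrize("shape", [(25,), (6, 8)])
    def test_matches_bruteforce_oracle(self, shape, rng):
        stat_map = rng.uniform(-0.5, 1.0, shape)
        out = tfce(stat_map, 0.5, 2.0, dh=0.01)
        expected = tfce_oracle(stat_map, 0.5, 2.0, 0.01)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_two_blobs_larger_extent_wins(self):
        stat_map = np.zeros(50)
        stat_map[5:10] = 1.0  # extent 5
        stat_map[20:40] = 1.0  # extent 20
        out = tfce(stat_map, dh=0.01)
        assert out[25] > out[7]


class TestPermutationCorrect:
    def test_fixed_seed_deterministic(self, rng):
        z = rng.normal(0.1, 1.0, (8, 30))
        scheme = PermutationScheme(n_permutations=50, seed=42)
        a = permutation_correct(z, scheme)
        b = permutation_correct(z, scheme)
        np.testing.assert_array_equal(a[2], b[2])

    def test_planted_effect_detected(self, rng):
        z = rng.normal(0.0, 0.3, (16, 60))
        z[:, 20:35] += 1.5
        scheme = PermutationScheme(n_permutations=300, seed=0)
        t, enhanced, p, mask = permutation_correct(z, scheme, alpha=0.05)
        assert mask[20:35].all()
        assert p[25] <= 0.05

    def test_no_positive_signal_returns_p_one(self):
        z = -np.ones((4, 10))
        t, enhanced, p, mask = permutation_correct(z, PermutationScheme(10, 0))
        np.testing.assert_array_equal(p, 1.0)
        assert not mask.any()

    def test_exhaustive_enumeration_warns(self, rng):
        z = rng.normal(0.5, 1.0, (4, 10))
        with pytest.warns(UserWarning, match="exhaustively"):
            permutation_correct(z, PermutationScheme(n_permutations=100, seed=0))


class TestVectorizedRhoMaps:
    def test_matches_scalar_spearman(self, rng):
        cells = rng.normal(0, 1, (3, 5, 28))
        model = rng.normal(0, 1, 28)
        rho = _rho_maps(cells, model, [])
        for p in range(3):
            for c in range(5):
                assert rho[p, c] == pytest.approx(
                    spearman_rsa(cells[p, c], model), abs=1e-12
                )

    def test_matches_scalar_partial(self, rng):
        cells = rng.normal(0, 1, (2, 4, 28))
        model = rng.normal(0, 1, 28)
        control = rng.normal(0, 1, 28)
        rho = _rho_maps(cells, model, [control])
        for p in range(2):
            for c in range(4):
                assert rho[p, c] == pytest.approx(
                    partial_spearman(cells[p, c], model, [control]), abs=1e-12
                )


class TestPatternCells:
    def test_over_time_matches_matrix_op(self, rng):
        from facesim.meg import EvokedSet
        from facesim.similarity import pattern_similarity_matrix, vectorize

        data = rng.normal(0, 1, (5, 8, 12))
        evoked = EvokedSet(
            data=data, stimulus_ids=tuple("abcde"), ch_names=tuple(f"c{k}" for k in range(8)),
            times=np.arange(12) * 10.0, sfreq=100.0,
        )
        cells = pattern_cells_over_time(evoked)
        assert cells.shape == (12, 10)
        for t in (0, 5, 11):
            expected = vectorize(
                pattern_similarity_matrix(data[:, :, t], list("abcde"))
            )
            np.testing.assert_allclose(cells[t], expected, atol=1e-10)

    def test_over_tf_rejects_edge_bins(self, rng):
        from facesim.meg import morlet_power
        from facesim.meg import EpochSet

        times = -500.0 + np.arange(150) * 10.0
        epochs = EpochSet(
            data=rng.normal(0, 1, (4, 3, 150)), sfreq=100.0, times=times,
            trial_stimulus_ids=("a", "b", "a", "b"),
            ch_names=("c0", "c1", "c2"), ch_types=("axial",) * 3,
        )
        power = morlet_power(epochs, [8.0])
        with pytest.raises(ValueError, match="edge"):
            pattern_cells_over_tf(power, time_window=(-500.0, 900.0))
        cells, freqs, out_times = pattern_cells_over_tf(
            power, time_window=(-500.0, 900.0), allow_edges=True
        )
        assert cells.shape[0] == 1


class TestRsaScan:
    def test_noise_free_model_recovery(self, identity_model):
        """Cells identical to the model geometry give rho = 1 everywhere."""
        model_cells = identity_model.cells()
        cells = np.tile(model_cells, (4, 6, 1))
        stat = rsa_scan(cells, identity_model, scheme=PermutationScheme(20, 0))
        np.testing.assert_allclose(stat.rho, 1.0)

    def test_planted_window_recovered_and_control_abolishes(self, rng, identity_model):
        ids = identity_model.stimulus_ids
        model_cells = identity_model.cells()
        n_cells = model_cells.size
        # continuous "physical" model correlated with the categorical one
        physical = model_cells + rng.normal(0, 0.35, n_cells)
        window = slice(10, 25)
        cells = rng.normal(0, 1.0, (16, 40, n_cells))
        cells[:, window, :] += 2.0 * model_cells
        scheme = PermutationScheme(n_permutations=200, seed=5)

        stat = rsa_scan(cells, physical, scheme=scheme)
        assert stat.mask[window].any()
        stat_controlled = rsa_scan(
            cells, physical, controls=[identity_model], scheme=scheme
        )
        assert not stat_controlled.mask.any()

    def test_degenerate_model_rejected(self):
        flat = category_model_matrix(["a", "b", "c"], ["x", "x", "x"])
        with pytest.raises(ValueError, match="degenerate"):
            rsa_scan(np.random.default_rng(0).normal(0, 1, (3, 4, 3)), flat)

    def test_params_recorded(self, rng, identity_model):
        cells = rng.normal(0, 1, (4, 6, identity_model.cells().size))
        stat = rsa_scan(cells, identity_model, scheme=PermutationScheme(10, 3))
        assert stat.params["n_permutations"] == 10
        assert stat.params["scheme"] == "participant_sign_flip"
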
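import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdot.approx_error import (absolute_error_stats, cylinder_sensitivity,
                               difference_error_stats, difference_ratios,
                               eigenvalue_fraction_count,
                               projection_ratio_mean, signal_visibility,
                               stats_from_differences)


@pytest.fixture
def two_sample_stats():
    """y_ref = (0,0); y_1 = (1,0), y_2 = (0,1)."""
    return absolute_error_stats(np.zeros(2), [np.array([1.0, 0.0]),
                                              np.array([0.0, 1.0])])


class TestTwoSampleHandExample:
    def test_mean_and_covariance(self, two_sample_stats):
        st_ = two_sample_stats
        assert np.allclose(st_.mean, [-0.5, -0.5])
        assert np.allclose(st_.cov, [[0.5, -0.5], [-0.5, 0.5]])

    def test_eigenpairs_and_std(self, two_sample_stats):
        st_ = two_sample_stats
        assert np.allclose(st_.eigenvalues, [1.0, 0.0], atol=1e-14)
        v1 = st_.eigenvectors[:, 0]
        assert np.allclose(np.abs(v1), [1, 1] / np.sqrt(2))
        assert st_.STD == pytest.approx(1.0)
        assert st_.rank == 1

    def test_mean_projection_ratio_zero(self, two_sample_stats):
        """mu_e is orthogonal to the single eigendirection (1,-1)."""
        assert projection_ratio_mean(two_sample_stats) == pytest.approx(0.0,
                                                                        abs=1e-12)


class TestStatsProperties:
    def test_identical_population_gives_zero_stats(self):
        ref = np.array([1.0, 2.0, 3.0])
        st_ = absolute_error_stats(ref, [ref.copy() for _ in range(4)])
        assert np.all(st_.mean == 0)
        assert np.all(st_.cov == 0)
        assert st_.STD == 0.0
        assert st_.rank == 0

    def test_rank_is_n_minus_1_for_independent_samples(self):
        rng = np.random.default_rng(0)
        N, m = 6, 20
        diffs = rng.standard_normal((N, m))
        st_ = stats_from_differences(diffs)
        assert st_.rank == N - 1
        lam = st_.eigenvalues
        assert np.all(lam[: N - 1] > 1e-10 * lam[0])
        assert np.all(lam[N - 1:] <= 1e-10 * lam[0])

    def test_trace_equals_eigenvalue_sum(self):
        rng = np.random.default_rng(1)
        st_ = stats_from_differences(rng.standard_normal((5, 8)))
        assert np.trace(st_.cov) == pytest.approx(st_.eigenvalues.sum())

    def test_covariance_psd_and_symmetric(self):
        rng = np.random.default_rng(2)
        st_ = stats_from_differences(rng.standard_normal((4, 7)))
        assert np.allclose(st_.cov, st_.cov.T)
        assert np.all(np.linalg.eigvalsh(st_.cov) > -1e-12)


class TestVisibility:
    def test_zero_signal_gives_zero_ratio(self, two_sample_stats):
        ratio, proj = signal_visibility(np.zeros(2), two_sample_stats)
        assert ratio == 0.0
        assert np.all(proj == 0.0)

    def test_single_direction_alignment(self):
        rng = np.random.default_rng(3)
        diffs = np.outer([1.0, -1.0, 2.0, -2.0], [3.0, 4.0])
        st_ = stats_from_differences(diffs)
        lam1 = st_.eigenvalues[0]
        v1 = st_.eigenvectors[:, 0]
        ratio, _ = signal_visibility(v1 * np.sqrt(lam1), st_)
        assert ratio == pytest.approx(np.sqrt(lam1 / st_.eigenvalues.sum()))

    def test_projection_never_longer_than_vector(self, two_sample_stats):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.standard_normal(2)
            assert np.linalg.norm(two_sample_stats.project(x)) <= \
                np.linalg.norm(x) + 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 100.0))
    def test_ratios_invariant_under_common_rescaling(self, scale):
        rng = np.random.default_rng(5)
        diffs = rng.standard_normal((5, 9))
        dy = rng.standard_normal(9)
        st1 = stats_from_differences(diffs)
        st2 = stats_from_differences(diffs * scale)
        r1, _ = signal_visibility(dy, st1)
        r2, _ = signal_visibility(dy * scale, st2)
        assert r1 == pytest.approx(r2, rel=1e-9)
        assert projection_ratio_mean(st1) == pytest.approx(
            projection_ratio_mean(st2), rel=1e-9)


class TestDifferenceErrorStats:
    def test_identical_jacobians_give_zero(self):
        J = np.arange(8.0).reshape(2, 4)
        dx = np.array([1.0, 0.0, 0.5, 0.0])
        rows = np.array([(J - J) @ dx for _ in range(3)])
        st_ = difference_error_stats(rows)
        assert st_.STD == 0.0

    def test_two_anatomy_toy_hand_check(self):
        """Hand-built 2x2 Jacobians: e_i = (J_ref - J_i) dx."""
        J_ref = np.array([[1.0, 0.0], [0.0, 1.0]])
        J_1 = np.array([[0.0, 0.0], [0.0, 1.0]])
        J_2 = np.array([[1.0, 0.0], [0.0, 0.0]])
        dx = np.array([1.0, 1.0])
        rows = np.array([(J_ref - J_1) @ dx, (J_ref - J_2) @ dx])
        # rows: (1,0), (0,1) -> same structure as the 2-sample example
        st_ = difference_error_stats(rows)
        assert np.allclose(st_.mean, [0.5, 0.5])
        assert np.allclose(st_.cov, [[0.5, -0.5], [-0.5, 0.5]])
        r1, r2 = difference_ratios(np.array([2.0, 2.0]), st_)
        # ||dy|| / ||mu|| = 2 sqrt2 / (sqrt2 / 2) = 4
        assert r1 == pytest.approx(4.0)
        # dy orthogonal to the only eigendirection -> visibility 0
        assert r2 == pytest.approx(0.0, abs=1e-12)


class TestTissueSweep:
    def test_visibility_monotone_in_change_magnitude(self):
        """Sweep curves are zero at no change and increase with the size
        of the relative absorption change (linear synthetic response)."""
        from fdot.approx_error import tissue_sweep

        rng = np.random.default_rng(8)
        base = {"log_amplitude": rng.standard_normal(12),
                "phase": rng.standard_normal(12)}
        stats = {k: stats_from_differences(rng.standard_normal((6, 12)) * 0.1)
                 for k in base}
        direction = {k: rng.standard_normal(12) for k in base}

        def measure(rc):
            return {k: base[k] + rc * direction[k] for k in base}

        grid = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])
        curves = tissue_sweep(measure, base, stats, grid)
        for k, c in curves.items():
            assert c[2] == 0.0
            assert c[1] < c[0] and c[3] < c[4]
            assert np.allclose(c[0], c[4] * 1.0, rtol=1e-9)  # even response


class TestEigenvalueFraction:
    def test_dominant_mode_counts(self):
        diffs = np.array([[10.0, 0.0], [-10.0, 0.0], [0.1, 0.1], [0.0, -0.1]])
        st_ = stats_from_differences(diffs)
        assert eigenvalue_fraction_count(st_, 0.95) == 1


class TestCylinderSensitivity:
    @pytest.fixture
    def grid_row(self):
        """Regular 1 mm voxel grid with a synthetic sensitivity row."""
        n = 20
        idx = np.indices((n, n, n)).reshape(3, -1).T
        cents = idx + 0.5
        vols = np.ones(len(cents))
        rng = np.random.default_rng(6)
        row = -np.exp(-0.2 * cents[:, 2]) * (1 + 0.1 * rng.random(len(cents)))
        return row, cents, vols

    def test_partition_additivity(self, grid_row):
        row, cents, vols = grid_row
        surface = np.array([10.0, 10.0, 0.0])
        normal = np.array([0.0, 0.0, 1.0])
        depths, prof = cylinder_sensitivity(row, cents, vols, surface, normal,
                                            radius=2.5, depth=10.0,
                                            slice_thickness=1.0)
        rel = cents - surface
        ax = rel @ normal
        rad = np.linalg.norm(rel - np.outer(ax, normal), axis=1)
        full = (rad <= 2.5) & (ax >= 0) & (ax <= 10.0)
        assert prof.sum() == pytest.approx(row[full].sum(), rel=1e-9)

    def test_cw_sign_and_empty_slices(self, grid_row):
        row, cents, vols = grid_row
        surface = np.array([10.0, 10.0, 0.0])
        normal = np.array([0.0, 0.0, 1.0])
        _, prof = cylinder_sensitivity(row, cents, vols, surface, normal,
                                       radius=2.5, depth=10.0)
        assert np.all(prof <= 0)  # CW log-amplitude rows are nonpositive
        # zero row outside the support
        row0 = np.zeros_like(row)
        _, prof0 = cylinder_sensitivity(row0, cents, vols, surface, normal)
        assert np.all(prof0 == 0)

    def test_cylinder_outside_model_rejected(self, grid_row):
        row, cents, vols = grid_row
        with pytest.raises(ValueError):
            cylinder_sensitivity(row, cents, vols, np.array([100.0, 100, 0]),
                                 np.array([0.0, 0, 1]))
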
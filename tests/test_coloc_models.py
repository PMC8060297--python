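import numpy as np
import pytest

from panoquant.coloc_models import (
    ProfileMatrix,
    RegressionFit,
    multiple_regression,
    polynomial_refine,
    serial_compatibility,
    simple_regression,
    stack_profiles,
    virtual_knockout,
)
from panoquant.quantify import TDProfile, td_profile
from panoquant.synthetic_data import SectionParams, generate_serial_stack


def _profile(values, res=1.0, name=""):
    values = np.asarray(values, dtype=np.float64)
    return TDProfile(
        row_means=values,
        in_section_counts=np.ones(values.size, dtype=np.int64),
        resolution_um_per_px=res,
        marker_name=name,
    )


def _matrix(rng, n, betas, noise_sd=10.0, intercept=20.0, x_mean=60.0, x_sd=15.0):
    """Design with known coefficients for recovery tests."""
    m = len(betas)
    X = rng.normal(x_mean, x_sd, (n, m))
    y = intercept + X @ np.asarray(betas) + rng.normal(0, noise_sd, n)
    names = [f"x{i}" for i in range(m)]
    cols = np.column_stack([X, y])
    return ProfileMatrix(
        markers=names + ["y"], values=cols, positions_um=np.arange(n, dtype=float)
    )


class TestStackProfiles:
    def test_assembly_preserves_order(self):
        profs = [_profile([1, 2, 3], name=n) for n in ("a", "b", "c")]
        X = stack_profiles(profs)
        assert X.markers == ["a", "b", "c"]
        assert X.values.shape == (3, 3)

    def test_mismatched_lengths_error_lists_lengths(self):
        profs = [_profile([1, 2, 3], name="a"), _profile([1, 2], name="b")]
        with pytest.raises(ValueError, match=r"\[3, 2\]"):
            stack_profiles(profs)

    def test_duplicate_marker_names_error(self):
        profs = [_profile([1, 2], name="a"), _profile([3, 4], name="a")]
        with pytest.raises(ValueError, match="duplicate"):
            stack_profiles(profs)

    def test_relative_mode(self):
        profs = [_profile([50, 100], name="a")]
        X = stack_profiles(profs, relative=True)
        assert X.values[:, 0].tolist() == [50.0, 100.0]


class TestSimpleRegression:
    def test_auto_correlation_reference_row(self, rng):
        x = rng.normal(100, 20, 200)
        fit = simple_regression(x, x)
        assert fit.R2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slopes[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.significant

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.normal(0, 1, 500)
        y = 2 * x + rng.normal(0, 1, 500)
        fit = simple_regression(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.R2 == pytest.approx(r**2, abs=1e-10)
        assert fit.R == pytest.approx(r, abs=1e-10)

    def test_ci99_coverage_in_simulation(self):
        # 99% CI for the slope should cover the true value in >= 95% of reps
        covered = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(50, 10, 200)
            y = 2.0 * x + rng.normal(0, 10, 200)
            fit = simple_regression(x, y)
            lo, hi = fit.ci99[0]
            covered += lo <= 2.0 <= hi
        assert covered >= 190

    def test_null_simulation_r2_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 8800)
        y = rng.normal(0, 1, 8800)
        assert simple_regression(x, y).R2 < 0.05

    def test_zero_variance_predictor_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            simple_regression(np.ones(10), np.arange(10.0))

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            simple_regression(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestMultipleRegression:
    def test_single_predictor_reduces_to_simple(self, rng):
        x = rng.normal(50, 10, 300)
        y = 3 * x + rng.normal(0, 5, 300)
        X = ProfileMatrix(markers=["x", "y"], values=np.column_stack([x, y]),
                          positions_um=np.arange(300.0))
        multi = multiple_regression(X, "y")
        simple = simple_regression(x, y)
        assert multi.R2 == pytest.approx(simple.R2, abs=1e-12)
        assert multi.slopes[0] == pytest.approx(simple.slopes[0], abs=1e-10)
        assert multi.intercept == pytest.approx(simple.intercept, abs=1e-8)

    def test_coefficient_recovery_within_ci99(self):
        rng = np.random.default_rng(3)
        betas = [1.5, -0.8, 0.4]
        X = _matrix(rng, 2000, betas)
        fit = multiple_regression(X, "y")
        for j, beta in enumerate(betas):
            lo, hi = fit.ci99[j]
            assert lo <= beta <= hi

    def test_noise_predictor_never_decreases_r2(self, rng):
        base = _matrix(rng, 500, [2.0])
        fit1 = multiple_regression(base, "y")
        noisy = ProfileMatrix(
            markers=base.markers + ["junk"],
            values=np.column_stack([base.values, rng.normal(0, 1, 500)]),
            positions_um=base.positions_um,
        )
        fit2 = multiple_regression(noisy, "y")
        assert fit2.R2 >= fit1.R2 - 1e-12

    def test_collinear_predictors_error_names_pair(self, rng):
        x = rng.normal(0, 1, 100)
        X = ProfileMatrix(
            markers=["a", "b", "y"],
            values=np.column_stack([x, 2 * x, rng.normal(0, 1, 100)]),
            positions_um=np.arange(100.0),
        )
        with pytest.raises(ValueError, match="'a' and 'b'"):
            multiple_regression(X, "y")

    def test_multiple_r2_at_least_best_single(self, rng):
        X = _matrix(rng, 800, [1.0, 0.5], noise_sd=20.0)
        fit = multiple_regression(X, "y")
        assert fit.R2 >= max(fit.simple_r2.values()) - 1e-12

    def test_parameter_recovery_50_seeds(self):
        # median absolute coefficient error under 5% of the true value
        betas = np.array([2.0, -1.0, 0.5])
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = _matrix(rng, 2000, list(betas), noise_sd=10.0)
            fit = multiple_regression(X, "y")
            errors.append(np.abs(fit.slopes - betas) / np.abs(betas))
        assert np.median(np.concatenate(errors)) < 0.05


class TestPolynomialRefine:
    def test_perfectly_linear_data_unchanged(self, rng):
        x = rng.normal(10, 2, 100)
        fit = simple_regression(x, 3 * x + 1)
        refined = polynomial_refine(fit, order=6)
        assert refined.R2 == pytest.approx(1.0, abs=1e-10)
        assert refined.polynomial_order == 6

    def test_saturating_link_improves_fit(self, rng):
        x = np.linspace(-3, 3, 400)
        y = 100 / (1 + np.exp(-2 * x)) + rng.normal(0, 1, 400)
        fit = simple_regression(x, y)
        refined = polynomial_refine(fit, order=6)
        assert refined.R2 > fit.R2 + 0.01

    def test_order_one_reproduces_linear_r2(self, rng):
        x = rng.normal(0, 1, 200)
        y = 2 * x + rng.normal(0, 1, 200)
        fit = simple_regression(x, y)
        refined = polynomial_refine(fit, order=1)
        assert refined.R2 == pytest.approx(fit.R2, abs=1e-10)

    def test_refined_never_below_linear(self, rng):
        x = rng.normal(0, 1, 300)
        y = x + 0.3 * x**2 + rng.normal(0, 0.5, 300)
        fit = simple_regression(x, y)
        assert polynomial_refine(fit, order=6).R2 >= fit.R2

    def test_order_at_least_n_errors(self, rng):
        x = rng.normal(0, 1, 5)
        fit = simple_regression(x, x + rng.normal(0, 0.1, 5))
        with pytest.raises(ValueError, match="order"):
            polynomial_refine(fit, order=5)


class TestVirtualKnockout:
    def test_zero_coefficient_is_neutral(self):
        n = 50
        x = np.linspace(10, 30, n)
        z = np.linspace(5, 9, n)
        slopes = np.array([2.0, 0.0])
        predicted = x * 2.0 + 5.0
        fit = RegressionFit(
            dependent="y", predictors=["a", "b"],
            coefficients=np.r_[slopes, 5.0],
            R=1.0, R2=1.0, F=np.inf, p=0.0, ci99=None,
            predicted=predicted, observed=predicted,
            std_error=0.0, n=n,
        )
        X = ProfileMatrix(markers=["a", "b"], values=np.column_stack([x, z]),
                          positions_um=np.arange(float(n)))
        res = virtual_knockout(fit, X, "b")
        assert res.fold_change == pytest.approx(1.0)
        assert res.direction == "neutral"

    def test_closed_form_identity(self, rng):
        # knockout mean must equal baseline mean - beta_j * mean(x_j)
        X = _matrix(rng, 400, [1.2, -0.4, 0.7], intercept=80.0)
        fit = multiple_regression(X, "y")
        for j, factor in enumerate(fit.predictors):
            res = virtual_knockout(fit, X, factor)
            closed = res.baseline_mean_gv - fit.slopes[j] * X.column(factor).mean()
            assert res.knockout_mean_gv == pytest.approx(closed, abs=1e-8)

    def test_large_positive_beta_gives_pro_direction(self, rng):
        # factor driving the dependent signal up: removal lowers prediction
        X = _matrix(rng, 400, [1.5, 0.1], intercept=150.0, x_mean=40.0)
        fit = multiple_regression(X, "y")
        res = virtual_knockout(fit, X, "x0")
        assert res.fold_change < 1.0
        assert res.direction == "pro"

    def test_unknown_factor_errors(self, rng):
        X = _matrix(rng, 100, [1.0])
        fit = multiple_regression(X, "y")
        with pytest.raises(ValueError, match="nope"):
            virtual_knockout(fit, X, "nope")

    def test_polynomial_fit_rejected(self, rng):
        X = _matrix(rng, 100, [1.0])
        fit = multiple_regression(X, "y")
        refined = polynomial_refine(fit, order=2)
        with pytest.raises(ValueError, match="linear"):
            virtual_knockout(refined, X, "x0")


class TestSerialCompatibility:
    def test_reference_row_is_perfect_autocorrelation(self, rng):
        profs = [_profile(rng.normal(100, 20, 80)) for _ in range(6)]
        report = serial_compatibility(profs, ref_index=0, step=5)
        frame = report.to_frame()
        assert frame.loc[0, "section"] == "REF"
        assert frame.loc[0, "r2"] == pytest.approx(1.0, abs=1e-12)
        assert frame.loc[0, "coefficient"] == pytest.approx(1.0, abs=1e-10)

    def test_identical_stack_all_r2_one(self, rng):
        base = rng.normal(100, 20, 60)
        profs = [_profile(base.copy()) for _ in range(11)]
        report = serial_compatibility(profs, ref_index=0, step=5)
        assert all(f.R2 == pytest.approx(1.0, abs=1e-12) for f in report.fits)

    def test_jittered_stack_r2_non_increasing(self):
        stack = generate_serial_stack(
            SectionParams(), n_sections=16, jitter=2.0, seed=4,
        )
        profs = [td_profile(s.dapi, s.truth.geometry.section_mask) for s in stack]
        report = serial_compatibility(profs, ref_index=0, step=5)
        r2s = [f.R2 for f in report.fits]
        assert all(a >= b - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_mismatched_lengths_error(self, rng):
        profs = [_profile(rng.normal(0, 1, 30)), _profile(rng.normal(0, 1, 40))]
        with pytest.raises(ValueError, match="mismatched lengths"):
            serial_compatibility(profs)

    def test_table_columns(self, rng):
        profs = [_profile(rng.normal(100, 10, 50)) for _ in range(6)]
        frame = serial_compatibility(profs).to_frame()
        assert list(frame.columns) == [
            "section", "r2", "std_error", "coefficient",
            "ci99_lower", "ci99_upper", "f_value", "p", "significant",
        ]
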
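import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haycal.preprocess import (
    DegenerateSpectrumError,
    DomainError,
    LengthError,
    MathTreatment,
    PreprocessError,
    absorbance_transform,
    apply_treatment,
    default_treatments,
    detrend,
    gap_derivative,
    gap_derivative_wavelengths,
    snv,
)
from haycal.spectra_io import SpectrumSet


class TestAbsorbanceTransform:
    @pytest.mark.parametrize(
        "r,base,expected",
        [(1.0, "log10", 0.0), (1.0, "natural", 0.0),
         (0.1, "log10", 1.0), (np.exp(-1.0), "natural", 1.0)],
    )
    def test_closed_forms(self, r, base, expected):
        assert np.isclose(absorbance_transform(np.array([[r]]), base)[0, 0], expected)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_domain_error_names_cell(self, bad):
        with pytest.raises(DomainError):
            absorbance_transform(np.array([[0.5, bad]]))


class TestSNV:
    def test_simple_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_rows_zero_mean_unit_sd(self, rng):
        x = rng.normal(size=(5, 50))
        out = snv(x)
        assert np.all(np.abs(out.mean(axis=1)) < 1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_idempotent_on_normalised(self, rng):
        x = snv(rng.normal(size=30))
        np.testing.assert_allclose(snv(x), x, atol=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=20)
        np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-8)

    def test_constant_spectrum_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            snv(np.full(10, 3.0))


class TestDetrend:
    W = np.linspace(680.0, 2500.0, 150)

    def test_exact_quadratic_annihilated(self):
        x = 1.0 + 0.002 * self.W + 3e-7 * self.W**2
        assert np.max(np.abs(detrend(x, self.W, 2))) < 1e-8

    def test_projection_idempotent(self, rng):
        x = rng.normal(size=self.W.size)
        once = detrend(x, self.W)
        np.testing.assert_allclose(detrend(once, self.W), once, atol=1e-10)

    def test_residual_orthogonal_to_basis(self, rng):
        x = rng.normal(size=self.W.size)
        res = detrend(x, self.W, 2)
        u = 2 * (self.W - self.W[0]) / (self.W[-1] - self.W[0]) - 1
        scale = np.linalg.norm(x) * self.W.size
        for p in range(3):
            assert abs(res @ u**p) < 1e-8 * scale

    def test_band_recovery_matches_normal_equations(self):
        # linear ramp + Gaussian band; compare with explicit LS fit
        band = 0.5 * np.exp(-0.5 * ((self.W - 1500.0) / 30.0) ** 2)
        x = 0.1 + 1e-4 * self.W + band
        res = detrend(x, self.W, 2)
        u = 2 * (self.W - self.W[0]) / (self.W[-1] - self.W[0]) - 1
        A = np.vander(u, 3, increasing=True)
        beta = np.linalg.solve(A.T @ A, A.T @ x)
        np.testing.assert_allclose(res, x - A @ beta, atol=1e-9)
        baseline_region = np.abs(self.W - 1500.0) > 300.0
        assert np.max(np.abs(res[baseline_region])) < 0.1 * band.max()

    def test_negative_order_rejected(self):
        with pytest.raises(PreprocessError):
            detrend(np.ones(10), np.arange(10.0), poly_order=-1)


def _naive_gap_derivative(x, d, gap, smoothing):
    """Independent nested-loop oracle for the gap-segment derivative."""
    x = list(map(float, x))
    if smoothing > 1:
        x = [sum(x[i : i + smoothing]) / smoothing for i in range(len(x) - smoothing + 1)]
    for _ in range(d):
        x = [x[i + gap] - x[i] for i in range(len(x) - gap)]
    return np.array(x)


class TestGapDerivative:
    def test_constant_gives_zeros(self):
        for d in (1, 2, 3, 4):
            out = gap_derivative(np.full(60, 2.5), d, 4, 4)
            np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_ramp_first_derivative(self):
        m = 0.37
        x = m * np.arange(50.0)
        out = gap_derivative(x, 1, 4, 1)
        np.testing.assert_allclose(out, 4 * m, atol=1e-12)

    def test_cubic_annihilated_by_fourth_derivative(self):
        i = np.arange(120.0)
        x = 1.0 + 0.5 * i - 0.02 * i**2 + 1e-4 * i**3
        for gap in (4, 8):
            out = gap_derivative(x, 4, gap, 1)
            assert np.max(np.abs(out)) < 1e-9

    @pytest.mark.parametrize("d,gap,smoothing", [(1, 4, 4), (2, 8, 8), (3, 5, 3), (4, 4, 1)])
    def test_matches_naive_oracle(self, rng, d, gap, smoothing):
        x = rng.normal(size=80)
        np.testing.assert_allclose(
            gap_derivative(x, d, gap, smoothing),
            _naive_gap_derivative(x, d, gap, smoothing),
            atol=1e-10,
        )

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 500), d=st.integers(1, 3), gap=st.sampled_from([4, 8]))
    def test_linearity(self, seed, d, gap):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 70))
        a, b = r.normal(size=2)
        lhs = gap_derivative(a * x + b * y, d, gap, 4)
        rhs = a * gap_derivative(x, d, gap, 4) + b * gap_derivative(y, d, gap, 4)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_length_error_states_minimum(self):
        with pytest.raises(LengthError, match="at least"):
            gap_derivative(np.ones(10), 4, 16, 16)

    def test_wavelength_bookkeeping_symmetric_even_gap(self):
        w = 680.0 + 2.0 * np.arange(40)
        out_w = gap_derivative_wavelengths(w, 1, 4, 1)
        # midpoint of the two support points, still on the original spacing
        assert out_w.size == 36
        np.testing.assert_allclose(np.diff(out_w), 2.0)
        np.testing.assert_allclose(out_w[0], (w[0] + w[4]) / 2)


class TestMathTreatment:
    def test_default_grid_is_twelve(self):
        grid = default_treatments()
        assert len(grid) == 12
        codes = {(t.derivative_order, t.gap, t.smoothing) for t in grid}
        assert codes == {(d, g, g) for d in (1, 2, 3, 4) for g in (4, 8, 16)}

    def test_parse_round_trip(self):
        t = MathTreatment.from_string("3,16,16")
        assert (t.derivative_order, t.gap, t.smoothing) == (3, 16, 16)
        assert str(t) == "3,16,16"
        t4 = MathTreatment.from_string("1,4,4,2")
        assert t4.smoothing2 == 2

    def test_invalid_codes_rejected(self):
        with pytest.raises(PreprocessError):
            MathTreatment(5, 4, 4)
        with pytest.raises(PreprocessError):
            MathTreatment(1, 0, 4)
        with pytest.raises(PreprocessError):
            MathTreatment.from_string("1,4")


class TestApplyTreatment:
    def _spectra(self, rng, n=4, p=80):
        w = 680.0 + 2.0 * np.arange(p)
        return SpectrumSet(
            [f"S{i}" for i in range(n)], w, rng.uniform(0.2, 1.0, (n, p))
        )

    def test_identity_treatment(self, rng):
        s = self._spectra(rng)
        out = apply_treatment(s, MathTreatment(0, 1, 1, scatter_correction="none"))
        np.testing.assert_allclose(out.absorbance, s.absorbance)

    def test_snv_makes_scalar_multiples_identical(self, rng):
        w = 680.0 + 2.0 * np.arange(60)
        base = rng.uniform(0.2, 1.0, 60)
        s = SpectrumSet(["a", "b"], w, np.vstack([base, 3.0 * base]))
        out = apply_treatment(s, MathTreatment(0, 1, 1, scatter_correction="snv"))
        np.testing.assert_allclose(out.absorbance[0], out.absorbance[1], atol=1e-10)

    def test_equals_manual_composition(self, rng):
        s = self._spectra(rng)
        t = MathTreatment.from_string("1,4,4")
        out = apply_treatment(s, t)
        manual = snv(s.absorbance)
        manual = detrend(manual, s.wavelengths_nm, 2)
        manual = gap_derivative(manual, 1, 4, 4)
        np.testing.assert_allclose(out.absorbance, manual, atol=1e-12)
        assert out.n_channels == s.n_channels - (4 - 1) - 4

    def test_row_permutation_equivariance(self, rng):
        s = self._spectra(rng, n=6)
        t = MathTreatment.from_string("2,8,8")
        out = apply_treatment(s, t).absorbance
        perm = rng.permutation(6)
        out_perm = apply_treatment(s.subset(perm), t).absorbance
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-12)
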
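"""Powder simulation, mixture unmixing and pKa inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsferric.epr import (
    EPRSpeciesModel,
    TitrationSeries,
    fit_mixture,
    logistic_fraction,
    pka_logistic_fit,
    pka_single_point,
    powder_pattern,
    resonance_field,
)
from lsferric.exceptions import GridCoverageError
from lsferric.synthetic import SyntheticConfig, make_epr_mixture

from conftest import FIELD_GRID


class TestResonanceField:
    def test_free_electron_x_band(self):
        assert resonance_field(2.0023, 9.40) == pytest.approx(335.4, abs=0.05)

    def test_low_spin_ferric_g(self):
        assert resonance_field(2.28, 9.40) == pytest.approx(294.6, abs=0.05)

    @given(st.floats(0.5, 3.9), st.floats(1.0, 35.0))
    @settings(max_examples=50, deadline=None)
    def test_doubling_g_halves_field(self, g, freq):
        assert resonance_field(2 * g, freq) == pytest.approx(
            resonance_field(g, freq) / 2, rel=1e-12
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            resonance_field(-2.0, 9.4)


class TestPowderPattern:
    def test_isotropic_derivative_crosses_zero_at_resonance(self):
        model = EPRSpeciesModel("iso", (2.1, 2.1, 2.1), (1.0, 1.0, 1.0))
        spec = powder_pattern(model, FIELD_GRID, 9.40, n_theta=50, n_phi=50)
        b0 = resonance_field(2.1, 9.40)
        lo, hi = np.argmax(spec.intensity), np.argmin(spec.intensity)
        seg = spec.intensity[lo : hi + 1]
        crossing = FIELD_GRID[lo + np.where(np.diff(np.sign(seg)))[0][0]]
        assert crossing == pytest.approx(b0, abs=0.2)
        # symmetric line: derivative is odd around the crossing
        assert spec.intensity.max() == pytest.approx(-spec.intensity.min(), rel=0.01)

    def test_rhombic_turning_points(self):
        model = EPRSpeciesModel("BA", (2.28, 2.14, 1.97), (1.5, 1.5, 1.5))
        spec = powder_pattern(model, FIELD_GRID, 9.40, n_theta=100, n_phi=100)
        y = spec.intensity
        for g in (2.28, 2.14, 1.97):
            b = resonance_field(g, 9.40)
            window = (FIELD_GRID > b - 3) & (FIELD_GRID < b + 3)
            # a derivative extremum within one FWHM of each principal field
            i_ext = np.argmax(np.abs(y[window]))
            assert abs(FIELD_GRID[window][i_ext] - b) < 1.5

    def test_absorption_area_invariant_under_anisotropy(self):
        wide = np.linspace(240.0, 400.0, 1200)
        for gset in [(2.1, 2.1, 2.1), (2.28, 2.14, 1.97), (2.4, 2.0, 1.9)]:
            model = EPRSpeciesModel("m", gset, (1.5, 1.5, 1.5))
            spec = powder_pattern(
                model, wide, 9.40, n_theta=60, n_phi=60, derivative=False
            )
            area = np.trapezoid(spec.intensity, wide)
            assert area == pytest.approx(1.0, abs=1e-6)

    def test_derivative_integrates_to_zero(self):
        model = EPRSpeciesModel("m", (2.28, 2.14, 1.97), (1.5, 1.5, 1.5))
        spec = powder_pattern(model, FIELD_GRID, 9.40, n_theta=60, n_phi=60)
        assert np.trapezoid(spec.intensity, FIELD_GRID) == pytest.approx(0.0, abs=1e-8)

    def test_grid_not_covering_turning_points_rejected(self):
        model = EPRSpeciesModel("m", (2.28, 2.14, 1.97))
        with pytest.raises(GridCoverageError):
            powder_pattern(model, np.linspace(300, 320, 256), 9.40)


class TestFitMixture:
    def test_single_component_recovers_unit_fraction(self, aq_components):
        models, comps = aq_components
        cfg = SyntheticConfig(seed=3, noise_sigma=0.02)
        obs = make_epr_mixture([models[0]], [1.0], config=cfg, components=[comps[0]])
        res = fit_mixture(obs, [comps[0]])
        assert res.fractions == (1.0,)

    def test_two_component_recovery_and_permutation_equivariance(self, aq_components):
        models, comps = aq_components
        cfg = SyntheticConfig(seed=11, noise_sigma=0.02)  # SNR 50
        obs = make_epr_mixture(models, [0.74, 0.26], config=cfg, components=comps)
        res = fit_mixture(obs, comps)
        assert res.fractions[0] == pytest.approx(0.74, abs=0.02)
        assert res.fractions[1] == pytest.approx(0.26, abs=0.02)
        assert sum(res.fractions) == pytest.approx(1.0, abs=1e-12)
        swapped = fit_mixture(obs, comps[::-1])
        assert swapped.fractions[::-1] == pytest.approx(res.fractions, abs=1e-6)

    def test_null_third_component_stays_near_zero(self, aq_components):
        models, comps = aq_components
        third = powder_pattern(
            EPRSpeciesModel("BA", (2.28, 2.14, 1.97)), FIELD_GRID, 9.40
        )
        cfg = SyntheticConfig(seed=5, noise_sigma=0.02)
        obs = make_epr_mixture(models, [0.74, 0.26], config=cfg, components=comps)
        res = fit_mixture(obs, comps + [third])
        assert res.fractions[2] < 0.02

    def test_collinear_components_warn(self, aq_components):
        _, comps = aq_components
        obs = comps[0]
        with pytest.warns(UserWarning, match="collinear"):
            fit_mixture(obs, [comps[0], comps[0]])


class TestPKa:
    @pytest.mark.parametrize(
        "ph, frac, expected",
        [
            (6.5, 0.28, 6.09),  # low-pH sulfenate ionization, prints as 6.1
            (8.5, 0.52, 8.53),  # aquo ligand ionization, prints as 8.5
            (7.0, 0.50, 7.00),  # half-protonation at pH = pKa
        ],
    )
    def test_single_point_examples(self, ph, frac, expected):
        assert pka_single_point(ph, frac) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("frac", [0.0, 1.0])
    def test_endpoint_fractions_rejected(self, frac):
        with pytest.raises(ValueError):
            pka_single_point(7.0, frac)

    @given(st.floats(3.0, 11.0), st.floats(4.0, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_single_point_inverts_logistic_exactly(self, ph, pka):
        assert pka_single_point(ph, logistic_fraction(ph, pka)) == pytest.approx(
            pka, abs=1e-9
        )

    def test_exact_two_point_fit(self):
        pka_true = 7.3
        series = TitrationSeries(
            points=tuple((ph, logistic_fraction(ph, pka_true)) for ph in (6.8, 7.9))
        )
        pka, diag = pka_logistic_fit(series)
        assert pka == pytest.approx(pka_true, abs=1e-6)
        assert diag["rmse"] < 1e-9

    def test_published_high_ph_fractions_bracket_single_point_estimates(self):
        """Fit to the aqueous form's printed minor-species fractions."""
        series = TitrationSeries(points=((7.5, 1 - 0.26), (8.5, 1 - 0.48)))
        pka, _ = pka_logistic_fit(series)
        assert 7.9 <= pka <= 8.6

    def test_one_sided_narrow_series_warns(self):
        series = TitrationSeries(points=((7.0, 0.9), (7.2, 0.88), (7.3, 0.87)))
        with pytest.warns(UserWarning, match="ill-conditioned"):
            pka_logistic_fit(series)
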
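"""Taylor analysis: closed forms, inversion, SOC model, assignment search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsferric.exceptions import (
    DegenerateAssignmentError,
    NormalizationError,
    OrderingError,
)
from lsferric.ligand_field import (
    HoleCoefficients,
    LigandFieldParameters,
    SignedGTensor,
    assign_g_tensor,
    coefficients_from_g,
    doublet_g_values,
    g_from_coefficients,
    ligand_field_from_g,
    predicted_transitions,
    soc_ground_doublet,
)

from conftest import TABLE1


class TestGFromCoefficients:
    @pytest.mark.parametrize(
        "coeffs, expected",
        [
            ((0.0, 0.0, 1.0), (-2.0, 2.0, -2.0)),  # pure d_xy hole
            ((1.0, 0.0, 0.0), (2.0, 2.0, 2.0)),  # pure d_yz hole, spin-only
        ],
    )
    def test_limiting_holes(self, coeffs, expected):
        g = g_from_coefficients(HoleCoefficients(*coeffs))
        assert g.as_array() == pytest.approx(expected, abs=1e-12)

    def test_published_ba_coefficients_reproduce_g(self):
        """Rounded printed coefficients re-predict the printed g values."""
        coeffs = HoleCoefficients.from_unnormalized(0.07, 0.04, 1.00)
        g = g_from_coefficients(coeffs)
        resid = np.linalg.norm(g.as_array() - np.array(TABLE1["BA"]["g"]))
        assert resid < 0.02  # self-consistency limit of 2-decimal rounding

    def test_unnormalized_input_rejected(self):
        with pytest.raises(NormalizationError):
            g_from_coefficients(HoleCoefficients(0.5, 0.5, 0.5))

    def test_kramers_phase_invariance(self):
        a, b, c = 0.0716, 0.0380, 0.9967
        n = np.linalg.norm([a, b, c])
        plus = g_from_coefficients(HoleCoefficients(a / n, b / n, c / n))
        minus = g_from_coefficients(HoleCoefficients(-a / n, -b / n, -c / n))
        assert plus.as_array() == pytest.approx(minus.as_array(), abs=1e-14)


class TestInversion:
    @pytest.mark.parametrize("form", ["BA", "Aq"])
    def test_table_scaled_coefficients(self, form):
        coeffs = coefficients_from_g(SignedGTensor(*TABLE1[form]["g"]))
        scaled = np.round(coeffs.table_scaled(), 2)
        assert tuple(scaled) == TABLE1[form]["coeffs_scaled"]

    def test_pure_dxy_hole(self):
        coeffs = coefficients_from_g(SignedGTensor(-2, 2, -2))
        assert coeffs.as_array() == pytest.approx([0, 0, 1], abs=1e-12)

    def test_isotropic_degenerate_flagged(self):
        with pytest.raises(DegenerateAssignmentError):
            ligand_field_from_g(SignedGTensor(2.0, 2.0, 2.0))

    @given(
        st.tuples(
            st.floats(0.0, 0.3),
            st.floats(0.0, 0.2),
            st.floats(0.7, 1.0),
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity(self, raw):
        """coefficients_from_g o g_from_coefficients is the identity."""
        coeffs = HoleCoefficients.from_unnormalized(*raw)
        back = coefficients_from_g(g_from_coefficients(coeffs))
        assert back.as_array() == pytest.approx(coeffs.as_array(), abs=1e-9)


class TestLigandFieldParameters:
    @pytest.mark.parametrize("form, rtol", [("BA", 0.01), ("Aq", 0.002)])
    def test_splittings_match_published(self, form, rtol):
        row = TABLE1[form]
        p = ligand_field_from_g(SignedGTensor(*row["g"]), zeta=380.0)
        assert p.delta == pytest.approx(row["delta"], rel=rtol)
        assert abs(p.v) == pytest.approx(row["v_abs"], rel=rtol)
        assert round(p.rhombicity, 2) == row["rhombicity"]

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_rhombicity_independent_of_zeta(self, scale):
        g = SignedGTensor(*TABLE1["BA"]["g"])
        assert ligand_field_from_g(g, zeta=380.0 * scale).rhombicity == pytest.approx(
            ligand_field_from_g(g, zeta=380.0).rhombicity, rel=1e-12
        )


class TestPredictedTransitions:
    @pytest.mark.parametrize(
        "delta, v, expected",
        [
            (-4030, 2560, (2750, 5310)),  # upper prints as 5300 (rounding)
            (-5010, 2320, (3850, 6170)),
            (-5000, 0, (5000, 5000)),  # axial limit
        ],
    )
    def test_examples(self, delta, v, expected):
        t = predicted_transitions(LigandFieldParameters(delta, v, 380.0))
        assert (t.trans1, t.trans2) == pytest.approx(expected, abs=1e-9)
        assert t.trans2 - t.trans1 == pytest.approx(abs(v), abs=1e-9)

    def test_unphysical_ordering_rejected(self):
        with pytest.raises(OrderingError):
            predicted_transitions(LigandFieldParameters(-1000, 2500, 380.0))


class TestSOCGroundDoublet:
    def test_zeta_to_zero_limit_recovers_orbital_gaps(self):
        _, energies = soc_ground_doublet(-5000.0, 1000.0, 1e-6)
        gaps = np.array(energies) - energies[0]
        assert gaps == pytest.approx([0.0, 4500.0, 5500.0], abs=1e-3)

    def test_aq_calibration(self):
        """The fixed sign convention reproduces the aqueous-form g values."""
        coeffs, _ = soc_ground_doublet(-5010.0, 2320.0, 380.0)
        g = g_from_coefficients(coeffs)
        assert g.as_array() == pytest.approx(TABLE1["Aq"]["g"], abs=0.02)

    def test_moment_route_equals_closed_forms(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            delta = -rng.uniform(2000, 9000)
            v = rng.uniform(50, 2 * abs(delta) / 3)
            zeta = rng.uniform(200, 600)
            coeffs, _ = soc_ground_doublet(delta, v, zeta)
            g_closed = g_from_coefficients(coeffs).as_array()
            g_moment = doublet_g_values(delta, v, zeta).as_array()
            assert np.abs(g_closed - g_moment).max() < 1e-8

    def test_forward_inverse_roundtrip(self):
        """Taylor inversion of SOC-generated g recovers the input splittings."""
        coeffs, _ = soc_ground_doublet(-4000.0, 2000.0, 380.0)
        p = ligand_field_from_g(g_from_coefficients(coeffs), zeta=380.0)
        assert p.delta == pytest.approx(-4000.0, rel=0.01)
        assert p.v == pytest.approx(2000.0, rel=0.01)


class TestAssignment:
    def test_ba_magnitudes_rank_published_pattern_first(self):
        top = assign_g_tensor((2.28, 2.14, 1.97))[0]
        assert top.signs == (-1, 1, -1)
        # largest |g| lands on y, positive; mid on x, negative
        assert top.g.g_y == pytest.approx(2.28)
        assert top.g.g_x == pytest.approx(-2.14)
        assert top.parameters.rhombicity <= 1 / 3

    def test_isotropic_input_returns_degenerate_flagged_candidates(self):
        cands = assign_g_tensor((2.0, 2.0, 2.0))
        assert cands
        # the spin-only hole is self-consistent; splitting-degenerate
        # hypotheses are flagged with parameters=None rather than dropped
        assert cands[0].residual == pytest.approx(0.0, abs=1e-12)
        assert any(c.parameters is None for c in cands)

    def test_inconsistent_magnitudes_warn(self):
        with pytest.warns(UserWarning, match="threshold"):
            assign_g_tensor((2.28, 2.14, 1.97), residual_threshold=1e-4)

    def test_noisy_recovery_rate(self):
        """True assignment ranks first in >= 95/100 seeded noisy trials."""
        coeffs, _ = soc_ground_doublet(-4000.0, 2000.0, 380.0)
        g_true = g_from_coefficients(coeffs).as_array()
        signs_true = tuple(int(np.sign(v)) for v in g_true)
        rng = np.random.default_rng(7)
        hits = sum(
            (
                (c := assign_g_tensor(tuple(np.abs(g_true + rng.normal(0, 0.005, 3))))[0])
                .permutation
                == ("x", "y", "z")
            )
            and c.signs == signs_true
            for _ in range(100)
        )
        assert hits >= 95
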
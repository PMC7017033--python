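"""The polynomial solubility surface and its sequence-level composition."""

import numpy as np
import pytest

from idpsol import (
    ALPHA_SYNUCLEIN,
    PUBLISHED_PARAMS,
    LipophilicityScale,
    ProteinSequence,
    isoelectric_point,
    lipophilicity_profile,
    net_charge,
    ph_sweep,
    predict_solubility,
    residue_lipophilicity,
    residue_solubility_profile,
    solubility_at_ph,
)
from idpsol.scales import AMINO_ACIDS


class TestPredictSolubility:
    def test_intercept_at_origin(self):
        assert predict_solubility(0.0, 0.0, PUBLISHED_PARAMS) == 38.24

    def test_hand_computed_point(self):
        # -97.82*0.1 - 0.00747*100 + 0.8770*10 + 38.24
        assert predict_solubility(0.1, 10.0, PUBLISHED_PARAMS) == pytest.approx(
            36.481, abs=1e-12
        )

    def test_slope_in_lipophilicity_is_alpha(self):
        h = 1e-3
        for q in (0.0, 5.0, 30.0):
            for lipo in (-0.5, 0.0, 0.7):
                fd = (
                    predict_solubility(lipo + h, q, PUBLISHED_PARAMS)
                    - predict_solubility(lipo - h, q, PUBLISHED_PARAMS)
                ) / (2 * h)
                assert fd == pytest.approx(PUBLISHED_PARAMS.alpha, rel=1e-9)

    def test_concave_in_charge_with_vertex(self):
        q = np.linspace(0.0, 120.0, 241)
        s = predict_solubility(np.zeros_like(q), q, PUBLISHED_PARAMS)
        second = np.diff(s, 2)
        assert np.all(second < 0)  # beta < 0
        vertex = PUBLISHED_PARAMS.charge_vertex
        assert vertex == pytest.approx(58.70, abs=0.005)
        assert abs(q[np.argmax(s)] - vertex) <= 0.5

    def test_negative_charge_magnitude_rejected(self):
        with pytest.raises(ValueError):
            predict_solubility(0.0, -1.0, PUBLISHED_PARAMS)


class TestSolubilityAtPh:
    def test_equals_manual_composition(self, scale, table, params):
        prof = lipophilicity_profile(ALPHA_SYNUCLEIN, 6.3, scale, table)
        q = net_charge(ALPHA_SYNUCLEIN, 6.3, table)
        manual = predict_solubility(prof.global_lipophilicity, q.abs_net_charge, params)
        score = solubility_at_ph(ALPHA_SYNUCLEIN, 6.3, params, scale, table)
        assert score.solubility == manual

    @pytest.mark.parametrize("ph", [3.0, 7.0, 11.0])
    def test_poly_ala_is_charge_free(self, ph, poly_ala_blocked, scale, table, params):
        score = solubility_at_ph(poly_ala_blocked, ph, params, scale, table)
        l_ala = residue_lipophilicity("A", ph, scale, table)
        assert score.solubility == pytest.approx(
            params.delta + params.alpha * l_ala, rel=1e-12
        )

    def test_charge_terms_vanish_at_the_pi(self, scale, table, params):
        pi = isoelectric_point(ALPHA_SYNUCLEIN, table, tol=1e-8)
        score = solubility_at_ph(ALPHA_SYNUCLEIN, pi, params, scale, table)
        assert score.solubility == pytest.approx(
            params.alpha * score.lipophilicity + params.delta, abs=1e-5
        )

    def test_alpha_synuclein_more_soluble_at_neutral_than_at_pi(
        self, scale, table, params
    ):
        # at the pI the protective charge contribution is zero
        at_pi = solubility_at_ph(ALPHA_SYNUCLEIN, 4.67, params, scale, table)
        neutral = solubility_at_ph(ALPHA_SYNUCLEIN, 7.4, params, scale, table)
        assert neutral.solubility > at_pi.solubility


class TestPhSweep:
    def test_grid_count(self, scale, table, params):
        seq = ProteinSequence(id="s", residues="ACDEFGHIKL")
        curve = ph_sweep(
            seq, params, scale, table, ph_min=2.0, ph_max=12.0, step=0.5, window=5
        )
        assert len(curve.ph) == 21
        assert np.all(np.diff(curve.ph) > 0)

    def test_non_ionizable_sequence_gives_flat_curve(
        self, poly_ala_blocked, scale, table, params
    ):
        curve = ph_sweep(poly_ala_blocked, params, scale, table, step=0.25)
        assert np.ptp(curve.solubility) == 0.0

    def test_coarse_minimum_matches_dense_scan(self, scale, table, params):
        # Lys/Arg-free acidic sequence: least soluble at the acidic end
        seq = ProteinSequence(id="acid", residues="GSDEAGSDEAGSDEAGSDEA")
        coarse = ph_sweep(seq, params, scale, table, ph_min=2.0, ph_max=12.0, step=0.5)
        dense = ph_sweep(seq, params, scale, table, ph_min=2.0, ph_max=12.0, step=0.05)
        coarse_argmin = coarse.ph[np.argmin(coarse.solubility)]
        dense_argmin = dense.ph[np.argmin(dense.solubility)]
        assert abs(coarse_argmin - dense_argmin) <= 0.5
        assert coarse_argmin <= 3.0  # acidic end

    def test_component_decomposition_identity(self, scale, table, params):
        curve = ph_sweep(ALPHA_SYNUCLEIN, params, scale, table, step=0.5)
        recomposed = (
            params.alpha * curve.lipophilicity
            + params.beta * curve.abs_net_charge**2
            + params.gamma * curve.abs_net_charge
            + params.delta
        )
        np.testing.assert_allclose(curve.solubility, recomposed, rtol=1e-12)

    def test_invalid_ranges_rejected(self, scale, table, params):
        seq = ProteinSequence(id="s", residues="ACDEFGHIKL")
        with pytest.raises(ValueError):
            ph_sweep(seq, params, scale, table, ph_min=5.0, ph_max=3.0)
        with pytest.raises(ValueError):
            ph_sweep(seq, params, scale, table, step=0.0)


class TestResidueSolubilityProfile:
    def test_homopolymer_is_flat(self, scale, table, params):
        seq = ProteinSequence(id="polyG", residues="G" * 25)
        prof = residue_solubility_profile(seq, 7.0, params, scale, table)
        assert np.ptp(prof.values) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_scale_shift_moves_scores_by_alpha_times_shift(
        self, scale, table, params
    ):
        const = 0.37
        shifted = LipophilicityScale(
            "shifted",
            {aa: scale.neutral(aa) + const for aa in AMINO_ACIDS},
            {aa: scale.charged(aa) + const for aa in AMINO_ACIDS},
        )
        seq = ProteinSequence(id="s", residues="GSDEAKGRHAYGSDEAKGRH")
        base = residue_solubility_profile(seq, 6.0, params, scale, table)
        moved = residue_solubility_profile(seq, 6.0, params, shifted, table)
        np.testing.assert_allclose(
            moved.values - base.values, params.alpha * const, rtol=1e-9
        )

    def test_profile_mean_equals_whole_chain_score(self, scale, table, params):
        # the charge term is shared, and the mean of window means is the
        # global lipophilicity, so the identity is exact
        seq = ProteinSequence(id="s", residues="GSDEAKGRHAYGSDEAKGRHMLVNQ")
        prof = residue_solubility_profile(seq, 7.0, params, scale, table)
        whole = solubility_at_ph(seq, 7.0, params, scale, table)
        assert np.mean(prof.values) == pytest.approx(whole.solubility, rel=1e-12)
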
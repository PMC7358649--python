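import numpy as np
import pytest
from hypothesis import given, strategies as st

from nrdecomp import composition_analysis as ca
from nrdecomp import materials as mat


class TestAreaPerLipid:
    def test_direct_arithmetic(self):
        assert ca.area_per_lipid(782.0, 20.0, 1.0) == pytest.approx(39.1)

    def test_inverse_proportionality_in_phi(self):
        a1 = ca.area_per_lipid(756.0, 14.0, 0.9)
        a2 = ca.area_per_lipid(756.0, 14.0, 0.45)
        assert a2 == pytest.approx(2 * a1)

    def test_round_trip_from_area(self):
        # set A, derive tau at given phi, recover A
        a_true, phi = 57.4, 0.894
        tau = 756.0 / (a_true * phi)
        assert ca.area_per_lipid(756.0, tau, phi) == pytest.approx(a_true, abs=1e-9)

    @given(
        tau=st.floats(5.0, 30.0),
        phi=st.floats(0.3, 1.0),
        dtau=st.floats(0.1, 5.0),
    )
    def test_strictly_decreasing_in_tau_and_phi(self, tau, phi, dtau):
        a = ca.area_per_lipid(756.0, tau, phi)
        assert ca.area_per_lipid(756.0, tau + dtau, phi) < a
        if phi <= 0.95:
            assert ca.area_per_lipid(756.0, tau, phi + 0.05) < a

    def test_domain_errors(self):
        with pytest.raises(ca.AnalysisError):
            ca.area_per_lipid(756.0, 0.0, 0.9)
        with pytest.raises(ca.AnalysisError):
            ca.area_per_lipid(756.0, 14.0, 0.0)


class TestAssignPhase:
    @pytest.mark.parametrize(
        "area, expected",
        [(57.4, "liquid_crystalline"), (49.0, "liquid_crystalline"),
         (45.4, "gel"), (45.0, "gel")],
    )
    def test_reported_areas_classify_as_reported(self, area, expected):
        assert ca.assign_phase(area) == expected

    def test_threshold_tie_goes_to_fluid(self):
        assert ca.assign_phase(ca.DEFAULT_PHASE_THRESHOLD) == "liquid_crystalline"

    def test_threshold_is_configurable(self):
        assert ca.assign_phase(48.0, threshold=50.0) == "gel"


class TestHelixLength:
    def test_21_residue_ideal_helix(self):
        assert ca.helix_length(21) == pytest.approx(3.15, abs=1e-12)

    def test_zero_and_linearity(self):
        assert ca.helix_length(0) == 0.0
        assert ca.helix_length(42) == pytest.approx(2 * ca.helix_length(21), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ca.AnalysisError):
            ca.helix_length(-1)


SLDS = {
    "lipid": {"d2o": -0.39e-6, "h2o": -0.39e-6},
    "pep": {"d2o": 3.99e-6, "h2o": 2.85e-6},
    "solvent": {"d2o": 6.36e-6, "h2o": -0.56e-6},
}


def compose(phi_l, phi_p, phi_s):
    return {
        c: SLDS["lipid"][c] * phi_l + SLDS["pep"][c] * phi_p + SLDS["solvent"][c] * phi_s
        for c in ("d2o", "h2o")
    }


class TestPeptideVolumeFraction:
    def test_pure_lipid_layer(self):
        vf = ca.peptide_volume_fraction(
            SLDS["lipid"], SLDS["lipid"], SLDS["pep"], SLDS["solvent"]
        )
        assert vf.phi_lipid == pytest.approx(1.0, abs=1e-10)
        assert vf.phi_peptide == pytest.approx(0.0, abs=1e-10)

    def test_pure_solvent_layer(self):
        vf = ca.peptide_volume_fraction(
            SLDS["solvent"], SLDS["lipid"], SLDS["pep"], SLDS["solvent"]
        )
        assert vf.phi_solvent == pytest.approx(1.0, abs=1e-10)

    def test_compose_then_invert(self):
        vf = ca.peptide_volume_fraction(
            compose(0.7, 0.2, 0.1), SLDS["lipid"], SLDS["pep"], SLDS["solvent"]
        )
        assert vf.as_tuple() == pytest.approx((0.7, 0.2, 0.1), abs=1e-10)

    def test_round_trip_identity_on_random_triples(self):
        rng = np.random.default_rng(314159)
        for _ in range(1000):
            phi = rng.dirichlet([1.0, 1.0, 1.0])
            vf = ca.peptide_volume_fraction(
                compose(*phi), SLDS["lipid"], SLDS["pep"], SLDS["solvent"]
            )
            assert np.allclose(vf.as_tuple(), phi, atol=1e-10)
            assert vf.residual <= 1e-10

    def test_degenerate_contrasts_rejected(self):
        same = {"d2o": 1e-6, "h2o": 1e-6}
        with pytest.raises(ca.AnalysisError, match="degenerate"):
            ca.peptide_volume_fraction(same, same, same, same)

    def test_single_contrast_rejected(self):
        with pytest.raises(ca.AnalysisError):
            ca.peptide_volume_fraction(
                {"d2o": 1e-6}, {"d2o": 0.0}, {"d2o": 2e-6}, {"d2o": 6e-6}
            )

    def test_out_of_range_solution_flagged(self):
        layer = {"d2o": 8.0e-6, "h2o": -1.5e-6}  # beyond any component mixture
        vf = ca.peptide_volume_fraction(
            layer, SLDS["lipid"], SLDS["pep"], SLDS["solvent"]
        )
        assert vf.clipped


@pytest.fixture(scope="module")
def peptide():
    return mat.mac1()


def leaflet_slds(peptide, scenario, phi_p_in, phi_p_out, phi_s_in=0.1, phi_s_out=0.1):
    lipid = {c: -0.39e-6 for c in ("d2o", "h2o")}
    solvent = {"d2o": 6.36e-6, "h2o": -0.56e-6}
    dfrac = {"d2o": 1.0, "h2o": 0.0}
    seg_in, seg_out = {
        "uneven": ("whole", "whole"),
        "n_in": ("n_half", "c_half"),
        "n_out": ("c_half", "n_half"),
    }[scenario]
    inner, outer = {}, {}
    for c in ("d2o", "h2o"):
        pin = mat.peptide_sld(peptide, dfrac[c], seg_in)
        pout = mat.peptide_sld(peptide, dfrac[c], seg_out)
        inner[c] = lipid[c] * (1 - phi_p_in - phi_s_in) + pin * phi_p_in + solvent[c] * phi_s_in
        outer[c] = lipid[c] * (1 - phi_p_out - phi_s_out) + pout * phi_p_out + solvent[c] * phi_s_out
    return inner, outer, lipid, solvent


class TestOrientationScenarios:
    def test_oriented_truth_identified(self, peptide):
        inner, outer, lipid, solvent = leaflet_slds(peptide, "n_in", 0.18, 0.18)
        sc = ca.orientation_scenarios(inner, outer, peptide, lipid, solvent)
        assert sc.oriented["n_in"]["residual"] == pytest.approx(0.0, abs=1e-15)
        assert sc.oriented["n_in"]["residual"] < sc.oriented["n_out"]["residual"]
        assert sc.best == "n_in"
        assert sc.oriented["n_in"]["phi_peptide"] == pytest.approx(0.18, abs=1e-9)

    def test_uneven_truth_identified(self, peptide):
        inner, outer, lipid, solvent = leaflet_slds(peptide, "uneven", 0.10, 0.22)
        sc = ca.orientation_scenarios(inner, outer, peptide, lipid, solvent)
        assert sc.uneven_residual == pytest.approx(0.0, abs=1e-15)
        assert sc.best == "uneven"
        assert sc.uneven["inner"].phi_peptide == pytest.approx(0.10, abs=1e-9)
        assert sc.uneven["outer"].phi_peptide == pytest.approx(0.22, abs=1e-9)

    def test_swapping_leaflets_swaps_orientations(self, peptide):
        inner, outer, lipid, solvent = leaflet_slds(peptide, "n_in", 0.18, 0.18,
                                                    phi_s_in=0.08, phi_s_out=0.14)
        a = ca.orientation_scenarios(inner, outer, peptide, lipid, solvent)
        b = ca.orientation_scenarios(outer, inner, peptide, lipid, solvent)
        assert a.oriented["n_in"]["residual"] == pytest.approx(
            b.oriented["n_out"]["residual"], rel=1e-12, abs=1e-18
        )
        assert a.oriented["n_out"]["residual"] == pytest.approx(
            b.oriented["n_in"]["residual"], rel=1e-12, abs=1e-18
        )

    def test_large_uncertainty_flags_indistinguishable(self, peptide):
        inner, outer, lipid, solvent = leaflet_slds(peptide, "n_in", 0.18, 0.18)
        sc = ca.orientation_scenarios(
            inner, outer, peptide, lipid, solvent, sld_uncertainty=1e-5
        )
        assert sc.indistinguishable

    def test_symmetric_labeling_rejected(self):
        p = mat.mac1(deuterated=False)
        inner, outer, lipid, solvent = leaflet_slds(p, "uneven", 0.1, 0.2)
        with pytest.raises(ca.AnalysisError, match="symmetric"):
            ca.orientation_scenarios(inner, outer, p, lipid, solvent)
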
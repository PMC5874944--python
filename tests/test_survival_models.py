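import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

import gridtr
from gridtr.survival_models import _HK_BETA_COEFF, _hk_from_k3


def truncate3(x: float) -> float:
    return math.floor(x * 1000) / 1000


class TestLQDerivation:
    # printed reference values are truncated, not rounded, to three decimals
    @pytest.mark.parametrize(
        ("sf2", "alpha_beta", "alpha3", "beta3"),
        [
            (0.2, 10.0, 0.670, 0.067),
            (0.4, 10.0, 0.381, 0.038),
            (0.5, 10.0, 0.288, 0.028),
            (0.4, 2.5, 0.254, 0.101),
        ],
    )
    def test_reference_alpha_beta_extraction(self, sf2, alpha_beta, alpha3, beta3):
        params = gridtr.derive_lq_params(sf2, alpha_beta)
        assert truncate3(params.alpha) == pytest.approx(alpha3, abs=1e-12)
        assert truncate3(params.beta) == pytest.approx(beta3, abs=1e-12)

    def test_pure_exponential_limit(self):
        params = gridtr.derive_lq_params(0.5, 1e12)
        assert params.alpha == pytest.approx(-math.log(0.5) / 2, rel=1e-9)
        assert params.beta == pytest.approx(0.0, abs=1e-12)

    @given(sf2=st.floats(0.01, 0.99), alpha_beta=st.floats(0.5, 50.0))
    def test_sf2_round_trip(self, sf2, alpha_beta):
        params = gridtr.derive_lq_params(sf2, alpha_beta)
        assert abs(gridtr.sf_lq(params, 2.0) - sf2) < 1e-12

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_sf2_domain_error(self, bad):
        with pytest.raises(ValueError):
            gridtr.derive_lq_params(bad, 10.0)

    def test_sensitivity_class_thresholds(self, cell_lines):
        expected = {
            "parotid": "radiosensitive",
            "liposarcoma": "radiosensitive",
            "tonsil": "radiosensitive",
            "base_of_tongue": "semisensitive",
            "adenocarcinoma": "semisensitive",
            "colorectal": "semisensitive",
            "larynx": "radioresistant",
            "nasopharynx": "radioresistant",
            "retromolar_trigone": "radioresistant",
            "sarcoma": "radioresistant",
            "melanoma": "radioresistant",
            "scc": "radioresistant",
            "osteosarcoma": "radioresistant",
            "leiomyosarcoma": "radioresistant",
        }
        for name, klass in expected.items():
            assert cell_lines[name].sensitivity_class == klass, name


class TestLQSurvival:
    def test_sf_at_two_gray_is_sf2(self, tumor_classes):
        for params in tumor_classes.values():
            assert gridtr.sf_lq(params, 2.0) == pytest.approx(params.sf2, abs=1e-14)

    def test_zero_dose_full_survival(self, tumor_classes):
        assert gridtr.sf_lq(tumor_classes["semisensitive"], 0.0) == 1.0

    def test_semisensitive_ten_gray(self, tumor_classes):
        assert gridtr.sf_lq(tumor_classes["semisensitive"], 10.0) == pytest.approx(
            4.8e-4, rel=0.01
        )

    def test_negative_dose_rejected(self, tumor_classes):
        with pytest.raises(ValueError):
            gridtr.sf_lq(tumor_classes["semisensitive"], -1.0)

    @given(d1=st.floats(0.0, 30.0), d2=st.floats(0.0, 30.0))
    def test_strictly_decreasing_in_dose(self, tumor_classes, d1, d2):
        lo, hi = sorted((d1, d2))
        assume(hi - lo > 1e-6)  # below float resolution of exp() near SF=1
        params = tumor_classes["radioresistant"]
        assert gridtr.sf_lq(params, hi) < gridtr.sf_lq(params, lo)


class TestHKModel:
    def test_parameter_relations_hold_exactly(self, tumor_classes, normal_tissue):
        for params in (*tumor_classes.values(), normal_tissue):
            hk = gridtr.fit_hk_params(params)
            r_alpha, r_beta = hk.relation_residuals()
            assert abs(r_alpha) < 1e-9
            assert abs(r_beta) < 1e-9
            assert min(hk.k1, hk.k2, hk.k3) > 0

    def test_zero_dose_full_survival(self, tumor_classes):
        hk = gridtr.fit_hk_params(tumor_classes["radioresistant"])
        assert gridtr.sf_hk(hk, 0.0) == 1.0

    def test_high_dose_survival_exceeds_lq(self, tumor_classes, normal_tissue):
        # the quadratic LQ term over-predicts kill at high dose; H-K relaxes it
        for params in (*tumor_classes.values(), normal_tissue):
            hk = gridtr.fit_hk_params(params)
            assert gridtr.sf_hk(hk, 20.0) >= gridtr.sf_lq(params, 20.0)

    def test_tracks_lq_over_calibration_range(self, tumor_classes, normal_tissue):
        # tracking error concentrates at the range edge and scales with beta;
        # worst case (normal tissue, beta ~ 0.10 / Gy^2) stays below 0.4 in
        # log-survival, i.e. the two curves agree within a factor ~1.5 even
        # at the 10 Gy calibration edge, and far closer below 8 Gy
        doses = np.linspace(0.1, 10.0, 100)
        for params in (*tumor_classes.values(), normal_tissue):
            hk = gridtr.fit_hk_params(params)
            gap = np.log(gridtr.sf_hk(hk, doses)) - np.log(gridtr.sf_lq(params, doses))
            assert np.max(np.abs(gap)) < 0.4

    def test_fit_matches_brute_force_grid_search(self, tumor_classes):
        # independent oracle: dense scan of the 1-D calibration objective
        params = tumor_classes["radioresistant"]
        doses = np.linspace(0.0, 10.0, 401)[1:]
        lq_log = -params.alpha * doses - params.beta * doses**2

        def objective(k3):
            k1, k2, _ = _hk_from_k3(params, k3)
            return np.sum((-k1 * doses + k2 * (1 - np.exp(-k3 * doses)) - lq_log) ** 2)

        grid = np.geomspace(1e-3, 5.0, 4000)
        k3_grid = grid[int(np.argmin([objective(k) for k in grid]))]
        hk = gridtr.fit_hk_params(params)
        assert hk.k3 == pytest.approx(k3_grid, rel=5e-3)
        assert objective(hk.k3) <= objective(k3_grid) * (1 + 1e-9)

    def test_optimal_k3_shared_across_lines(self, tumor_classes, normal_tissue):
        # the calibration objective scales as beta^2, so k3 is line-independent
        k3s = {
            gridtr.fit_hk_params(p).k3
            for p in (*tumor_classes.values(), normal_tissue)
        }
        assert max(k3s) - min(k3s) < 1e-6

    @given(d1=st.floats(0.0, 30.0), d2=st.floats(0.0, 30.0))
    def test_strictly_decreasing_in_dose(self, tumor_classes, d1, d2):
        lo, hi = sorted((d1, d2))
        assume(hi - lo > 1e-6)
        hk = gridtr.fit_hk_params(tumor_classes["semisensitive"])
        assert gridtr.sf_hk(hk, hi) < gridtr.sf_hk(hk, lo)

    def test_beta_coefficient_identity(self):
        # the printed beta relation equals exact LQ/H-K curve agreement at
        # dose ln2/k3; sanity-check the coefficient
        assert _HK_BETA_COEFF == pytest.approx(
            (math.log(2) - 0.5) / math.log(2) ** 2, abs=1e-15
        )


def test_catalogue_classes_match_definitions(cell_lines):
    assert cell_lines["radiosensitive"].sf2 == 0.2
    assert cell_lines["semisensitive"].sf2 == 0.4
    assert cell_lines["radioresistant"].sf2 == 0.5
    assert cell_lines["normal"].alpha_beta == 2.5
    for name in ("radiosensitive", "semisensitive", "radioresistant"):
        assert cell_lines[name].alpha_beta == 10.0
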
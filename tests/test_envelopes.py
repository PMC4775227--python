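"""Bimodal deconvolution: mixture evaluation, global fits, splits, uptake."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hdxthermo as ht
from hdxthermo.envelopes import BimodalSeriesModel, IsotopeCluster, centroid


def make_cluster(mz, intensity, condition_value=20.0, ctype="temperature_C"):
    return IsotopeCluster("159-168", 1, ctype, condition_value,
                          np.asarray(mz, float), np.asarray(intensity, float))


class TestClusterInvariants:
    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            make_cluster([1.0, 2.0, 3.0], [1, 1, 1])

    def test_non_monotone_mz_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_cluster([1.0, 2.0, 1.5, 3.0], [1, 1, 1, 1])

    def test_irregular_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            make_cluster([0.0, 1.0, 2.0, 3.9], [1, 1, 1, 1])


class TestEvaluateBimodal:
    def test_single_gaussian_peak_height(self):
        v = ht.evaluate_bimodal(5.0, a1=2.0, a2=0.0, mu1_bar=5.0, mu2_bar=9.0,
                                sigma=0.5)
        assert v == pytest.approx(2.0 / (0.5 * np.sqrt(2 * np.pi)))

    def test_standard_normal_density_value(self):
        v = ht.evaluate_bimodal(1.0, a1=1.0, a2=0.0, mu1_bar=0.0, mu2_bar=10.0,
                                sigma=1.0)
        assert v == pytest.approx(0.24197072451914337, rel=1e-12)

    def test_symmetry_at_midpoint(self):
        mid = 0.5 * (3.0 + 7.0)
        v = ht.evaluate_bimodal(mid, 1.5, 1.5, 3.0, 7.0, 1.0)
        half = ht.evaluate_bimodal(mid, 1.5, 0.0, 3.0, 7.0, 1.0)
        assert v == pytest.approx(2 * half)

    def test_component_exchange_symmetry(self):
        mu = np.linspace(0, 10, 21)
        a = ht.evaluate_bimodal(mu, 1.0, 2.5, 3.0, 7.0, 0.8)
        b = ht.evaluate_bimodal(mu, 2.5, 1.0, 7.0, 3.0, 0.8)
        np.testing.assert_allclose(a, b)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ht.evaluate_bimodal(1.0, 1.0, 1.0, 0.0, 1.0, 0.0)


class TestGlobalSeriesFit:
    def test_noise_free_round_trip(self, noise_free_thermal_series):
        scen, clusters, fr = noise_free_thermal_series
        fit = ht.fit_bimodal_series(clusters)
        assert fit.converged_
        assert fit.mu1_bar_ == pytest.approx(scen.centroid_low, rel=1e-6)
        assert fit.mu2_bar_ == pytest.approx(scen.centroid_high, rel=1e-6)
        assert fit.sigma_ == pytest.approx(scen.sigma_true, rel=1e-6)
        np.testing.assert_allclose(fit.f_high_, fr, atol=1e-6)

    def test_pure_low_series_flags_mu2_unidentifiable(self):
        scen = ht.ExchangeScenario(
            noise_rel=0.0,
            fraction_law=ht.ExplicitFractions((0.0,) * 4),
            condition_values=(20.0, 25.0, 30.0, 35.0),
        )
        clusters, _ = ht.simulate_series(scen)
        fit = ht.fit_bimodal_series(clusters)
        assert not fit.mu2_identifiable_
        assert fit.mu1_identifiable_
        assert np.all(fit.areas_[:, 1] / fit.areas_.sum(axis=1) < 0.02)

    def test_mixed_peptides_rejected(self, noise_free_thermal_series):
        _, clusters, _ = noise_free_thermal_series
        other = IsotopeCluster("389-395", 1, "temperature_C", 20.0,
                               clusters[0].mz, clusters[0].intensity)
        with pytest.raises(ValueError, match="mixes"):
            ht.fit_bimodal_series(clusters + [other])

    def test_label_order_mu1_below_mu2(self):
        # falling series: high-exchanging fraction decreases with condition
        scen = ht.ExchangeScenario(
            noise_rel=0.0,
            fraction_law=ht.ExplicitFractions((0.9, 0.6, 0.3, 0.1)),
            condition_values=(20.0, 25.0, 30.0, 35.0),
        )
        clusters, fr = ht.simulate_series(scen)
        fit = ht.fit_bimodal_series(clusters)
        assert fit.mu1_bar_ < fit.mu2_bar_
        np.testing.assert_allclose(fit.f_high_, fr, atol=1e-6)

    def test_controls_inform_initialization_only(self, noise_free_thermal_series,
                                                 controls):
        scen, clusters, fr = noise_free_thermal_series
        _, unexchanged, full = controls
        fit = ht.fit_bimodal_series(clusters + [unexchanged, full])
        assert len(fit.conditions_) == len(clusters)
        np.testing.assert_allclose(fit.f_high_, fr, atol=1e-6)

    def test_area_grid_search_oracle(self):
        """Per-spectrum areas match a dense (total, fraction) grid search."""
        scen = ht.ExchangeScenario(seed=2, noise_rel=0.02)
        clusters, _ = ht.simulate_series(scen)
        fit = ht.fit_bimodal_series(clusters)
        for i, cl in enumerate(clusters):
            total_fit = fit.areas_[i].sum()
            best = np.inf
            for tot in np.linspace(0.7, 1.3, 61) * max(total_fit, 1e-12):
                for g in np.linspace(0.0, 1.0, 201):
                    model = ht.evaluate_bimodal(
                        cl.mz, (1 - g) * tot, g * tot,
                        fit.mu1_bar_, fit.mu2_bar_, fit.sigma_)
                    best = min(best, float(np.sum((model - cl.intensity) ** 2)))
            assert fit.residual_sse_[i] <= best * 1.01 + 1e-12


class TestSplit:
    def test_intensity_conservation_exact(self):
        scen = ht.ExchangeScenario(seed=4, noise_rel=0.02)
        clusters, _ = ht.simulate_series(scen)
        fit = ht.fit_bimodal_series(clusters)
        for cl in clusters:
            sp = ht.split_peak_intensities(cl, fit)
            np.testing.assert_array_equal(
                sp.intensity_low + sp.intensity_high, cl.intensity)

    def test_single_component_gives_f_high_zero(self):
        scen = ht.ExchangeScenario(
            noise_rel=0.0,
            fraction_law=ht.ExplicitFractions((0.0,) * 4),
            condition_values=(20.0, 25.0, 30.0, 35.0),
        )
        clusters, _ = ht.simulate_series(scen)
        fit = ht.fit_bimodal_series(clusters)
        sp = ht.split_peak_intensities(clusters[0], fit)
        assert sp.f_high == pytest.approx(0.0, abs=1e-6)
        assert sp.f_low == pytest.approx(1.0, abs=1e-6)

    def test_exactly_zero_second_area_gives_f_high_zero(self):
        fit = BimodalSeriesModel()
        fit.mu1_bar_, fit.mu2_bar_, fit.sigma_ = 1157.5, 1161.5, 1.0
        fit.areas_ = np.array([[2.0, 0.0]])
        fit.conditions_ = [("temperature_C", 20.0)]
        fit.converged_ = True
        cl = make_cluster([1156.0, 1157.0, 1158.0, 1159.0], [1, 3, 3, 1])
        sp = fit.split(cl)
        assert sp.f_high == 0.0

    def test_known_fraction_recovered(self):
        scen = ht.ExchangeScenario(
            noise_rel=0.0,
            fraction_law=ht.ExplicitFractions((0.1, 0.3, 0.6, 0.9)),
            condition_values=(20.0, 25.0, 30.0, 35.0),
        )
        clusters, _ = ht.simulate_series(scen)
        fit = ht.fit_bimodal_series(clusters)
        sp = ht.split_peak_intensities(clusters[1], fit)
        assert sp.f_high == pytest.approx(0.30, abs=0.005)

    def test_midway_peak_splits_evenly_for_equal_areas(self):
        fit = BimodalSeriesModel()
        fit.mu1_bar_, fit.mu2_bar_, fit.sigma_ = 4.0, 8.0, 1.0
        fit.areas_ = np.array([[1.0, 1.0]])
        fit.conditions_ = [("temperature_C", 20.0)]
        fit.converged_ = True
        cl = make_cluster([4.0, 5.0, 6.0, 7.0, 8.0], [1, 1, 2, 1, 1])
        sp = fit.split(cl)
        assert sp.intensity_low[2] == pytest.approx(1.0)
        assert sp.intensity_high[2] == pytest.approx(1.0)

    def test_degenerate_peaks_split_half_with_warning(self):
        fit = BimodalSeriesModel()
        fit.mu1_bar_, fit.mu2_bar_, fit.sigma_ = 5.0, 5.5, 1e-3
        fit.areas_ = np.array([[1.0, 1.0]])
        fit.conditions_ = [("temperature_C", 20.0)]
        fit.converged_ = True
        cl = make_cluster([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        with pytest.warns(UserWarning, match="tails"):
            sp = fit.split(cl)
        np.testing.assert_allclose(sp.intensity_low, 0.5 * cl.intensity)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=50))
    def test_f_high_invariant_under_uniform_rescaling(self, scale, seed):
        scen = ht.ExchangeScenario(seed=seed, noise_rel=0.02,
                                   condition_values=(20.0, 32.0, 36.0, 40.0))
        clusters, _ = ht.simulate_series(scen)
        fit = ht.fit_bimodal_series(clusters)
        cl = clusters[2]
        sp = fit.split(cl)
        scaled = IsotopeCluster(cl.peptide_id, cl.charge, cl.condition_type,
                                cl.condition_value, cl.mz, cl.intensity * scale)
        sp2 = fit.split(scaled)
        assert 0.0 <= sp2.f_high <= 1.0
        assert sp2.f_high == pytest.approx(sp.f_high, rel=1e-9)


class TestUptake:
    def test_control_identities_and_linearity(self, controls):
        scen, unexchanged, full = controls
        res0 = ht.centroid_uptake(unexchanged, unexchanged, full, 8)
        assert res0.corrected_deuterons == pytest.approx(0.0, abs=1e-9)
        res1 = ht.centroid_uptake(full, unexchanged, full, 8)
        assert res1.corrected_deuterons == pytest.approx(8.0, abs=1e-9)
        mid = ht.simulate_isotope_envelope(scen, 0.5)
        resm = ht.centroid_uptake(mid, unexchanged, full, 8)
        # grid discretization limits the half-mixture identity to ~1e-5
        assert resm.corrected_deuterons == pytest.approx(4.0, abs=1e-4)
        assert resm.deuterons == pytest.approx(
            (centroid(mid) - centroid(unexchanged)) * scen.charge)

    def test_inverted_controls_rejected(self, controls):
        _, unexchanged, full = controls
        with pytest.raises(ValueError, match="exceed"):
            ht.centroid_uptake(full, full, unexchanged, 8)


class TestUptakeDifference:
    def test_reference_condition_maps_to_zero(self):
        df = pd.DataFrame({
            "peptide_id": ["p1"] * 3,
            "condition_value": [20.0, 36.0, 42.0],
            "uptake": [2.0, 3.0, 5.0],
            "sem": [0.1, 0.1, 0.2],
        })
        out = ht.uptake_difference(df, 20.0)
        ref_row = out[out["condition_value"] == 20.0]
        assert ref_row["delta_uptake"].iloc[0] == 0.0

    def test_sem_propagates_in_quadrature(self):
        df = pd.DataFrame({
            "peptide_id": ["p1", "p1"],
            "condition_value": [20.0, 42.0],
            "uptake": [2.0, 5.0],
            "sem": [0.1, 0.1],
        })
        out = ht.uptake_difference(df, 20.0)
        d = out[out["condition_value"] == 42.0]["delta_sem"].iloc[0]
        assert d == pytest.approx(np.sqrt(0.02), rel=1e-12)

    def test_rising_fraction_gives_positive_differences(self, controls):
        scen, unexchanged, full = controls
        law = ht.ThermalLaw()
        rows = []
        for t in (20.0, 36.0, 40.0, 42.0):
            cl = ht.simulate_isotope_envelope(scen, float(law(t)))
            up = ht.centroid_uptake(cl, unexchanged, full, 8)
            rows.append({"peptide_id": "hrc", "condition_value": t,
                         "uptake": up.corrected_deuterons})
        out = ht.uptake_difference(pd.DataFrame(rows), 20.0)
        above = out[out["condition_value"] > 20.0]
        assert np.all(above["delta_uptake"] > 0)

    def test_missing_reference_named(self):
        df = pd.DataFrame({"peptide_id": ["p9"], "condition_value": [42.0],
                           "uptake": [1.0]})
        with pytest.raises(ValueError, match="p9"):
            ht.uptake_difference(df, 20.0)
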
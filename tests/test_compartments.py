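"""Compartment attribution, oil estimation, water partitioning and kinetics."""

import numpy as np
import pytest

from seednmr.compartments import (
    AttributionError,
    Calibration,
    ManualFit,
    assign_compartments,
    estimate_oil,
    fit_kinetics,
    partition_water,
    synthetic_seed_sample,
)
from seednmr.core import (
    AcquisitionConfig,
    ComponentSet,
    InvalidModelError,
    SampleMeta,
    simulate_imbibition_series,
)
from seednmr.discrete import MultiExponentialModel
from seednmr.reference import REFERENCE_WATER, reference_set

DRY_LABELS = ["solid", "exchangeable", "oil_intracellular_water", "oil_mucilage_water"]


def unlabeled(name):
    cs = reference_set(name)
    return ManualFit(ComponentSet.from_amplitudes(cs.amplitudes, cs.t2s,
                                                  state=cs.state), 100.0)


class TestAssignment:
    def test_dry_four_components(self):
        labelled = assign_compartments(unlabeled("wt-dry"), "dry")
        assert list(labelled.labels) == DRY_LABELS

    def test_imbibed_fifth_is_external_water(self):
        labelled = assign_compartments(unlabeled("wt-imb-24h"), "imbibed")
        assert labelled.labels[-1] == "external_water"
        assert list(labelled.labels[:4]) == DRY_LABELS

    def test_component_count_guard(self):
        fit = ManualFit(ComponentSet.from_amplitudes([60, 40], [1.0, 100.0]), 100.0)
        with pytest.raises(AttributionError):
            assign_compartments(fit, "imbibed")

    def test_slow_solid_flagged_not_relabelled(self):
        cs = ComponentSet.from_amplitudes([40, 30, 20, 10], [0.5, 5.0, 50.0, 500.0])
        with pytest.warns(UserWarning, match="unusually slow"):
            labelled = assign_compartments(ManualFit(cs, 100.0), "dry")
        assert labelled.labels[0] == "solid"  # flagged, never silently changed


class TestOil:
    @pytest.mark.parametrize(
        "name, expected",
        [("wt-dry", 20.2 + 19.2), ("mum2-dry", (22.1 + 21.0) / 99.9 * 100),
         ("myb5-dry", 23.9 + 22.7)],
    )
    def test_reference_dry_rows(self, name, expected):
        fit = ManualFit(reference_set(name), 100.0)
        assert estimate_oil(fit) == pytest.approx(expected, abs=1e-6)

    def test_no_oil_components(self):
        cs = ComponentSet.from_amplitudes([50, 10, 0, 0], [0.02, 0.2, 30, 130],
                                          DRY_LABELS, state="dry")
        assert estimate_oil(ManualFit(cs, 60.0)) == 0.0

    def test_unlabeled_fit_rejected(self):
        with pytest.raises(AttributionError):
            estimate_oil(unlabeled("wt-dry"))


class TestPartition:
    @staticmethod
    def _worked_example():
        """Known-arithmetic case: imbibed total 1000, oil 350 split 200:150."""
        dry = ManualFit(
            ComponentSet.from_amplitudes([10, 55, 20, 15], [0.016, 0.2, 35, 140],
                                         DRY_LABELS, state="dry"), 1000.0)
        imb = ManualFit(
            ComponentSet.from_amplitudes([10, 10, 40, 30, 10],
                                         [0.025, 2.5, 20, 114, 457],
                                         DRY_LABELS + ["external_water"],
                                         state="imbibed"), 777.0)
        meta = SampleMeta(seed_mass=300.0, added_water_mass=100.0, imbibition_time=24.0)
        return imb, dry, meta

    def test_stated_arithmetic(self):
        imb, dry, meta = self._worked_example()
        wp = partition_water(imb, dry, meta, Calibration(1.0))
        assert wp.imbibed_total_signal == pytest.approx(1000.0)
        np.testing.assert_allclose(wp.oil_abs, [0, 0, 200.0, 150.0, 0])
        # water(3) = (400 - 200) / 1 / 400 mg * 100
        assert wp.water_pct[2] == pytest.approx(50.0)

    def test_oil_only_limit(self):
        # imbibed amplitudes identical to dry: no water entered 3 or 4
        dry_cs = ComponentSet.from_amplitudes([49.1, 11.5, 20.2, 19.2],
                                              [0.016, 0.23, 35, 138],
                                              DRY_LABELS, state="dry")
        imb_cs = ComponentSet.from_amplitudes([49.1, 11.5, 20.2, 19.2],
                                              [0.016, 0.23, 35, 138],
                                              DRY_LABELS, state="imbibed")
        meta = SampleMeta(seed_mass=200.0)
        wp = partition_water(ManualFit(imb_cs, 123.0), ManualFit(dry_cs, 100.0),
                             meta, Calibration(1.0))
        assert wp.water_pct[2] == pytest.approx(0.0, abs=1e-9)
        assert wp.water_pct[3] == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_seed_self_consistency(self):
        dry, imb, meta, calib, truth = synthetic_seed_sample(
            water_added_mg={"exchangeable": 15.0, "oil_intracellular_water": 60.0,
                            "oil_mucilage_water": 70.0, "external_water": 40.0})
        wp = partition_water(imb, dry, meta, calib)
        for lbl, got in zip(wp.labels, wp.water_pct):
            assert got == pytest.approx(truth[lbl], rel=0.01, abs=1e-9)

    def test_mass_balance(self):
        added = {"exchangeable": 12.0, "oil_intracellular_water": 55.0,
                 "oil_mucilage_water": 80.0, "external_water": 33.0}
        bound = 17.0
        dry, imb, meta, calib, _ = synthetic_seed_sample(
            bound_water_mg=bound, water_added_mg=added)
        wp = partition_water(imb, dry, meta, calib)
        recovered_mg = wp.total_water / 100.0 * meta.total_mass
        assert recovered_mg == pytest.approx(sum(added.values()) + bound, rel=0.01)

    def test_oil_conservation(self):
        dry, imb, meta, calib, _ = synthetic_seed_sample(
            water_added_mg={"oil_intracellular_water": 50.0,
                            "oil_mucilage_water": 60.0})
        wp = partition_water(imb, dry, meta, calib)
        oil_abs_dry = estimate_oil(dry) / 100.0 * dry.total_amplitude
        assert wp.oil_abs.sum() == pytest.approx(oil_abs_dry, rel=0.01)

    def test_negative_water_floored_with_warning(self):
        imb, dry, meta = self._worked_example()
        # inflate the dry oil so the allocation exceeds the imbibed amplitude
        dry_hot = ManualFit(
            ComponentSet.from_amplitudes([5, 15, 45, 35], [0.016, 0.2, 35, 140],
                                         DRY_LABELS, state="dry"), 1000.0)
        with pytest.warns(UserWarning, match="over-allocated oil"):
            wp = partition_water(imb, dry_hot, meta, Calibration(1.0))
        assert np.all(wp.water_pct >= 0)

    def test_gravimetric_cross_check_logged(self):
        imb, dry, meta = self._worked_example()
        meta = SampleMeta(meta.seed_mass, meta.added_water_mass, meta.imbibition_time,
                          gravimetric_water_fraction=60.0)
        wp = partition_water(imb, dry, meta, Calibration(1.0))
        assert wp.gravimetric_difference is not None
        assert any("gravimetric" in f for f in wp.flags)

    def test_buoyancy_ordering_wildtype_vs_mutant(self):
        # wild-type-like seeds trap more of their water outside (mucilage)
        # than mum2-like seeds: the flotation mechanism as an inequality
        fractions = {}
        for key, genotype in (("wt", "wt-imb-24h"), ("mum2", "mum2-imb-24h")):
            water = REFERENCE_WATER[genotype]
            total_mass = 390.0
            added = {
                "exchangeable": water[1] / 100 * total_mass - 17.0,
                "oil_intracellular_water": water[2] / 100 * total_mass,
                "oil_mucilage_water": water[3] / 100 * total_mass,
                "external_water": water[4] / 100 * total_mass,
            }
            dry, imb, meta, calib, _ = synthetic_seed_sample(
                bound_water_mg=17.0, water_added_mg=added)
            wp = partition_water(imb, dry, meta, calib)
            fractions[key] = wp.external_fraction
        assert fractions["wt"] > fractions["mum2"]


class TestKinetics:
    def test_flat_series_has_zero_rate(self):
        cs = ComponentSet.from_amplitudes([60, 40], [1.0, 100.0],
                                          ["solid", "external_water"])
        kr = fit_kinetics([0.1, 1.0, 5.0], [cs, cs, cs])
        np.testing.assert_array_equal(kr.initial_rate, 0.0)
        assert np.all(np.isnan(kr.tau_h))

    def test_tau_recovery_within_tolerance(self):
        tau_true = 0.5
        times = [0.1, 0.25, 0.5, 1.0, 2.0, 4.0]
        a0 = np.array([30.0, 40.0, 30.0])
        ainf = np.array([10.0, 30.0, 60.0])
        labels = ["solid", "exchangeable", "external_water"]
        sets = [
            ComponentSet.from_amplitudes(
                ainf + (a0 - ainf) * np.exp(-t / tau_true), [1.0, 10.0, 100.0], labels)
            for t in times
        ]
        kr = fit_kinetics(times, sets)
        np.testing.assert_allclose(kr.tau_h, tau_true, rtol=0.05)
        np.testing.assert_allclose(kr.initial_rate, (ainf - a0) / tau_true, rtol=0.05)

    def test_mismatched_labels_rejected(self):
        a = ComponentSet.from_amplitudes([60, 40], [1.0, 100.0],
                                         ["solid", "external_water"])
        b = ComponentSet.from_amplitudes([60, 40], [1.0, 100.0],
                                         ["solid", "exchangeable"])
        with pytest.raises(AttributionError):
            fit_kinetics([0.1, 1.0, 5.0], [a, b, a])

    def test_requires_three_timepoints(self):
        cs = ComponentSet.from_amplitudes([100.0], [10.0], ["solid"])
        with pytest.raises(InvalidModelError):
            fit_kinetics([0.1, 1.0], [cs, cs])

    def test_mucilage_uptake_rises_through_fitted_series(self):
        # early imbibition: water flows into the adherent-mucilage compartment,
        # so its fitted amplitude must rise monotonically through the series
        start = reference_set("wt-wsm-imb-1h")
        end = reference_set("wt-imb-24h")
        times = [0.25, 0.75, 1.5, 3.0]
        acq_f, acq_c = AcquisitionConfig.fid(), AcquisitionConfig.cpmg(n_points=4000)
        fits = []
        for t in times:
            curves = (simulate_imbibition_series(start, end, [1.0] * 5, [t], acq_f)
                      + simulate_imbibition_series(start, end, [1.0] * 5, [t], acq_c))
            res = MultiExponentialModel(curves).fit(5)
            res.components = assign_compartments(res, "imbibed")
            fits.append(res)
        kr = fit_kinetics(times, fits)
        i = list(kr.labels).index("oil_mucilage_water")
        amps = [f.components.amplitudes[i] for f in fits]
        assert all(b > a for a, b in zip(amps, amps[1:]))
        assert kr.initial_rate[i] > 0
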
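"""Control-anchored genotype caller: geometry, calls, flags, properties."""

import math

import numpy as np
import pytest

from kaspcall import (
    CloneTruth,
    ConfigurationError,
    PlatePanel,
    ValidationError,
    WellReading,
    call_genotypes,
    detect_intermediate_wells,
    fit_control_clusters,
    normalize_readings,
)
from kaspcall.genotype_calling import (
    AMBIGUOUS,
    INTERMEDIATE,
    MUT_MUT,
    NO_AMP,
    WT_MUT,
    WT_WT,
    NormalizedReading,
)
from kaspcall.synthetic_data import (
    simulate_clone_screen,
    simulate_panel_from_truths,
)


def _panel(readings):
    return PlatePanel(readings=readings).validate()


def _well_iter():
    for row in "ABCDEFGHIJKLMNOP":
        for col in range(1, 25):
            yield f"{row}{col}"


def _make_reading(well, role, rfu_mut, rfu_wt, sample_id=None):
    return WellReading(plate_id="p1", well=well, sample_id=sample_id or well,
                       role=role, rfu_mut=rfu_mut, rfu_wt=rfu_wt)


class TestNormalize:
    def test_reading_at_ntc_means_is_zero(self):
        wells = _well_iter()
        readings = [
            _make_reading(next(wells), "ntc", 50, 70),
            _make_reading(next(wells), "ntc", 70, 50),
            _make_reading(next(wells), "clone", 60, 60),
        ]
        normalized, ntc = normalize_readings(_panel(readings))
        clone = [r for r in normalized if r.role == "clone"][0]
        assert clone.x == clone.y == 0.0
        assert clone.magnitude == 0.0
        assert clone.angle is None
        assert ntc.mean_mut == ntc.mean_wt == 60.0

    def test_pure_wildtype_axis(self):
        wells = _well_iter()
        readings = [
            _make_reading(next(wells), "ntc", 60, 60),
            _make_reading(next(wells), "ntc", 60, 60),
            _make_reading(next(wells), "clone", 60, 560),
        ]
        normalized, _ = normalize_readings(_panel(readings))
        clone = [r for r in normalized if r.role == "clone"][0]
        assert clone.angle == pytest.approx(0.0)
        assert clone.magnitude == pytest.approx(500.0)

    def test_noise_free_heterozygote_at_45_degrees(self, noise_free, rng):
        panel = simulate_panel_from_truths(
            [CloneTruth("het", ("WT", "HDR"))], noise_free, rng)
        normalized, _ = normalize_readings(panel)
        het = [r for r in normalized if r.sample_id == "het"][0]
        assert het.angle == pytest.approx(45.0, abs=1e-6)

    def test_no_ntc_is_configuration_error(self):
        panel = _panel([_make_reading("A1", "clone", 100, 100)])
        with pytest.raises(ConfigurationError):
            normalize_readings(panel)


class TestFitControls:
    def _controls(self, gain_mut=1.0):
        wells = _well_iter()
        readings = [_make_reading(next(wells), "ntc", 60, 60)
                    for _ in range(2)]
        fracs = {"control_wt_wt": 0.0, "control_wt_mut": 0.5,
                 "control_mut_mut": 1.0}
        for role, f in fracs.items():
            for _ in range(2):
                readings.append(_make_reading(
                    next(wells), role,
                    60 + 2000 * f * gain_mut, 60 + 2000 * (1 - f)))
        return _panel(readings)

    def test_equal_gain_centroids(self):
        normalized, ntc = normalize_readings(self._controls())
        model = fit_control_clusters(normalized, ntc)
        assert model.classes["wt_wt"].centroid_angle == pytest.approx(0.0)
        assert model.classes["wt_mut"].centroid_angle == pytest.approx(45.0)
        assert model.classes["mut_mut"].centroid_angle == pytest.approx(90.0)

    def test_mutant_gain_skews_het_centroid(self):
        normalized, ntc = normalize_readings(self._controls(gain_mut=2.0))
        model = fit_control_clusters(normalized, ntc)
        expected = math.degrees(math.atan2(1.0, 0.5))
        assert model.classes["wt_mut"].centroid_angle == pytest.approx(
            expected, abs=1e-3)

    def test_mislabeled_controls_violate_ordering(self):
        panel = self._controls()
        swapped = []
        for r in panel.readings:
            role = {"control_wt_mut": "control_mut_mut",
                    "control_mut_mut": "control_wt_mut"}.get(r.role, r.role)
            swapped.append(WellReading(r.plate_id, r.well, r.sample_id, role,
                                       r.rfu_mut, r.rfu_wt))
        normalized, ntc = normalize_readings(_panel(swapped))
        with pytest.raises(ValidationError, match="order"):
            fit_control_clusters(normalized, ntc)

    def test_too_few_controls_names_class(self):
        panel = self._controls()
        trimmed = [r for r in panel.readings if r.role != "control_mut_mut"]
        normalized, ntc = normalize_readings(_panel(trimmed))
        with pytest.raises(ConfigurationError, match="mut_mut"):
            fit_control_clusters(normalized, ntc)


class TestCalls:
    def _fit(self, panel):
        normalized, ntc = normalize_readings(panel)
        model = fit_control_clusters(normalized, ntc)
        return normalized, model

    def test_noise_free_compound_genotypes(self, noise_free_panel):
        normalized, model = self._fit(noise_free_panel)
        calls = {c.sample_id: c for c in call_genotypes(normalized, model)}
        assert calls["wt_wt"].call == WT_WT
        assert calls["het"].call == WT_MUT
        assert calls["hom"].call == MUT_MUT
        assert not calls["hom"].half_signal_flag
        # both-alleles-NHEJ reads like a no-template well
        assert calls["nhej_nhej"].call == NO_AMP
        assert calls["nhej_nhej"].nearest_class is None
        # edited/NHEJ compound: homozygous-looking at half magnitude
        assert calls["hdr_nhej"].call == MUT_MUT
        assert calls["hdr_nhej"].half_signal_flag
        assert calls["wt_nhej"].call == WT_WT
        assert calls["wt_nhej"].half_signal_flag

    def test_ten_cell_well_with_one_het_cell_is_intermediate(
            self, noise_free_panel):
        normalized, model = self._fit(noise_free_panel)
        calls = {c.sample_id: c for c in call_genotypes(normalized, model)}
        multi = calls["multi10"]
        assert multi.call == INTERMEDIATE
        assert multi.nearest_class == "wt_wt"
        assert multi.angle == pytest.approx(
            math.degrees(math.atan2(0.05, 0.95)), abs=1e-6)

    def test_off_axis_well_is_ambiguous_not_intermediate(
            self, noise_free_panel):
        # angle beyond the mut_mut centroid cannot be a mixture of classes
        import dataclasses

        _, model = self._fit(noise_free_panel)
        classes = dict(model.classes)
        classes["mut_mut"] = dataclasses.replace(
            classes["mut_mut"], centroid_angle=85.0)
        model2 = dataclasses.replace(model, classes=classes)
        reading = NormalizedReading(sample_id="odd", well="P24", role="clone",
                                    x=0.0, y=2000.0)
        call = call_genotypes([reading], model2)[0]
        assert call.call == AMBIGUOUS


class TestDetectIntermediate:
    def test_no_intermediates_gives_empty_list(self, noise_free, rng):
        panel = simulate_panel_from_truths(
            [CloneTruth("c1", ("WT", "WT"))], noise_free, rng)
        normalized, ntc = normalize_readings(panel)
        model = fit_control_clusters(normalized, ntc)
        calls = call_genotypes(normalized, model)
        assert detect_intermediate_wells(calls, model) == []

    def test_53_well_screen_finds_exactly_the_two_hdr_wells(
            self, noise_free, rng):
        truths = [CloneTruth(f"m{i}", tuple(["WT"] * 20)) for i in range(51)]
        truths.append(CloneTruth("hit1", tuple(["HDR"] + ["WT"] * 19)))
        truths.append(CloneTruth("hit2", tuple(["HDR", "HDR"] + ["WT"] * 18)))
        panel = simulate_panel_from_truths(truths, noise_free, rng)
        normalized, ntc = normalize_readings(panel)
        model = fit_control_clusters(normalized, ntc)
        calls = call_genotypes(normalized, model)
        hits = detect_intermediate_wells(calls, model)
        assert sorted(c.sample_id for c in hits) == ["hit1", "hit2"]

    def test_ranking_puts_higher_mutant_fraction_first(
            self, noise_free, rng):
        truths = [
            CloneTruth("frac05", tuple(["HDR"] + ["WT"] * 19)),
            CloneTruth("frac10", tuple(["HDR", "HDR"] + ["WT"] * 18)),
        ]
        panel = simulate_panel_from_truths(truths, noise_free, rng)
        normalized, ntc = normalize_readings(panel)
        model = fit_control_clusters(normalized, ntc)
        calls = call_genotypes(normalized, model)
        hits = detect_intermediate_wells(calls, model)
        assert [c.sample_id for c in hits] == ["frac10", "frac05"]


class TestCallerProperties:
    def test_noise_free_concordance_is_total(self, noise_free, rng):
        """Calls match generative truth for every compound genotype."""
        panel, truths = simulate_clone_screen(
            200, 1, 0.25, 0.25, noise_free, rng)
        normalized, ntc = normalize_readings(panel)
        model = fit_control_clusters(normalized, ntc)
        calls = {c.sample_id: c for c in call_genotypes(normalized, model)}
        for truth in truths:
            call = calls[truth.sample_id]
            assert call.call == truth.genotype_class, truth.alleles
            if truth.genotype_class != "NO_AMP":
                expect_half = truth.amplifiable_fraction < 0.6
                assert call.half_signal_flag == expect_half, truth.alleles

    def test_monotone_in_mutant_channel(self, noise_free_panel):
        normalized, ntc = normalize_readings(noise_free_panel)
        model = fit_control_clusters(normalized, ntc)
        order = {WT_WT: 0, WT_MUT: 1, MUT_MUT: 2}
        classes = []
        for y in np.linspace(0.0, 4000.0, 161):
            call = call_genotypes(
                [NormalizedReading("s", "A1", "clone", x=1000.0, y=float(y))],
                model)[0]
            if call.call in order:
                classes.append(order[call.call])
        assert classes == sorted(classes)

    def test_gain_invariance(self, default_params, rng):
        panel, _ = simulate_clone_screen(60, 1, 0.2, 0.2, default_params, rng)

        def calls_for(scale):
            scaled = PlatePanel(readings=[
                WellReading(r.plate_id, r.well, r.sample_id, r.role,
                            r.rfu_mut * scale, r.rfu_wt * scale, r.antibody)
                for r in panel.readings])
            normalized, ntc = normalize_readings(scaled)
            model = fit_control_clusters(normalized, ntc)
            return [(c.sample_id, c.call, c.half_signal_flag)
                    for c in call_genotypes(normalized, model)]

        assert calls_for(1.0) == calls_for(3.7)

    def test_ntc_like_wells_called_no_amp(self, default_params):
        """Wells with no template land in the NTC band >=99.9% of the time."""
        rng = np.random.default_rng(5)
        misses = total = 0
        for _ in range(200):
            truths = [CloneTruth(f"n{i}", ("NHEJ", "NHEJ")) for i in range(10)]
            panel = simulate_panel_from_truths(truths, default_params, rng)
            normalized, ntc = normalize_readings(panel)
            model = fit_control_clusters(normalized, ntc)
            for call in call_genotypes(normalized, model):
                total += 1
                misses += call.call != NO_AMP
        assert total == 2000
        assert misses / total <= 1e-3
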
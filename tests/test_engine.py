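import numpy as np
import pytest

from fetaldose.coefficients import SynthCoeffParams, generate_coefficients
from fetaldose.engine import (
    ICRP103_FEMALE_WEIGHTS,
    DoseReport,
    TissueWeights,
    effective_dose,
    integrate_organ_dose,
    run_acquisition,
)
from fetaldose.errors import BoundsError, ConfigurationError
from fetaldose.protocol import RotationPlan, ScanProtocol
from fetaldose.study import (
    SCANNER_80_ROW,
    SCANNER_320_ROW,
    helical_protocols,
    wide_volume_protocols,
)


def make_plan(intervals, mode="wide_volume"):
    slabs = sorted({i for a, b in intervals for i in range(a, b)})
    return RotationPlan(
        mode=mode,
        intervals_slabs=tuple(intervals),
        scan_range_slabs=(min(slabs), max(slabs) + 1),
        total_irradiated_mm=float(sum(5 * (b - a) for a, b in intervals)),
        total_overlap_mm=0.0,
        overlap_ratio_unrounded=0.0,
        overlap_ratio_pct=0,
    )


def brute_force_dose(coeffs, plan, mas, pitch, kv=100, bw_class="A"):
    """Independent oracle: explicit loop over every (rotation, slab) pair."""
    doses = {organ: 0.0 for organ in coeffs.organs()}
    for a, b in plan.intervals_slabs:
        for slab in range(a, b):
            for organ in doses:
                doses[organ] += coeffs.coefficient(kv, bw_class, organ, slab) * (
                    mas / pitch
                )
    return doses


class TestIntegrateOrganDose:
    def test_single_slab_single_rotation(self, phantom, coeffs):
        plan = make_plan([(130, 131)])
        doses = integrate_organ_dose(coeffs, plan, 51.5, 1.0, phantom=phantom)
        expected = coeffs.coefficient(100, "A", "uterus_fetus", 130) * 51.5
        assert doses["uterus_fetus"] == pytest.approx(expected, rel=1e-12)

    def test_full_overlap_doubles_dose(self, phantom, coeffs):
        single = integrate_organ_dose(coeffs, make_plan([(120, 140)]), 51.5)
        double = integrate_organ_dose(
            coeffs, make_plan([(120, 140), (120, 140)]), 51.5
        )
        for organ in single:
            assert double[organ] == pytest.approx(2 * single[organ], rel=1e-12)

    def test_oracle_equivalence_randomized(self, phantom, coeffs_jittered):
        """Matches the brute-force per-(rotation, slab) oracle on 120 plans."""
        rng = np.random.default_rng(2024)
        for _ in range(120):
            n_rot = int(rng.integers(1, 5))
            intervals = []
            for _ in range(n_rot):
                a = int(rng.integers(0, 200))
                b = int(rng.integers(a + 1, min(a + 30, 208) + 1))
                intervals.append((a, b))
            mas = float(rng.uniform(1, 200))
            pitch = float(rng.choice([1.0, 1.39]))
            bw_class = str(rng.choice(["A", "B", "H"]))
            plan = make_plan(intervals)
            fast = integrate_organ_dose(
                coeffs_jittered, plan, mas, pitch, bw_class=bw_class
            )
            slow = brute_force_dose(coeffs_jittered, plan, mas, pitch, bw_class=bw_class)
            for organ in slow:
                assert fast[organ] == pytest.approx(slow[organ], rel=1e-12)

    def test_linearity_in_mas(self, coeffs):
        plan = make_plan([(110, 150), (130, 170)])
        d1 = integrate_organ_dose(coeffs, plan, 10.0)
        d3 = integrate_organ_dose(coeffs, plan, 30.0)
        for organ in d1:
            assert d3[organ] == pytest.approx(3 * d1[organ], rel=1e-12)

    def test_adding_rotation_never_decreases(self, coeffs):
        base = integrate_organ_dose(coeffs, make_plan([(110, 140)]), 51.5)
        more = integrate_organ_dose(
            coeffs, make_plan([(110, 140), (150, 170)]), 51.5
        )
        assert all(more[o] >= base[o] for o in base)

    def test_out_of_bounds_interval(self, coeffs):
        with pytest.raises(BoundsError):
            integrate_organ_dose(coeffs, make_plan([(200, 210)]), 51.5)

    def test_missing_matrix(self, coeffs):
        with pytest.raises(Exception):
            integrate_organ_dose(coeffs, make_plan([(0, 10)]), 51.5, kv=120)


class TestEffectiveDose:
    def test_zero_doses(self, phantom):
        doses = {o: 0.0 for o in phantom.organ_names}
        assert effective_dose(doses) == 0.0

    def test_uniform_dose_factorizes(self, phantom):
        doses = {o: 2.5 for o in phantom.organ_names}
        total_w = ICRP103_FEMALE_WEIGHTS.total_weight
        assert effective_dose(doses) == pytest.approx(2.5 * total_w, rel=1e-12)

    def test_two_organ_toy_table(self):
        w = TissueWeights(
            weights={"a": 0.12, "b": 0.04}, remainder_weight=0.0, remainder_organs=()
        )
        assert effective_dose({"a": 10.0, "b": 5.0}, w) == pytest.approx(1.4)

    def test_female_weight_table_sums_to_one(self):
        assert ICRP103_FEMALE_WEIGHTS.total_weight == pytest.approx(1.0)

    def test_missing_organ_rejected(self):
        w = TissueWeights(
            weights={"a": 0.1}, remainder_weight=0.0, remainder_organs=()
        )
        with pytest.raises(ConfigurationError):
            effective_dose({"b": 1.0}, w)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            TissueWeights(weights={"a": -0.1}, remainder_weight=0.0, remainder_organs=())


class TestRunAcquisition:
    def test_wide_volume_ctdivol(self, phantom, coeffs):
        report = run_acquisition(
            wide_volume_protocols()[0], SCANNER_320_ROW, phantom, coeffs
        )
        assert report.ctdivol_mgy == pytest.approx(2.6, abs=1e-12)
        assert report.dlp_displayed == 62
        assert report.fetal_dose == report.organ_dose["uterus_fetus"]

    def test_helical_348_dlp(self, phantom, coeffs):
        proto = [p for p in helical_protocols() if p.scan_length_mm == 348][0]
        report = run_acquisition(proto, SCANNER_80_ROW, phantom, coeffs)
        assert report.dlp_displayed == 101
        assert report.dlp_mgycm == pytest.approx(100.92)

    def test_zero_ma_all_zero(self, phantom, coeffs):
        proto = ScanProtocol(
            kv=100, ma=0, rotation_time_s=0.5, pitch=1.0,
            beam_width_mm=120, n_rotations=2, scan_length_mm=176,
        )
        report = run_acquisition(proto, SCANNER_320_ROW, phantom, coeffs)
        assert report.dlp_mgycm == 0.0
        assert report.effective_dose_msv == 0.0
        assert all(d == 0.0 for d in report.organ_dose.values())

    def test_helical_fetal_dose_monotone_in_scan_length(self, phantom, coeffs):
        """Longer helical scans never give a lower fetal dose (jitter 0)."""
        doses = [
            run_acquisition(p, SCANNER_80_ROW, phantom, coeffs).fetal_dose
            for p in helical_protocols()
        ]
        assert all(b >= a for a, b in zip(doses, doses[1:]))

    def test_overlap_non_monotonicity_348_vs_352(self, phantom, coeffs):
        """Three 160-mm rotations over 348 mm out-dose four 120-mm over 352 mm.

        The 348-mm plan carries both the larger per-length overlap and the
        higher-output beam-width class, so its fetal dose is strictly higher
        even though its scan length is shorter.
        """
        by_length = {
            p.scan_length_mm: run_acquisition(p, SCANNER_320_ROW, phantom, coeffs)
            for p in wide_volume_protocols()
            if p.scan_length_mm in (348, 352)
        }
        assert by_length[348].fetal_dose > by_length[352].fetal_dose
        assert by_length[348].effective_dose_msv > by_length[352].effective_dose_msv

    def test_fetal_dose_mismatch_rejected(self, phantom, coeffs):
        report = run_acquisition(
            wide_volume_protocols()[0], SCANNER_320_ROW, phantom, coeffs
        )
        with pytest.raises(ConfigurationError):
            DoseReport(
                organ_dose=report.organ_dose,
                fetal_dose=report.fetal_dose + 1.0,
                effective_dose_msv=report.effective_dose_msv,
                ctdivol_mgy=report.ctdivol_mgy,
                dlp_mgycm=report.dlp_mgycm,
                dlp_displayed=report.dlp_displayed,
                protocol=report.protocol,
                scanner_name=report.scanner_name,
                plan=report.plan,
            )
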
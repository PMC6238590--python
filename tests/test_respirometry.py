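"""Trace segmentation and respiration-component decomposition."""

import numpy as np
import pytest

from adipoflux import (
    Condition,
    RespirationPhases,
    RespirationTrace,
    decompose_respiration,
    oligo_sensitivity,
    segment_phases,
)


def make_trace(ocr, times=None, injections=(), well="w1", ppr=None):
    times = np.arange(1, len(ocr) + 1) * 6.0 if times is None else np.asarray(times)
    return RespirationTrace(
        well_id=well,
        condition=Condition("WT"),
        timepoints=times,
        ocr=np.asarray(ocr, dtype=float),
        ppr=ppr,
        injections=list(injections),
    )


class TestTraceValidation:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_trace([1, 2, 3], times=[0, 5, 5])

    def test_injection_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_trace([1, 2, 3], injections=[(100.0, "oligomycin")])

    def test_unordered_injections_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            make_trace(
                [1] * 6, injections=[(20.0, "oligomycin"), (10.0, "isoproterenol")]
            )

    def test_unknown_agent_rejected(self):
        with pytest.raises(ValueError, match="unknown agent"):
            make_trace([1] * 4, injections=[(10.0, "rotenone")])


class TestSegmentPhases:
    def test_constant_trace_unit_conversion(self):
        # 100 pmol/min over 0.1 cm² -> 100*60/1000/0.1 = 60 nmol/h/cm²
        trace = make_trace([100] * 8, injections=[(27.0, "oligomycin")])
        phases = segment_phases(trace, well_area_cm2=0.1, skip_first=1)
        assert phases.ocr == {"basal": 60.0, "post_oligomycin": 60.0}
        assert phases.order == ["basal", "post_oligomycin"]

    def test_two_phase_hand_average_with_skip(self):
        trace = make_trace(
            [10, 10, 10, 4, 4], times=[0, 6, 12, 18, 24],
            injections=[(15.0, "oligomycin")],
        )
        phases = segment_phases(trace, well_area_cm2=1.0, skip_first=1)
        scale = 60 / 1000
        assert phases.ocr["basal"] == pytest.approx(10 * scale)
        assert phases.ocr["post_oligomycin"] == pytest.approx(4 * scale)

    def test_empty_phase_after_skipping_raises_naming_phase(self):
        trace = make_trace(
            [10, 10, 4], times=[0, 6, 12], injections=[(9.0, "oligomycin")]
        )
        with pytest.raises(ValueError, match="post_oligomycin"):
            segment_phases(trace, well_area_cm2=1.0, skip_first=1)

    def test_invariant_to_time_translation(self):
        ocr = [100, 90, 95, 40, 42, 41]
        base = make_trace(ocr, times=[0, 6, 12, 18, 24, 30],
                          injections=[(15.0, "oligomycin")])
        shifted = make_trace(ocr, times=[500, 506, 512, 518, 524, 530],
                             injections=[(515.0, "oligomycin")])
        a = segment_phases(base, well_area_cm2=0.106)
        b = segment_phases(shifted, well_area_cm2=0.106)
        assert a.ocr == pytest.approx(b.ocr)

    def test_non_mito_above_basal_flagged_not_clamped(self):
        phases = RespirationPhases(
            ocr={"basal": 10.0, "post_antimycinA": 12.0},
            order=["basal", "post_antimycinA"],
        )
        assert "non_mito_exceeds_basal" in phases.flags
        assert phases.ocr["post_antimycinA"] == 12.0


class TestDecomposeRespiration:
    def phases(self, **ocr):
        order = ["basal"] + [k for k in ocr if k != "basal"]
        return RespirationPhases(ocr=ocr, order=order)

    def test_iso_induced_and_percent_of_basal(self):
        # WT condition means: basal 50.4, post-iso 165.6
        comp = decompose_respiration(
            self.phases(basal=50.4, post_isoproterenol=165.6), ["isoproterenol"]
        )
        assert comp.iso_induced == pytest.approx(115.2)
        assert comp.iso_percent_of_basal == pytest.approx(328.57, abs=0.01)

    def test_coupled_from_oligomycin(self):
        # KO condition means: basal 44.4, post-oligo 20.4
        comp = decompose_respiration(
            self.phases(basal=44.4, post_oligomycin=20.4), ["oligomycin"]
        )
        assert comp.coupled == pytest.approx(24.0)

    def test_all_equal_phases_give_zero_components(self):
        comp = decompose_respiration(
            self.phases(
                basal=50.0, post_oligomycin=50.0, post_isoproterenol=50.0,
                post_FCCP=50.0, post_antimycinA=50.0,
            )
        )
        assert comp.coupled == 0.0
        assert comp.iso_induced == 0.0
        assert comp.mito_basal == 0.0

    def test_mito_plus_non_mito_conserves_basal(self):
        comp = decompose_respiration(
            self.phases(basal=50.4, post_antimycinA=3.1), ["antimycinA"]
        )
        assert comp.mito_basal + comp.non_mito == comp.total_basal

    def test_iso_reference_is_preceding_phase(self):
        # oligomycin-first order: iso reference is the post-oligo phase
        comp = decompose_respiration(
            self.phases(basal=50.4, post_oligomycin=18.6, post_isoproterenol=152.4),
            ["oligomycin", "isoproterenol"],
        )
        assert comp.iso_induced == pytest.approx(152.4 - 18.6)

    def test_missing_phase_raises(self):
        with pytest.raises(ValueError, match="post_FCCP"):
            decompose_respiration(self.phases(basal=50.0), ["FCCP"])

    def test_negative_coupled_flagged(self):
        comp = decompose_respiration(
            self.phases(basal=10.0, post_oligomycin=15.0), ["oligomycin"]
        )
        assert comp.coupled == pytest.approx(-5.0)
        assert "negative_coupled" in comp.flags

    def test_recovers_known_components_from_synthetic_phases(self):
        truth = {"coupled": 30.0, "leak": 15.0, "non_mito": 5.0}
        basal = truth["coupled"] + truth["leak"] + truth["non_mito"]
        comp = decompose_respiration(
            self.phases(
                basal=basal,
                post_oligomycin=truth["leak"] + truth["non_mito"],
                post_FCCP=90.0,
                post_antimycinA=truth["non_mito"],
            )
        )
        assert comp.coupled == pytest.approx(truth["coupled"])
        assert comp.non_mito == pytest.approx(truth["non_mito"])
        assert comp.mito_basal == pytest.approx(truth["coupled"] + truth["leak"])
        assert comp.max_capacity == 90.0


class TestOligoSensitivity:
    def test_ko_condition_means_partially_sensitive(self):
        free = 151.8 - 44.4
        under = 48.0 - 20.4
        s = oligo_sensitivity(free, under)
        assert s.value == pytest.approx(0.743, abs=0.001)
        assert not s.clamped

    def test_wt_condition_means_clamp_to_zero(self):
        s = oligo_sensitivity(115.2, 152.4 - 18.6)
        assert s.value == 0.0
        assert s.clamped

    def test_full_sensitivity_when_response_abolished(self):
        assert oligo_sensitivity(100.0, 0.0).value == 1.0

    def test_undefined_without_free_response(self):
        with pytest.raises(ValueError, match="undefined"):
            oligo_sensitivity(0.0, 10.0)


def test_condition_block_labels():
    assert Condition("WT").block == "Basal"
    assert Condition("WT", stimulated=True).block == "Iso"
    assert Condition("UCP1KO", oligomycin_present=True).block == "Oligo basal"
    assert Condition.from_block("WT", "Oligo iso") == Condition(
        "WT", stimulated=True, oligomycin_present=True
    )
    with pytest.raises(ValueError):
        Condition("HET")
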
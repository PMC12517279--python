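"""The six diagnostic rules: worked examples, boundaries, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audiorules.audiogram import (
    FREQUENCIES,
    AudiogramError,
    EarRecord,
    FrequencyThresholds,
    WorkerRecord,
)
from audiorules.rules import (
    CATEGORIES,
    ActionFlags,
    DiagnosisSet,
    RuleConfig,
    StsStatus,
    classify_ear,
    classify_worker,
    detect_hearing_impairment,
    detect_hearing_loss,
    detect_nihl,
    resolve_sts,
    sts_shift,
)

from conftest import make_audiogram, make_ear_record, make_worker

# the worked high-frequency-notch audiogram: all five notch terms >= 15 dB,
# 8 kHz recovery 15/20/15 dB
NOTCH = dict(f500=10, f1000=10, f2000=20, f3000=40, f4000=45, f6000=40, f8000=25)


class TestHearingLoss:
    def test_all_thresholds_at_cutoff_is_not_loss(self):
        assert detect_hearing_loss(make_audiogram(20)) is False

    def test_single_exceedance_is_loss(self):
        assert detect_hearing_loss(make_audiogram(10, f6000=25)) is True

    def test_perfect_hearing_is_not_loss(self):
        assert detect_hearing_loss(make_audiogram(0)) is False

    @given(
        st.sampled_from(FREQUENCIES),
        st.sampled_from([5.0, 10.0, 25.0, 40.0]),
    )
    @settings(max_examples=60, deadline=None)
    def test_raising_one_threshold_never_clears_a_loss_call(self, freq, bump):
        rng = np.random.default_rng(11)
        levels = {f: float(rng.choice(np.arange(-10, 125, 5))) for f in FREQUENCIES}
        a = make_audiogram(0, **{f"f{f}": v for f, v in levels.items()})
        before = detect_hearing_loss(a)
        levels[freq] = min(120.0, levels[freq] + bump)
        b = make_audiogram(0, **{f"f{f}": v for f, v in levels.items()})
        assert detect_hearing_loss(b) >= before


class TestHearingImpairment:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            (dict(f500=25, f1000=25, f2000=25, f3000=25), True),  # PTA 25, inclusive
            (dict(f500=20, f1000=20, f2000=20, f3000=40), True),  # PTA 25.0
            (dict(f500=20, f1000=20, f2000=20, f3000=35), False),  # PTA 23.75
        ],
    )
    def test_speech_pta_cutoff_examples(self, overrides, expected):
        a = make_audiogram(0, **overrides)
        assert detect_hearing_impairment(a) is expected

    def test_raising_a_speech_frequency_never_clears_impairment(self):
        base = dict(f500=25, f1000=25, f2000=25, f3000=25)
        a = make_audiogram(0, **base)
        assert detect_hearing_impairment(a)
        for f in (500, 1000, 2000, 3000):
            bumped = dict(base)
            bumped[f"f{f}"] += 20
            assert detect_hearing_impairment(make_audiogram(0, **bumped))


class TestStsShift:
    def test_shift_is_annual_minus_baseline(self):
        baseline = make_audiogram(0, occasion="baseline", f2000=10, f3000=10, f4000=10)
        annual = make_audiogram(0, f2000=20, f3000=20, f4000=20)
        assert sts_shift(baseline, annual) == pytest.approx(10.0)

    def test_identical_audiograms_have_zero_shift(self):
        a = make_audiogram(15, occasion="baseline")
        b = make_audiogram(15)
        assert sts_shift(a, b) == 0.0

    def test_improvement_is_negative(self):
        baseline = make_audiogram(0, occasion="baseline", f2000=30, f3000=30, f4000=30)
        annual = make_audiogram(0, f2000=25, f3000=25, f4000=25)
        assert sts_shift(baseline, annual) == pytest.approx(-5.0)

    def test_ear_mismatch_is_an_error(self):
        baseline = make_audiogram(10, ear="left", occasion="baseline")
        annual = make_audiogram(10, ear="right")
        with pytest.raises(AudiogramError, match="ear mismatch"):
            sts_shift(baseline, annual)


def _sts_trio(shift, retest_shift=None, retest_date="2024-01-31"):
    baseline = make_audiogram(5, occasion="baseline", date="2023-01-01")
    annual = make_audiogram(
        5, date="2024-01-01",
        **{f"f{f}": 5 + shift for f in (2000, 3000, 4000)},
    )
    retest = None
    if retest_shift is not None:
        retest = make_audiogram(
            5, occasion="retest", date=retest_date,
            **{f"f{f}": 5 + retest_shift for f in (2000, 3000, 4000)},
        )
    return baseline, annual, retest


class TestResolveSts:
    def test_persisting_shift_on_retest_is_permanent(self):
        assert resolve_sts(*_sts_trio(15, retest_shift=12)) is StsStatus.PSTS

    def test_resolved_shift_on_retest_is_temporary(self):
        assert resolve_sts(*_sts_trio(10, retest_shift=2)) is StsStatus.TSTS

    def test_shift_without_retest_is_pending(self):
        assert resolve_sts(*_sts_trio(10)) is StsStatus.PENDING

    def test_retest_beyond_the_window_leaves_the_shift_pending(self):
        assert (
            resolve_sts(*_sts_trio(10, retest_shift=2, retest_date="2024-06-01"))
            is StsStatus.PENDING
        )

    def test_subthreshold_shift_is_no_sts(self):
        assert resolve_sts(*_sts_trio(5)) is StsStatus.NONE

    def test_retest_before_annual_is_an_error(self):
        with pytest.raises(AudiogramError, match="before annual"):
            resolve_sts(*_sts_trio(10, retest_shift=2, retest_date="2023-12-01"))


class TestNihl:
    def test_worked_notch_example_is_nihl_under_corrected_recovery(self):
        assert detect_nihl(make_audiogram(0, **NOTCH)) is True

    def test_flat_audiogram_is_not_nihl(self):
        assert detect_nihl(make_audiogram(10)) is False

    def test_worked_notch_example_fails_under_literal_recovery_sign(self):
        cfg = RuleConfig(recovery_sign="literal")
        assert detect_nihl(make_audiogram(0, **NOTCH), cfg) is False

    def test_literal_recovery_accepts_a_rising_high_frequency_profile(self):
        # notch terms hold and 8 kHz is >=10 dB *worse* than 3/4/6 kHz
        profile = dict(f500=0, f1000=0, f2000=10, f3000=15, f4000=20, f6000=20, f8000=35)
        cfg = RuleConfig(recovery_sign="literal")
        assert detect_nihl(make_audiogram(0, **profile), cfg) is True
        assert detect_nihl(make_audiogram(0, **profile)) is False

    def test_one_failing_notch_term_defeats_the_conjunction(self):
        # 6000 - 500 = 10 < 15
        profile = dict(NOTCH, f6000=20)
        assert detect_nihl(make_audiogram(0, **profile)) is False


CUTOFF_GRID = [
    # (cfg_field, cutoff, inclusive)
    ("loss_cutoff_db", 20.0, False),
    ("impairment_cutoff_db", 25.0, True),
    ("sts_shift_db", 10.0, True),
    ("nihl_notch_db", 15.0, True),
    ("nihl_recovery_db", 10.0, True),
]


class TestBoundaries:
    """Each cutoff at cutoff-5 / cutoff / cutoff+5 on the 5-dB grid."""

    @pytest.mark.parametrize("delta, expected", [(-5, False), (0, False), (5, True)])
    def test_loss_cutoff_is_strict(self, delta, expected):
        a = make_audiogram(0, f4000=20 + delta)
        assert detect_hearing_loss(a) is expected

    @pytest.mark.parametrize("delta, expected", [(-5, False), (0, True), (5, True)])
    def test_impairment_cutoff_is_inclusive(self, delta, expected):
        a = make_audiogram(0, **{f"f{f}": 25 + delta for f in (500, 1000, 2000, 3000)})
        assert detect_hearing_impairment(a) is expected

    @pytest.mark.parametrize(
        "delta, expected",
        [(-5, StsStatus.NONE), (0, StsStatus.PENDING), (5, StsStatus.PENDING)],
    )
    def test_sts_shift_cutoff_is_inclusive(self, delta, expected):
        assert resolve_sts(*_sts_trio(10 + delta)) is expected

    @pytest.mark.parametrize("delta, expected", [(-5, False), (0, True), (5, True)])
    def test_nihl_notch_depth_is_inclusive(self, delta, expected):
        d = 15 + delta  # uniform notch depth above the 0-dB low frequencies
        profile = dict(f500=0, f1000=0, f2000=0, f3000=d, f4000=d, f6000=d, f8000=d - 10)
        assert detect_nihl(make_audiogram(0, **profile)) is expected

    @pytest.mark.parametrize("delta, expected", [(-5, False), (0, True), (5, True)])
    def test_nihl_recovery_depth_is_inclusive(self, delta, expected):
        rec = 10 + delta
        profile = dict(f500=0, f1000=0, f2000=0, f3000=30, f4000=30, f6000=30, f8000=30 - rec)
        assert detect_nihl(make_audiogram(0, **profile)) is expected

    @pytest.mark.parametrize(
        "days, expected",
        [(87, StsStatus.TSTS), (92, StsStatus.TSTS), (97, StsStatus.PENDING)],
    )
    def test_retest_window_is_inclusive_at_92_days(self, days, expected):
        import datetime as dt

        retest_date = (dt.date(2024, 1, 1) + dt.timedelta(days=days)).isoformat()
        assert (
            resolve_sts(*_sts_trio(10, retest_shift=0, retest_date=retest_date))
            is expected
        )


class TestClassifyEar:
    def test_flat_quiet_ear_is_normal_only(self):
        d = classify_ear(make_ear_record())
        assert d == DiagnosisSet(
            normal=True, hearing_loss=False, hearing_impairment=False,
            psts=False, tsts=False, nihl=False,
        )

    def test_notch_ear_is_nihl_plus_hearing_loss(self):
        rec = make_ear_record(baseline=(0, NOTCH), annual=(0, NOTCH))
        d = classify_ear(rec)
        assert d.nihl and d.hearing_loss and not d.normal
        assert not (d.psts or d.tsts or d.hearing_impairment)

    def test_resolved_shift_is_tsts_and_not_normal(self):
        shift = {f"f{f}": 20 for f in (2000, 3000, 4000)}
        rec = make_ear_record(
            baseline=(5, {f"f{f}": 5 for f in (2000, 3000, 4000)}),
            annual=(5, shift),
            retest=(5, {f"f{f}": 5 for f in (2000, 3000, 4000)}),
        )
        d = classify_ear(rec)
        assert d.tsts and not d.psts and not d.normal

    def test_pending_shift_leaves_the_ear_normal_but_marked(self):
        shift = {f"f{f}": 15 for f in (2000, 3000, 4000)}
        rec = make_ear_record(baseline=(5, {}), annual=(5, shift))
        d = classify_ear(rec)
        assert d.sts_pending and d.normal and not (d.psts or d.tsts)


class TestClassifyWorker:
    def test_both_ears_normal_gives_normal_worker_without_flags(self, flat_worker):
        d = classify_worker(flat_worker)
        assert d.worker.normal
        assert d.flags == ActionFlags(False, False, ())

    def test_single_positive_ear_propagates_to_the_worker_union(self):
        left = make_ear_record(baseline=(0, NOTCH), annual=(0, NOTCH), ear="left")
        w = make_worker(left=left)
        d = classify_worker(w)
        assert d.worker.nihl and not d.worker.normal
        assert d.right.normal and not d.left.normal

    def test_pending_sts_raises_the_repeat_flag_with_an_ear_coded_reason(self):
        shift = {f"f{f}": 15 for f in (2000, 3000, 4000)}
        right = make_ear_record(baseline=(5, {}), annual=(5, shift), ear="right")
        d = classify_worker(make_worker(right=right))
        assert d.flags.repeat_required
        assert "STS_PENDING_R" in d.flags.reasons

    def test_psts_raises_the_report_flag(self):
        shift = {f"f{f}": 20 for f in (2000, 3000, 4000)}
        left = make_ear_record(
            baseline=(5, {f"f{f}": 5 for f in (2000, 3000, 4000)}),
            annual=(5, shift),
            retest=(5, shift),
            ear="left",
        )
        d = classify_worker(make_worker(left=left))
        assert d.left.psts
        assert d.flags.report_required
        assert "PSTS_L" in d.flags.reasons

    def test_discordant_ears_resolve_to_permanent_at_worker_level(self):
        lo = {f"f{f}": 5 for f in (2000, 3000, 4000)}
        hi = {f"f{f}": 20 for f in (2000, 3000, 4000)}
        psts_ear = make_ear_record(baseline=(5, lo), annual=(5, hi), retest=(5, hi), ear="left")
        tsts_ear = make_ear_record(baseline=(5, lo), annual=(5, hi), retest=(5, lo), ear="right")
        d = classify_worker(make_worker(left=psts_ear, right=tsts_ear))
        assert d.left.psts and d.right.tsts
        assert d.worker.psts and not d.worker.tsts

    def test_classification_is_deterministic(self, flat_worker):
        assert classify_worker(flat_worker) == classify_worker(flat_worker)


class TestDiagnosisSetInvariants:
    def test_normal_must_negate_the_positives(self):
        with pytest.raises(ValueError, match="normal"):
            DiagnosisSet(
                normal=True, hearing_loss=True, hearing_impairment=False,
                psts=False, tsts=False, nihl=False,
            )

    def test_psts_and_tsts_are_mutually_exclusive(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            DiagnosisSet(
                normal=False, hearing_loss=False, hearing_impairment=False,
                psts=True, tsts=True, nihl=False,
            )

    def test_pending_excludes_confirmed_sts(self):
        with pytest.raises(ValueError, match="pending"):
            DiagnosisSet(
                normal=False, hearing_loss=False, hearing_impairment=False,
                psts=True, tsts=False, nihl=False, sts_pending=True,
            )
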
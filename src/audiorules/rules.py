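"""The six diagnostic rules for occupational noise-related hearing disorder.

Per ear, evaluated on the annual (surveillance) audiogram unless noted:

1. *Hearing impairment* — speech-frequency PTA (500/1000/2000/3000 Hz)
   of 25 dB HL or more, relative to the 0-dB reference.
2. *Hearing loss* — any single threshold strictly greater than 20 dB HL.
3./4. *Permanent / temporary standard threshold shift* (PSTS / TSTS) — a
   >=10 dB worsening of the 2000/3000/4000 Hz PTA versus baseline,
   resolved permanent or temporary by a retest within ~3 months of the
   annual test; an unresolved shift is *pending*, not a diagnosis.
5. *Noise-induced hearing loss* (NIHL) — the 3-6 kHz notch conjunction:
   five notch terms (>=15 dB worse at 3/4/6 kHz than at 0.5/1 kHz) and
   three recovery terms at 8 kHz (>=10 dB).  The recovery-term sign is
   configurable: ``corrected`` (default) requires the 8 kHz threshold to
   be *better* than the notch (true recovery); ``literal`` requires it to
   be worse, reproducing the condition exactly as originally typeset.
6. *Normal* — none of the five positive categories.

All cutoffs live in :class:`RuleConfig` and are configurable; the
defaults are the published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .audiogram import (
    FREQUENCIES,
    Audiogram,
    AudiogramError,
    Ear,
    EarRecord,
    WorkerRecord,
    pta_speech,
    pta_sts,
)

__all__ = [
    "CATEGORIES",
    "RuleConfig",
    "DiagnosisSet",
    "ActionFlags",
    "WorkerDiagnosis",
    "StsStatus",
    "detect_hearing_loss",
    "detect_hearing_impairment",
    "sts_shift",
    "resolve_sts",
    "detect_nihl",
    "classify_ear",
    "classify_worker",
    "action_flags",
]

#: The six diagnostic categories, in report order.
CATEGORIES: tuple[str, ...] = (
    "normal",
    "hearing_loss",
    "hearing_impairment",
    "psts",
    "tsts",
    "nihl",
)


@dataclass(frozen=True)
class RuleConfig:
    """Numeric cutoffs and switches for the diagnostic rules.

    Parameters
    ----------
    loss_cutoff_db:
        Hearing loss when any threshold is strictly greater than this
        (dB HL).
    impairment_cutoff_db:
        Hearing impairment when the speech PTA is >= this (dB HL).
    sts_shift_db:
        Standard threshold shift when the STS-PTA worsens by >= this
        versus baseline (dB).
    nihl_notch_db:
        Minimum notch depth (dB) for each of the five NIHL notch terms.
    nihl_recovery_db:
        Minimum 8-kHz recovery (dB) for each of the three NIHL recovery
        terms.
    retest_window_days:
        Maximum retest delay after the annual test (~3 months) for STS
        resolution.
    recovery_sign:
        ``"corrected"`` — recovery means a *lower* threshold at 8 kHz
        than at the notch; ``"literal"`` — the inequality as originally
        typeset (8 kHz worse than the notch).
    repeat_on_pending:
        Raise the repeat-audiogram flag on an unresolved (pending) STS.
    report_categories:
        Ear-level categories that trigger the report-to-authority flag.
    """

    loss_cutoff_db: float = 20.0
    impairment_cutoff_db: float = 25.0
    sts_shift_db: float = 10.0
    nihl_notch_db: float = 15.0
    nihl_recovery_db: float = 10.0
    retest_window_days: int = 92
    recovery_sign: str = "corrected"
    repeat_on_pending: bool = True
    report_categories: tuple[str, ...] = ("psts", "nihl", "hearing_impairment")

    def __post_init__(self) -> None:
        for name in (
            "loss_cutoff_db",
            "impairment_cutoff_db",
            "sts_shift_db",
            "nihl_notch_db",
            "nihl_recovery_db",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.retest_window_days < 1:
            raise ValueError("retest_window_days must be >= 1")
        if self.recovery_sign not in ("corrected", "literal"):
            raise ValueError("recovery_sign must be 'corrected' or 'literal'")
        unknown = set(self.report_categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown report categories: {sorted(unknown)}")


class StsStatus(str, Enum):
    NONE = "none"
    PSTS = "psts"
    TSTS = "tsts"
    PENDING = "pending"


@dataclass(frozen=True)
class DiagnosisSet:
    """Binary calls for the six categories plus an unresolved-STS marker.

    Invariants (enforced at construction): ``normal`` is true exactly when
    every positive category is false; PSTS and TSTS are mutually
    exclusive; a pending STS implies neither PSTS nor TSTS.
    """

    normal: bool
    hearing_loss: bool
    hearing_impairment: bool
    psts: bool
    tsts: bool
    nihl: bool
    sts_pending: bool = False

    def __post_init__(self) -> None:
        positives = (
            self.hearing_loss
            or self.hearing_impairment
            or self.psts
            or self.tsts
            or self.nihl
        )
        if self.normal != (not positives):
            raise ValueError("normal must equal the negation of all positives")
        if self.psts and self.tsts:
            raise ValueError("PSTS and TSTS are mutually exclusive")
        if self.sts_pending and (self.psts or self.tsts):
            raise ValueError("a pending STS cannot coexist with PSTS/TSTS")

    def __getitem__(self, category: str) -> bool:
        if category not in CATEGORIES:
            raise KeyError(category)
        return bool(getattr(self, category))


@dataclass(frozen=True)
class ActionFlags:
    """Follow-up alerts: repeat the audiogram and/or report the case."""

    repeat_required: bool
    report_required: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if bool(self.reasons) != (self.repeat_required or self.report_required):
            raise ValueError("reasons must be non-empty iff any flag is set")


@dataclass(frozen=True)
class WorkerDiagnosis:
    """Per-ear and worker-level diagnosis sets plus action flags.

    The worker-level set is the per-category union over the classified
    ears; the worker is normal only when every classified ear is normal.
    """

    worker_id: str
    left: Optional[DiagnosisSet]
    right: Optional[DiagnosisSet]
    worker: DiagnosisSet
    flags: ActionFlags


def detect_hearing_loss(a: Audiogram, cfg: RuleConfig = RuleConfig()) -> bool:
    """True iff any threshold exceeds the loss cutoff (strict >)."""
    return any(a.thresholds[f] > cfg.loss_cutoff_db for f in FREQUENCIES)


def detect_hearing_impairment(
    a: Audiogram, cfg: RuleConfig = RuleConfig()
) -> bool:
    """True iff the speech-frequency PTA meets the impairment cutoff (>=)."""
    return pta_speech(a.thresholds).value >= cfg.impairment_cutoff_db


def sts_shift(baseline: Audiogram, annual: Audiogram) -> float:
    """Signed STS-PTA shift (dB): annual minus baseline; negative = better."""
    if baseline.ear != annual.ear:
        raise AudiogramError(
            f"ear mismatch: baseline {baseline.ear.value}, "
            f"annual {annual.ear.value}"
        )
    return pta_sts(annual.thresholds).value - pta_sts(baseline.thresholds).value


def resolve_sts(
    baseline: Audiogram,
    annual: Audiogram,
    retest: Optional[Audiogram] = None,
    cfg: RuleConfig = RuleConfig(),
) -> StsStatus:
    """Resolve a standard threshold shift as permanent, temporary, or pending.

    No STS when the annual-vs-baseline shift is below the cutoff.  With a
    shift, a retest within the retest window decides: the shift persisting
    on retest makes it permanent (PSTS), a resolved shift temporary
    (TSTS).  Without an in-window retest the shift is PENDING.
    """
    shift = sts_shift(baseline, annual)
    if shift < cfg.sts_shift_db:
        return StsStatus.NONE
    if retest is not None:
        if retest.test_date < annual.test_date:
            raise AudiogramError(
                f"retest dated {retest.test_date} before annual "
                f"{annual.test_date}"
            )
        delay = (retest.test_date - annual.test_date).days
        if delay <= cfg.retest_window_days:
            retest_shift = sts_shift(baseline, retest)
            if retest_shift >= cfg.sts_shift_db:
                return StsStatus.PSTS
            return StsStatus.TSTS
    return StsStatus.PENDING


def detect_nihl(a: Audiogram, cfg: RuleConfig = RuleConfig()) -> bool:
    """Noise-induced hearing loss: the 3-6 kHz notch conjunction.

    All five notch terms and all three recovery terms must hold.  Under
    the default ``corrected`` recovery sign, recovery means the 8 kHz
    threshold is at least ``nihl_recovery_db`` *better* (lower) than each
    notch frequency; ``literal`` reverses each recovery inequality.
    """
    t = a.thresholds
    notch = cfg.nihl_notch_db
    rec = cfg.nihl_recovery_db
    notch_ok = (
        t[3000] - t[1000] >= notch
        and t[4000] - t[500] >= notch
        and t[4000] - t[1000] >= notch
        and t[6000] - t[500] >= notch
        and t[6000] - t[1000] >= notch
    )
    if not notch_ok:
        return False
    if cfg.recovery_sign == "corrected":
        return (
            t[3000] - t[8000] >= rec
            and t[4000] - t[8000] >= rec
            and t[6000] - t[8000] >= rec
        )
    return (
        t[8000] - t[3000] >= rec
        and t[8000] - t[4000] >= rec
        and t[8000] - t[6000] >= rec
    )


def classify_ear(rec: EarRecord, cfg: RuleConfig = RuleConfig()) -> DiagnosisSet:
    """Classify one ear from its baseline/annual(/retest) audiograms.

    Hearing loss, impairment, and NIHL are evaluated on the annual
    (surveillance) audiogram; the retest serves only to resolve an STS.
    A pending STS does not by itself negate normal — it is carried in
    ``sts_pending`` and surfaced through the repeat flag.
    """
    status = resolve_sts(rec.baseline, rec.annual, rec.retest, cfg)
    loss = detect_hearing_loss(rec.annual, cfg)
    impairment = detect_hearing_impairment(rec.annual, cfg)
    nihl = detect_nihl(rec.annual, cfg)
    psts = status is StsStatus.PSTS
    tsts = status is StsStatus.TSTS
    pending = status is StsStatus.PENDING
    normal = not (loss or impairment or psts or tsts or nihl)
    return DiagnosisSet(
        normal=normal,
        hearing_loss=loss,
        hearing_impairment=impairment,
        psts=psts,
        tsts=tsts,
        nihl=nihl,
        sts_pending=pending,
    )


_EAR_SUFFIX = {Ear.LEFT: "L", Ear.RIGHT: "R"}


def action_flags(
    ear_sets: dict[Ear, DiagnosisSet], cfg: RuleConfig = RuleConfig()
) -> ActionFlags:
    """Follow-up flags from the per-ear diagnosis sets.

    Repeat when any ear carries an unresolved STS; report when any ear is
    positive for a reportable category (PSTS, NIHL, or hearing
    impairment by default).  Each trigger contributes one reason code
    such as ``PSTS_L`` or ``STS_PENDING_R``.
    """
    reasons: list[str] = []
    repeat = False
    report = False
    for ear in (Ear.LEFT, Ear.RIGHT):
        if ear not in ear_sets:
            continue
        d = ear_sets[ear]
        suffix = _EAR_SUFFIX[ear]
        if cfg.repeat_on_pending and d.sts_pending:
            repeat = True
            reasons.append(f"STS_PENDING_{suffix}")
        for cat in cfg.report_categories:
            if d[cat]:
                report = True
                reasons.append(f"{cat.upper()}_{suffix}")
    return ActionFlags(
        repeat_required=repeat, report_required=report, reasons=tuple(reasons)
    )


def classify_worker(
    r: WorkerRecord, cfg: RuleConfig = RuleConfig()
) -> WorkerDiagnosis:
    """Classify both ears and aggregate to the worker level.

    Worker-level positive categories are the union over ears; the worker
    is normal only when every classified ear is normal.
    """
    ears = r.ears()
    if not ears:
        raise AudiogramError(f"worker {r.worker_id}: no ear records")
    ear_sets: dict[Ear, DiagnosisSet] = {}
    for ear, rec in ears.items():
        try:
            ear_sets[ear] = classify_ear(rec, cfg)
        except AudiogramError as exc:
            raise AudiogramError(
                f"worker {r.worker_id} {ear.value} ear: {exc}"
            ) from exc
    union = {
        cat: any(d[cat] for d in ear_sets.values())
        for cat in CATEGORIES
        if cat != "normal"
    }
    # Discordant ears (PSTS left, TSTS right): the permanent shift
    # dominates the worker-level call; the temporary one remains visible
    # in the ear-level sets.  Likewise a confirmed STS suppresses the
    # worker-level pending marker (the repeat flag still fires per ear).
    if union["psts"] and union["tsts"]:
        union["tsts"] = False
    pending = any(d.sts_pending for d in ear_sets.values()) and not (
        union["psts"] or union["tsts"]
    )
    worker_set = DiagnosisSet(
        normal=not any(union.values()), sts_pending=pending, **union
    )
    return WorkerDiagnosis(
        worker_id=r.worker_id,
        left=ear_sets.get(Ear.LEFT),
        right=ear_sets.get(Ear.RIGHT),
        worker=worker_set,
        flags=action_flags(ear_sets, cfg),
    )
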
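"""Brute-force reference classifier used as the test oracle.

This module transcribes every diagnostic inequality literally and
independently of :mod:`audiorules.rules`: it recomputes the pure tone
averages inline, spells out each of the eight notch/recovery comparisons,
and walks the shift/retest logic step by step.  It deliberately shares no
rule helpers with the engine so that agreement between the two is a
meaningful cross-implementation check.  It is slower and clumsier by
design; use :func:`audiorules.rules.classify_worker` in production.
"""

from __future__ import annotations

from typing import Optional

from .audiogram import Audiogram, AudiogramError, Ear, EarRecord, WorkerRecord
from .rules import ActionFlags, DiagnosisSet, RuleConfig, WorkerDiagnosis

__all__ = ["oracle_classify"]


def _oracle_ear(rec: EarRecord, cfg: RuleConfig) -> DiagnosisSet:
    ann = rec.annual.thresholds.levels
    base = rec.baseline.thresholds.levels

    # hearing loss: any single threshold strictly above the cutoff
    loss = False
    for f in (500, 1000, 2000, 3000, 4000, 6000, 8000):
        if ann[f] > cfg.loss_cutoff_db:
            loss = True

    # hearing impairment: 4-frequency speech average at or above the cutoff
    speech_avg = (ann[500] + ann[1000] + ann[2000] + ann[3000]) / 4.0
    impairment = speech_avg >= cfg.impairment_cutoff_db

    # NIHL: all five notch terms, then all three recovery terms
    nihl = True
    if not (ann[3000] - ann[1000] >= cfg.nihl_notch_db):
        nihl = False
    if not (ann[4000] - ann[500] >= cfg.nihl_notch_db):
        nihl = False
    if not (ann[4000] - ann[1000] >= cfg.nihl_notch_db):
        nihl = False
    if not (ann[6000] - ann[500] >= cfg.nihl_notch_db):
        nihl = False
    if not (ann[6000] - ann[1000] >= cfg.nihl_notch_db):
        nihl = False
    if cfg.recovery_sign == "corrected":
        if not (ann[3000] - ann[8000] >= cfg.nihl_recovery_db):
            nihl = False
        if not (ann[4000] - ann[8000] >= cfg.nihl_recovery_db):
            nihl = False
        if not (ann[6000] - ann[8000] >= cfg.nihl_recovery_db):
            nihl = False
    else:
        if not (ann[8000] - ann[3000] >= cfg.nihl_recovery_db):
            nihl = False
        if not (ann[8000] - ann[4000] >= cfg.nihl_recovery_db):
            nihl = False
        if not (ann[8000] - ann[6000] >= cfg.nihl_recovery_db):
            nihl = False

    # standard threshold shift on the 2/3/4 kHz average vs baseline
    sts_base = (base[2000] + base[3000] + base[4000]) / 3.0
    sts_ann = (ann[2000] + ann[3000] + ann[4000]) / 3.0
    psts = False
    tsts = False
    pending = False
    if sts_ann - sts_base >= cfg.sts_shift_db:
        resolved = False
        if rec.retest is not None:
            if rec.retest.test_date < rec.annual.test_date:
                raise AudiogramError("retest dated before annual audiogram")
            days = (rec.retest.test_date - rec.annual.test_date).days
            if days <= cfg.retest_window_days:
                ret = rec.retest.thresholds.levels
                sts_ret = (ret[2000] + ret[3000] + ret[4000]) / 3.0
                if sts_ret - sts_base >= cfg.sts_shift_db:
                    psts = True
                else:
                    tsts = True
                resolved = True
        if not resolved:
            pending = True

    normal = (
        (not loss)
        and (not impairment)
        and (not psts)
        and (not tsts)
        and (not nihl)
    )
    return DiagnosisSet(
        normal=normal,
        hearing_loss=loss,
        hearing_impairment=impairment,
        psts=psts,
        tsts=tsts,
        nihl=nihl,
        sts_pending=pending,
    )


def oracle_classify(r: WorkerRecord, cfg: RuleConfig = RuleConfig()) -> WorkerDiagnosis:
    """Classify a worker with the literal reference transcription.

    Same contract as :func:`audiorules.rules.classify_worker`.
    """
    left: Optional[DiagnosisSet] = None
    right: Optional[DiagnosisSet] = None
    if r.left is not None:
        left = _oracle_ear(r.left, cfg)
    if r.right is not None:
        right = _oracle_ear(r.right, cfg)
    if left is None and right is None:
        raise AudiogramError(f"worker {r.worker_id}: no ear records")

    sets = [s for s in (left, right) if s is not None]
    loss = any(s.hearing_loss for s in sets)
    impairment = any(s.hearing_impairment for s in sets)
    psts = any(s.psts for s in sets)
    tsts = any(s.tsts for s in sets)
    nihl = any(s.nihl for s in sets)
    if psts and tsts:
        tsts = False  # permanent shift dominates at worker level
    pending = any(s.sts_pending for s in sets) and not (psts or tsts)
    worker = DiagnosisSet(
        normal=not (loss or impairment or psts or tsts or nihl),
        hearing_loss=loss,
        hearing_impairment=impairment,
        psts=psts,
        tsts=tsts,
        nihl=nihl,
        sts_pending=pending,
    )

    reasons: list[str] = []
    repeat = False
    report = False
    for suffix, s in (("L", left), ("R", right)):
        if s is None:
            continue
        if cfg.repeat_on_pending and s.sts_pending:
            repeat = True
            reasons.append(f"STS_PENDING_{suffix}")
        for cat in cfg.report_categories:
            if getattr(s, cat):
                report = True
                reasons.append(f"{cat.upper()}_{suffix}")
    flags = ActionFlags(
        repeat_required=repeat, report_required=report, reasons=tuple(reasons)
    )
    return WorkerDiagnosis(
        worker_id=r.worker_id, left=left, right=right, worker=worker, flags=flags
    )
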
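"""Seeded synthetic worker cohorts with known ground-truth diagnoses.

The generator emulates an occupational-surveillance dataset: per worker,
baseline and annual audiograms for both ears (plus a retest where a
threshold shift needs resolution), and a gold-standard multi-label
diagnosis per worker.  Audiograms are built from audiometric templates —
flat low thresholds for normal hearing, broadband elevation for hearing
loss/impairment, a 3-6 kHz notch with 8 kHz recovery for NIHL, and an
added 2-4 kHz shift with a persisting or resolving retest for permanent
or temporary standard threshold shifts — then perturbed with test-retest
noise and snapped to the 5-dB audiometer grid.

Templates express *intent*; the gold labels are always recomputed by the
independent reference classifier (:func:`audiorules.oracle.oracle_classify`),
so labels stay consistent with the rules even when templates interact
(a NIHL notch, for instance, also constitutes hearing loss).

The default category mixture targets the study conditions: about 51.4 %
of workers carry at least one noise-related finding.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .audiogram import (
    FREQUENCIES,
    Audiogram,
    Ear,
    EarRecord,
    FrequencyThresholds,
    Occasion,
    WorkerRecord,
)
from .oracle import oracle_classify
from .rules import CATEGORIES, DiagnosisSet, RuleConfig, WorkerDiagnosis

__all__ = [
    "DEFAULT_MIXTURE",
    "GeneratorSpec",
    "generate_case",
    "generate_cohort",
    "random_worker_record",
    "flip_labels",
    "gold_frame",
]

#: Default worker-profile mixture.  Keys are target-category profiles
#: ("sts" is split into PSTS/TSTS by ``persistence_p``); values sum to 1.
#: The empty profile (normal) has weight 0.486, so the expected share of
#: workers with at least one finding is 51.4 %.
DEFAULT_MIXTURE: dict[tuple[str, ...], float] = {
    (): 0.486,
    ("hearing_loss",): 0.10,
    ("hearing_impairment",): 0.10,
    ("sts",): 0.16,
    ("nihl",): 0.10,
    ("nihl", "sts"): 0.054,
}

_POSITIVE_TARGETS = {"hearing_loss", "hearing_impairment", "psts", "tsts", "nihl", "sts"}


@dataclass(frozen=True)
class GeneratorSpec:
    """Cohort generator configuration.

    Parameters
    ----------
    n_workers:
        Cohort size (the emulated dataset has 320 workers).
    seed:
        RNG seed; identical specs yield identical cohorts.
    mixture:
        Worker-profile probabilities (see :data:`DEFAULT_MIXTURE`).
    noise_sd:
        Test-retest threshold noise SD in dB, applied before snapping to
        the 5-dB grid.  2.5 dB is the order of magnitude of audiometric
        test-retest variability.
    retest_p:
        Probability that a worker with a threshold shift has an in-window
        retest; without one the shift stays pending.
    persistence_p:
        Probability that a generic "sts" profile persists on retest
        (permanent) rather than resolving (temporary).
    bilateral_p:
        Probability that the target profile affects both ears rather
        than one random ear.
    """

    n_workers: int = 320
    seed: int = 0
    mixture: Mapping[tuple[str, ...], float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    noise_sd: float = 2.5
    retest_p: float = 1.0
    persistence_p: float = 0.5
    bilateral_p: float = 0.25

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        total = float(sum(self.mixture.values()))
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture probabilities sum to {total}, not 1")
        for profile, p in self.mixture.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} for {profile} outside [0,1]")
            unknown = set(profile) - _POSITIVE_TARGETS
            if unknown:
                raise ValueError(f"unknown target categories: {sorted(unknown)}")
        for name in ("retest_p", "persistence_p", "bilateral_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _snap(x: float) -> float:
    """Round to the 5-dB grid and clamp to the audiometer range."""
    return float(min(120.0, max(-10.0, 5.0 * round(x / 5.0))))


def _noisy(levels: Mapping[int, float], rng: np.random.Generator, sd: float) -> dict[int, float]:
    if sd == 0.0:
        return {f: _snap(v) for f, v in levels.items()}
    return {f: _snap(v + rng.normal(0.0, sd)) for f, v in levels.items()}


def _normal_base(rng: np.random.Generator) -> dict[int, float]:
    base = float(rng.choice([0.0, 5.0, 10.0]))
    return {f: min(15.0, base + float(rng.choice([0.0, 5.0]))) for f in FREQUENCIES}


# chronic 3-6 kHz notch with 8 kHz recovery (dB HL)
_NOTCH = {500: 10.0, 1000: 10.0, 2000: 20.0, 3000: 40.0, 4000: 45.0, 6000: 40.0, 8000: 25.0}


def _ear_templates(
    rng: np.random.Generator, targets: frozenset[str]
) -> tuple[dict[int, float], dict[int, float], Optional[dict[int, float]]]:
    """(baseline, annual, retest-or-None) template levels for one ear."""
    annual = _normal_base(rng)
    if "hearing_impairment" in targets:
        level = float(rng.choice([30.0, 35.0, 40.0, 45.0]))
        annual = {f: level for f in FREQUENCIES}
    if "nihl" in targets:
        offset = float(rng.choice([0.0, 5.0]))
        if "hearing_impairment" in targets:
            offset += 15.0  # lift the notch so the speech PTA clears 25 dB
        annual = {f: v + offset for f, v in _NOTCH.items()}
    elif "hearing_loss" in targets and "hearing_impairment" not in targets:
        annual[8000] = float(rng.choice([25.0, 30.0, 35.0, 40.0]))

    sts = targets & {"psts", "tsts"}
    if sts:
        # keep the pre-shift thresholds on the audiometer grid floor
        for f in (2000, 3000, 4000):
            annual[f] = max(annual[f], 5.0)
    baseline = dict(annual)
    retest: Optional[dict[int, float]] = None
    if sts:
        for f in (2000, 3000, 4000):
            baseline[f] = annual[f] - 15.0
        retest = dict(annual) if "psts" in sts else dict(baseline)
    return baseline, annual, retest


def generate_case(
    rng: np.random.Generator,
    target_categories: Sequence[str],
    *,
    noise_sd: float = 0.0,
    retest_p: float = 1.0,
    bilateral_p: float = 0.25,
    worker_id: str = "W0",
) -> tuple[WorkerRecord, DiagnosisSet]:
    """Construct one worker record aimed at the given category profile.

    Returns the record together with its gold diagnosis set, which is
    the *oracle's* classification of the constructed record — the
    targets are intents; the oracle output is truth.
    """
    targets = frozenset(target_categories)
    unknown = targets - (_POSITIVE_TARGETS - {"sts"})
    if unknown:
        raise ValueError(f"unknown target categories: {sorted(unknown)}")
    if {"psts", "tsts"} <= targets:
        raise ValueError("a worker cannot target both PSTS and TSTS in one ear")

    base_date = _dt.date(2023, 3, 1) + _dt.timedelta(days=int(rng.integers(0, 60)))
    annual_date = base_date + _dt.timedelta(days=365 + int(rng.integers(-14, 15)))
    retest_date = annual_date + _dt.timedelta(days=int(rng.integers(14, 61)))

    if targets and rng.random() >= bilateral_p:
        affected = {Ear.LEFT if rng.random() < 0.5 else Ear.RIGHT}
    else:
        affected = {Ear.LEFT, Ear.RIGHT}

    has_retest = bool(targets & {"psts", "tsts"}) and rng.random() < retest_p
    ear_recs: dict[Ear, EarRecord] = {}
    for ear in (Ear.LEFT, Ear.RIGHT):
        ear_targets = targets if ear in affected else frozenset()
        base_t, ann_t, ret_t = _ear_templates(rng, ear_targets)

        def _gram(occ: Occasion, date: _dt.date, levels: Mapping[int, float]) -> Audiogram:
            return Audiogram(
                worker_id=worker_id,
                ear=ear,
                occasion=occ,
                test_date=date,
                thresholds=FrequencyThresholds(_noisy(levels, rng, noise_sd)),
            )

        retest_gram = None
        if ret_t is not None and has_retest:
            retest_gram = _gram(Occasion.RETEST, retest_date, ret_t)
        ear_recs[ear] = EarRecord(
            baseline=_gram(Occasion.BASELINE, base_date, base_t),
            annual=_gram(Occasion.ANNUAL, annual_date, ann_t),
            retest=retest_gram,
        )

    record = WorkerRecord(
        worker_id=worker_id, left=ear_recs[Ear.LEFT], right=ear_recs[Ear.RIGHT]
    )
    gold = oracle_classify(record).worker
    return record, gold


def _resolve_profile(
    profile: tuple[str, ...], rng: np.random.Generator, persistence_p: float
) -> tuple[str, ...]:
    """Split a generic 'sts' target into PSTS or TSTS."""
    out: list[str] = []
    for t in profile:
        if t == "sts":
            out.append("psts" if rng.random() < persistence_p else "tsts")
        else:
            out.append(t)
    return tuple(out)


def generate_cohort(
    spec: GeneratorSpec,
) -> tuple[list[WorkerRecord], pd.DataFrame]:
    """Generate a seeded cohort and its gold label table.

    Returns the worker records and a DataFrame indexed by worker id with
    one 0/1 column per diagnostic category (the gold CSV dialect).
    Identical specs produce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = list(spec.mixture.keys())
    probs = np.asarray([spec.mixture[p] for p in profiles], dtype=float)
    probs = probs / probs.sum()
    width = len(str(spec.n_workers))
    records: list[WorkerRecord] = []
    gold_rows: list[dict[str, object]] = []
    for i in range(spec.n_workers):
        profile = profiles[int(rng.choice(len(profiles), p=probs))]
        targets = _resolve_profile(profile, rng, spec.persistence_p)
        wid = f"W{i + 1:0{width}d}"
        record, gold = generate_case(
            rng,
            targets,
            noise_sd=spec.noise_sd,
            retest_p=spec.retest_p,
            bilateral_p=spec.bilateral_p,
            worker_id=wid,
        )
        records.append(record)
        gold_rows.append(
            {"worker_id": wid, **{cat: int(gold[cat]) for cat in CATEGORIES}}
        )
    gold = pd.DataFrame(gold_rows).set_index("worker_id")
    return records, gold


def gold_frame(diagnoses: Sequence[WorkerDiagnosis]) -> pd.DataFrame:
    """Worker-level diagnosis sets as a gold-dialect DataFrame."""
    rows = [
        {"worker_id": d.worker_id, **{c: int(d.worker[c]) for c in CATEGORIES}}
        for d in diagnoses
    ]
    return pd.DataFrame(rows).set_index("worker_id")


_GRID = np.arange(-10.0, 125.0, 5.0)


def random_worker_record(
    rng: np.random.Generator, worker_id: str = "W0", retest_prob: float = 0.5
) -> WorkerRecord:
    """A worker record with thresholds uniform on the 5-dB grid.

    Used for stress-testing rule implementations: thresholds span the
    full audiometer range with no clinical structure, and the retest —
    present with probability ``retest_prob`` — may fall outside the
    resolution window.
    """
    base_date = _dt.date(2023, 1, 1)
    annual_date = _dt.date(2024, 1, 1)
    ears: dict[str, EarRecord] = {}
    for ear in (Ear.LEFT, Ear.RIGHT):
        def _rand_gram(occ: Occasion, date: _dt.date) -> Audiogram:
            levels = {f: float(rng.choice(_GRID)) for f in FREQUENCIES}
            return Audiogram(
                worker_id=worker_id,
                ear=ear,
                occasion=occ,
                test_date=date,
                thresholds=FrequencyThresholds(levels),
            )

        retest = None
        if rng.random() < retest_prob:
            delay = int(rng.integers(0, 151))  # sometimes beyond the window
            retest = _rand_gram(
                Occasion.RETEST, annual_date + _dt.timedelta(days=delay)
            )
        ears[ear.value] = EarRecord(
            baseline=_rand_gram(Occasion.BASELINE, base_date),
            annual=_rand_gram(Occasion.ANNUAL, annual_date),
            retest=retest,
        )
    return WorkerRecord(worker_id=worker_id, left=ears["left"], right=ears["right"])


def flip_labels(
    gold: pd.DataFrame,
    category: str,
    epsilon: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Flip a fraction ``epsilon`` of one category's gold labels.

    Emulates expert disagreement (multiple published criteria sets exist
    for NIHL in particular).  Workers are ranked once by a seeded
    permutation and the first ``ceil(epsilon * n)`` flipped, so flip
    sets are nested as ``epsilon`` grows — larger noise strictly
    contains smaller.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category: {category}")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0,1]")
    out = gold.copy()
    n_flip = math.ceil(epsilon * len(out))
    order = rng.permutation(len(out))
    idx = out.index[order[:n_flip]]
    out.loc[idx, category] = 1 - out.loc[idx, category]
    return out
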
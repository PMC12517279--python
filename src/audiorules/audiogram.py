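"""Audiogram data model and pure-tone-average computations.

An audiogram records one ear's hearing threshold levels (dB HL) at the
seven standard occupational test frequencies.  Two pure tone averages
(PTAs) drive every downstream diagnostic rule:

* the *speech-frequency* PTA over 500/1000/2000/3000 Hz, used for the
  hearing-impairment call, and
* the *STS* PTA over 2000/3000/4000 Hz, used for standard-threshold-shift
  detection against the baseline audiogram.

Both are exact arithmetic means kept at full precision; rounding happens
only at report time.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

__all__ = [
    "FREQUENCIES",
    "SPEECH_FREQUENCIES",
    "STS_FREQUENCIES",
    "THRESHOLD_MIN",
    "THRESHOLD_MAX",
    "AudiogramError",
    "Ear",
    "Occasion",
    "FrequencyThresholds",
    "Audiogram",
    "EarRecord",
    "WorkerRecord",
    "PtaValue",
    "Finding",
    "pta_speech",
    "pta_sts",
    "validate_record",
]

#: The seven frequencies (Hz) of an occupational pure-tone audiogram.
FREQUENCIES: tuple[int, ...] = (500, 1000, 2000, 3000, 4000, 6000, 8000)

#: Frequencies averaged for the speech-frequency PTA (hearing impairment).
SPEECH_FREQUENCIES: tuple[int, ...] = (500, 1000, 2000, 3000)

#: Frequencies averaged for the standard-threshold-shift PTA.
STS_FREQUENCIES: tuple[int, ...] = (2000, 3000, 4000)

#: Audiometer output range in dB HL.
THRESHOLD_MIN: float = -10.0
THRESHOLD_MAX: float = 120.0


class AudiogramError(ValueError):
    """Raised for structurally invalid audiometric input."""


class Ear(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Occasion(str, Enum):
    BASELINE = "baseline"
    ANNUAL = "annual"
    RETEST = "retest"


@dataclass(frozen=True)
class FrequencyThresholds:
    """Hearing threshold levels (dB HL) for one ear at the 7 test frequencies.

    All seven frequencies must be present and numeric; this is enforced at
    construction.  Range and 5-dB-grid conformance are *findings* reported
    by :func:`validate_record` so that nonconforming records can still be
    loaded and inspected.
    """

    levels: Mapping[int, float]

    def __post_init__(self) -> None:
        levels = dict(self.levels)
        for f in FREQUENCIES:
            if f not in levels:
                raise AudiogramError(f"missing threshold at {f} Hz")
        extra = set(levels) - set(FREQUENCIES)
        if extra:
            raise AudiogramError(f"unknown frequencies: {sorted(extra)}")
        for f, v in levels.items():
            try:
                levels[f] = float(v)
            except (TypeError, ValueError) as exc:
                raise AudiogramError(
                    f"non-numeric threshold {v!r} at {f} Hz"
                ) from exc
            if levels[f] != levels[f]:  # NaN
                raise AudiogramError(f"NaN threshold at {f} Hz")
        object.__setattr__(self, "levels", levels)

    def __getitem__(self, frequency: int) -> float:
        return self.levels[frequency]

    def out_of_range_frequencies(self) -> list[int]:
        """Frequencies whose threshold falls outside [-10, 120] dB HL."""
        return [
            f
            for f in FREQUENCIES
            if not (THRESHOLD_MIN <= self.levels[f] <= THRESHOLD_MAX)
        ]

    def off_grid_frequencies(self) -> list[int]:
        """Frequencies whose threshold is not a multiple of 5 dB.

        Clinical audiometers step in 5-dB increments; off-grid values are
        accepted but flagged.
        """
        return [f for f in FREQUENCIES if self.levels[f] % 5 != 0]


@dataclass(frozen=True)
class Audiogram:
    """One ear's audiogram on one test occasion."""

    worker_id: str
    ear: Ear
    occasion: Occasion
    test_date: _dt.date
    thresholds: FrequencyThresholds

    def __post_init__(self) -> None:
        object.__setattr__(self, "ear", Ear(self.ear))
        object.__setattr__(self, "occasion", Occasion(self.occasion))
        if isinstance(self.test_date, str):
            object.__setattr__(
                self, "test_date", _dt.date.fromisoformat(self.test_date)
            )
        if not isinstance(self.test_date, _dt.date):
            raise AudiogramError(f"unparseable test date: {self.test_date!r}")


@dataclass(frozen=True)
class EarRecord:
    """Baseline + annual (+ optional retest) audiograms for one ear."""

    baseline: Audiogram
    annual: Audiogram
    retest: Optional[Audiogram] = None


@dataclass(frozen=True)
class WorkerRecord:
    """A worker's per-ear surveillance audiograms.

    Both ears are expected for classification; a single-ear record is
    classifiable per-ear but flagged by :func:`validate_record`.
    """

    worker_id: str
    left: Optional[EarRecord] = None
    right: Optional[EarRecord] = None

    def ears(self) -> dict[Ear, EarRecord]:
        out: dict[Ear, EarRecord] = {}
        if self.left is not None:
            out[Ear.LEFT] = self.left
        if self.right is not None:
            out[Ear.RIGHT] = self.right
        return out


@dataclass(frozen=True)
class PtaValue:
    """A pure tone average in dB HL over a named frequency set."""

    value: float
    frequency_set: tuple[int, ...]


@dataclass(frozen=True)
class Finding:
    """One validation finding: machine-readable code + severity + context."""

    code: str
    severity: str  # "error" | "warning"
    message: str


def pta_speech(t: FrequencyThresholds) -> PtaValue:
    """Speech-frequency pure tone average: mean over 500/1000/2000/3000 Hz."""
    vals = [t[f] for f in SPEECH_FREQUENCIES]
    return PtaValue(value=sum(vals) / len(vals), frequency_set=SPEECH_FREQUENCIES)


def pta_sts(t: FrequencyThresholds) -> PtaValue:
    """STS pure tone average: mean over 2000/3000/4000 Hz."""
    vals = [t[f] for f in STS_FREQUENCIES]
    return PtaValue(value=sum(vals) / len(vals), frequency_set=STS_FREQUENCIES)


def _audiogram_findings(a: Audiogram, label: str) -> list[Finding]:
    findings: list[Finding] = []
    for f in a.thresholds.out_of_range_frequencies():
        findings.append(
            Finding(
                code="THRESHOLD_OUT_OF_RANGE",
                severity="error",
                message=(
                    f"{label}: threshold {a.thresholds[f]} dB HL at {f} Hz "
                    f"outside [{THRESHOLD_MIN:g}, {THRESHOLD_MAX:g}]"
                ),
            )
        )
    for f in a.thresholds.off_grid_frequencies():
        findings.append(
            Finding(
                code="OFF_GRID_THRESHOLD",
                severity="warning",
                message=(
                    f"{label}: threshold {a.thresholds[f]} dB HL at {f} Hz "
                    "not on the 5-dB audiometer grid"
                ),
            )
        )
    return findings


def validate_record(r: WorkerRecord) -> list[Finding]:
    """Validate a worker record; returns [] when fully conformant.

    Checks per-audiogram threshold range and 5-dB-grid conformance, per-ear
    date ordering (baseline <= annual <= retest), and flags single-ear
    records.  Idempotent and side-effect free.
    """
    findings: list[Finding] = []
    ears = r.ears()
    if len(ears) < 2:
        findings.append(
            Finding(
                code="SINGLE_EAR",
                severity="warning",
                message=f"worker {r.worker_id}: only one ear recorded",
            )
        )
    for ear, rec in ears.items():
        label = f"worker {r.worker_id} {ear.value}"
        for occ, a in (
            ("baseline", rec.baseline),
            ("annual", rec.annual),
            ("retest", rec.retest),
        ):
            if a is not None:
                findings.extend(_audiogram_findings(a, f"{label} {occ}"))
        if rec.baseline.test_date > rec.annual.test_date:
            findings.append(
                Finding(
                    code="DATE_ORDER",
                    severity="error",
                    message=(
                        f"{label}: baseline dated {rec.baseline.test_date} "
                        f"after annual {rec.annual.test_date}"
                    ),
                )
            )
        if rec.retest is not None and rec.retest.test_date < rec.annual.test_date:
            findings.append(
                Finding(
                    code="DATE_ORDER",
                    severity="error",
                    message=(
                        f"{label}: retest dated {rec.retest.test_date} "
                        f"before annual {rec.annual.test_date}"
                    ),
                )
            )
    return findings
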
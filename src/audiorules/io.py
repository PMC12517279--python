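"""CSV readers/writers for the audiogram, gold-label and results dialects.

Audiogram CSV (input), one row per ear-occasion::

    worker_id,ear,occasion,test_date,hz500,hz1000,hz2000,hz3000,hz4000,hz6000,hz8000

with ``ear`` in {L, R}, ``occasion`` in {baseline, annual, retest} and
ISO-8601 dates.  A column-mapping dict (standard name -> actual column)
adapts arbitrary layouts.  Gold CSV: ``worker_id`` plus one 0/1 column
per diagnostic category.  Results CSV: one row per ear plus an
``ear=worker`` summary row per worker.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .audiogram import (
    FREQUENCIES,
    Audiogram,
    AudiogramError,
    Ear,
    EarRecord,
    FrequencyThresholds,
    Occasion,
    WorkerRecord,
    validate_record,
)
from .rules import CATEGORIES, WorkerDiagnosis

__all__ = [
    "AUDIOGRAM_COLUMNS",
    "GOLD_COLUMNS",
    "CsvFormatError",
    "read_audiograms",
    "write_audiograms",
    "read_gold",
    "write_gold",
    "write_results",
]

logger = logging.getLogger(__name__)

_FREQ_COLUMNS = tuple(f"hz{f}" for f in FREQUENCIES)
AUDIOGRAM_COLUMNS: tuple[str, ...] = (
    "worker_id",
    "ear",
    "occasion",
    "test_date",
) + _FREQ_COLUMNS
GOLD_COLUMNS: tuple[str, ...] = ("worker_id",) + CATEGORIES

_EAR_VALUES = {"L": Ear.LEFT, "R": Ear.RIGHT, "left": Ear.LEFT, "right": Ear.RIGHT}


class CsvFormatError(ValueError):
    """Raised when an input CSV does not conform to its dialect."""


def read_audiograms(
    path: str | Path, mapping: Optional[Mapping[str, str]] = None
) -> list[WorkerRecord]:
    """Read and validate worker records from an audiogram CSV.

    ``mapping`` renames columns (standard dialect name -> column present
    in the file).  Hard errors — missing columns, unparseable values,
    duplicate (worker, ear, occasion) rows, missing required occasions,
    error-severity validation findings — abort with row/column context;
    warning findings are logged and counted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CsvFormatError(f"{path}: empty file") from exc
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in AUDIOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing columns: {missing}")
    if df.empty:
        raise CsvFormatError(f"{path}: no audiogram rows")

    grams: dict[tuple[str, Ear, Occasion], Audiogram] = {}
    for i, row in df.iterrows():
        loc = f"{path} row {i + 2}"  # 1-based with header
        wid = str(row["worker_id"])
        ear = _EAR_VALUES.get(str(row["ear"]).strip())
        if ear is None:
            raise CsvFormatError(f"{loc}: ear must be L or R, got {row['ear']!r}")
        try:
            occasion = Occasion(str(row["occasion"]).strip().lower())
        except ValueError as exc:
            raise CsvFormatError(
                f"{loc}: occasion must be baseline/annual/retest, "
                f"got {row['occasion']!r}"
            ) from exc
        levels = {}
        for f, col in zip(FREQUENCIES, _FREQ_COLUMNS):
            try:
                levels[f] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise CsvFormatError(
                    f"{loc}: unparseable threshold {row[col]!r} in {col}"
                ) from exc
        try:
            gram = Audiogram(
                worker_id=wid,
                ear=ear,
                occasion=occasion,
                test_date=str(row["test_date"]).strip(),
                thresholds=FrequencyThresholds(levels),
            )
        except (AudiogramError, ValueError) as exc:
            raise CsvFormatError(f"{loc}: {exc}") from exc
        key = (wid, ear, occasion)
        if key in grams:
            raise CsvFormatError(
                f"{loc}: duplicate row for ({wid}, {ear.value}, {occasion.value})"
            )
        grams[key] = gram

    records: list[WorkerRecord] = []
    worker_ids = list(dict.fromkeys(wid for wid, _, _ in grams))
    n_warnings = 0
    for wid in worker_ids:
        ears: dict[Ear, EarRecord] = {}
        for ear in (Ear.LEFT, Ear.RIGHT):
            baseline = grams.get((wid, ear, Occasion.BASELINE))
            annual = grams.get((wid, ear, Occasion.ANNUAL))
            retest = grams.get((wid, ear, Occasion.RETEST))
            if baseline is None and annual is None and retest is None:
                continue
            if baseline is None or annual is None:
                missing_occ = "baseline" if baseline is None else "annual"
                raise CsvFormatError(
                    f"{path}: worker {wid} {ear.value} ear lacks its "
                    f"{missing_occ} audiogram"
                )
            ears[ear] = EarRecord(baseline=baseline, annual=annual, retest=retest)
        record = WorkerRecord(
            worker_id=wid, left=ears.get(Ear.LEFT), right=ears.get(Ear.RIGHT)
        )
        findings = validate_record(record)
        errors = [f for f in findings if f.severity == "error"]
        if errors:
            raise CsvFormatError(
                f"{path}: worker {wid}: " + "; ".join(f.message for f in errors)
            )
        for f in findings:
            logger.warning("%s: [%s] %s", path, f.code, f.message)
            n_warnings += 1
        records.append(record)
    if n_warnings:
        logger.info("%s: %d validation warning(s)", path, n_warnings)
    return records


def _gram_row(a: Audiogram) -> dict[str, object]:
    row: dict[str, object] = {
        "worker_id": a.worker_id,
        "ear": "L" if a.ear is Ear.LEFT else "R",
        "occasion": a.occasion.value,
        "test_date": a.test_date.isoformat(),
    }
    for f, col in zip(FREQUENCIES, _FREQ_COLUMNS):
        v = a.thresholds[f]
        row[col] = int(v) if float(v).is_integer() else v
    return row


def write_audiograms(records: Sequence[WorkerRecord], path: str | Path) -> None:
    """Write worker records in the audiogram CSV dialect (lossless)."""
    rows = []
    for r in records:
        for rec in r.ears().values():
            for a in (rec.baseline, rec.annual, rec.retest):
                if a is not None:
                    rows.append(_gram_row(a))
    pd.DataFrame(rows, columns=AUDIOGRAM_COLUMNS).to_csv(path, index=False)


def read_gold(path: str | Path) -> pd.DataFrame:
    """Read a gold label table: worker_id index, one 0/1 column per category."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in GOLD_COLUMNS if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing columns: {missing}")
    if df["worker_id"].duplicated().any():
        dupes = df.loc[df["worker_id"].duplicated(), "worker_id"].tolist()
        raise CsvFormatError(f"{path}: duplicate worker ids: {dupes}")
    df["worker_id"] = df["worker_id"].astype(str)
    out = df.set_index("worker_id")[list(CATEGORIES)]
    bad = out[~out.isin([0, 1]).all(axis=1)].index.tolist()
    if bad:
        raise CsvFormatError(f"{path}: non-binary labels for workers {bad}")
    return out.astype(int)


def write_gold(gold: pd.DataFrame, path: str | Path) -> None:
    gold.astype(int).to_csv(path, index_label="worker_id")


def write_results(
    diagnoses: Sequence[WorkerDiagnosis], path: str | Path
) -> None:
    """Write classification results: one row per ear + a worker summary row."""
    rows = []
    for d in diagnoses:
        for ear_label, s in (("L", d.left), ("R", d.right)):
            if s is None:
                continue
            rows.append(
                {
                    "worker_id": d.worker_id,
                    "ear": ear_label,
                    **{c: int(s[c]) for c in CATEGORIES},
                    "sts_pending": int(s.sts_pending),
                    "repeat_required": int(d.flags.repeat_required),
                    "report_required": int(d.flags.report_required),
                }
            )
        rows.append(
            {
                "worker_id": d.worker_id,
                "ear": "worker",
                **{c: int(d.worker[c]) for c in CATEGORIES},
                "sts_pending": int(d.worker.sts_pending),
                "repeat_required": int(d.flags.repeat_required),
                "report_required": int(d.flags.report_required),
            }
        )
    cols = (
        ["worker_id", "ear"]
        + list(CATEGORIES)
        + ["sts_pending", "repeat_required", "report_required"]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
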
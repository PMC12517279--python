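"""Agreement statistics and the k-fold cross-validation harness.

For each diagnostic category the classifier's calls are compared against
gold-standard (expert) labels in a 2x2 table, from which sensitivity,
specificity, PPV, NPV and Cohen's kappa are derived.  The cross-validation
harness partitions workers into k seeded folds, evaluates the (untrained,
deterministic) rule engine on each held-out fold, and reports per-category
fold means +/- SD alongside pooled whole-dataset metrics.

A metric whose denominator is zero in a fold (e.g. sensitivity in a fold
with no positives) is *undefined*: it is reported as ``None`` and excluded
from the mean/SD with an explicit exclusion count, never imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .audiogram import WorkerRecord
from .rules import CATEGORIES, RuleConfig, WorkerDiagnosis, classify_worker

__all__ = [
    "ConfusionTable",
    "MetricSet",
    "FoldPlan",
    "CVReport",
    "METRIC_NAMES",
    "confusion",
    "metric_set",
    "cohens_kappa",
    "kappa_pvalue",
    "interpret_kappa",
    "kfold_plan",
    "cross_validate",
    "round_percent",
    "round_kappa",
]

METRIC_NAMES: tuple[str, ...] = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "kappa",
)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 agreement counts for one category (prediction vs gold)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Validity metrics (proportions in [0, 1]) plus kappa for one category.

    ``None`` marks a metric whose denominator was zero.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    kappa: Optional[float]

    def __getitem__(self, name: str) -> Optional[float]:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def confusion(
    pred: Mapping[str, bool], gold: Mapping[str, bool]
) -> ConfusionTable:
    """Tabulate per-worker binary calls against gold labels.

    Both mappings must cover exactly the same worker ids.
    """
    missing = set(gold) - set(pred)
    extra = set(pred) - set(gold)
    if missing or extra:
        raise ValueError(
            f"worker id mismatch: missing from predictions {sorted(missing)}, "
            f"absent from gold {sorted(extra)}"
        )
    tp = fp = fn = tn = 0
    for wid, g in gold.items():
        p = bool(pred[wid])
        g = bool(g)
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metric_set(c: ConfusionTable) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV and kappa from a 2x2 table."""
    if c.n == 0:
        raise ValueError("empty confusion table")
    return MetricSet(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        kappa=cohens_kappa(c),
    )


def cohens_kappa(c: ConfusionTable) -> float:
    """Chance-corrected agreement kappa = (po - pe) / (1 - pe).

    Degenerate case pe = 1 (both raters constant): defined as 1.0 under
    perfect observed agreement and 0.0 otherwise, so that all-negative
    folds of rare categories do not crash the harness.
    """
    n = c.n
    if n == 0:
        raise ValueError("empty confusion table")
    po = (c.tp + c.tn) / n
    pe = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / (
        n * n
    )
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_pvalue(c: ConfusionTable) -> Optional[float]:
    """Two-sided large-sample p-value for testing kappa = 0.

    Uses the standard null standard error
    SE0 = sqrt(pe + pe^2 - sum_i p_i. p_.i (p_i. + p_.i)) / ((1 - pe) sqrt(n)).
    Returns ``None`` in degenerate tables (pe = 1).
    """
    n = c.n
    if n == 0:
        raise ValueError("empty confusion table")
    # marginal proportions: rows = prediction, columns = gold
    p_pos_pred = (c.tp + c.fp) / n
    p_neg_pred = (c.fn + c.tn) / n
    p_pos_gold = (c.tp + c.fn) / n
    p_neg_gold = (c.fp + c.tn) / n
    pe = p_pos_pred * p_pos_gold + p_neg_pred * p_neg_gold
    if pe == 1.0:
        return None
    s = p_pos_pred * p_pos_gold * (p_pos_pred + p_pos_gold)
    s += p_neg_pred * p_neg_gold * (p_neg_pred + p_neg_gold)
    se0 = math.sqrt(max(pe + pe * pe - s, 0.0)) / ((1.0 - pe) * math.sqrt(n))
    if se0 == 0.0:
        return None
    z = cohens_kappa(c) / se0
    return float(2.0 * norm.sf(abs(z)))


_KAPPA_BANDS = (
    (0.0, "no agreement"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Map kappa to its qualitative agreement band (Landis-Koch)."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa <= 0.0:
        return "no agreement"
    for upper, label in _KAPPA_BANDS[1:]:
        if kappa <= upper:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class FoldPlan:
    """Seeded partition of workers into k folds of near-equal size."""

    k: int
    seed: int
    assignment: Mapping[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [w for w, f in self.assignment.items() if f == fold]


def kfold_plan(worker_ids: Sequence[str], k: int, seed: int) -> FoldPlan:
    """Seeded uniform shuffle then contiguous split into k folds.

    Fold sizes differ by at most one; the plan is reproducible for a
    fixed seed.
    """
    ids = list(worker_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate worker ids")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of workers ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    # contiguous split: first (n mod k) folds get the extra worker
    n = len(ids)
    base, extra = divmod(n, k)
    assignment: dict[str, int] = {}
    start = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        for wid in shuffled[start : start + size]:
            assignment[wid] = fold
        start += size
    return FoldPlan(k=k, seed=seed, assignment=assignment)


def round_percent(p: Optional[float]) -> Optional[float]:
    """Proportion -> percent, one decimal, round-half-up (report style)."""
    if p is None:
        return None
    return float(
        Decimal(repr(p * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def round_kappa(k: Optional[float]) -> Optional[float]:
    """Kappa to three decimals, round-half-up (report style)."""
    if k is None:
        return None
    return float(
        Decimal(repr(k)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    )


@dataclass
class CVReport:
    """Cross-validation results: fold-wise metrics, mean +/- SD, pooled.

    ``fold_values[category][metric]`` is the list of per-fold values
    (``None`` where undefined); ``mean``/``sd`` aggregate the defined
    values; ``n_excluded`` counts undefined folds; ``pooled`` holds the
    whole-dataset metrics over the concatenated test folds, and
    ``pooled_pvalue`` the kappa-vs-0 test p-value per category.
    """

    k: int
    seed: int
    sd_mode: str
    categories: tuple[str, ...]
    fold_sizes: list[int]
    fold_values: dict[str, dict[str, list[Optional[float]]]]
    mean: dict[str, dict[str, Optional[float]]]
    sd: dict[str, dict[str, Optional[float]]]
    n_excluded: dict[str, dict[str, int]]
    pooled: dict[str, MetricSet]
    pooled_pvalue: dict[str, Optional[float]]

    def summary_frame(self) -> pd.DataFrame:
        """Report table: one row per category, mean +/- SD per metric.

        Percent metrics are rounded to one decimal, kappa to three
        (round-half-up); undefined means show as NaN.
        """
        rows = []
        for cat in self.categories:
            row: dict[str, object] = {"category": cat}
            for m in METRIC_NAMES:
                mean, sd = self.mean[cat][m], self.sd[cat][m]
                if m == "kappa":
                    row["kappa_mean"] = round_kappa(mean)
                    row["kappa_sd"] = round_kappa(sd)
                else:
                    row[f"{m}_mean_pct"] = round_percent(mean)
                    row[f"{m}_sd_pct"] = round_percent(sd)
            row["kappa_pvalue"] = self.pooled_pvalue[cat]
            rows.append(row)
        return pd.DataFrame(rows).set_index("category")

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "sd_mode": self.sd_mode,
            "fold_sizes": self.fold_sizes,
            "categories": list(self.categories),
            "fold_values": self.fold_values,
            "mean": self.mean,
            "sd": self.sd,
            "n_excluded": self.n_excluded,
            "pooled": {
                cat: {m: ms[m] for m in METRIC_NAMES}
                for cat, ms in self.pooled.items()
            },
            "pooled_kappa_pvalue": self.pooled_pvalue,
        }
        return json.dumps(payload, indent=2)


def _aggregate(
    values: Sequence[Optional[float]], sd_mode: str
) -> tuple[Optional[float], Optional[float], int]:
    defined = [v for v in values if v is not None]
    excluded = len(values) - len(defined)
    if not defined:
        return None, None, excluded
    arr = np.asarray(defined, dtype=float)
    mean = float(arr.mean())
    if len(arr) == 1:
        return mean, 0.0, excluded
    ddof = 1 if sd_mode == "sample" else 0
    return mean, float(arr.std(ddof=ddof)), excluded


def _gold_mapping(gold: pd.DataFrame) -> dict[str, dict[str, bool]]:
    missing = [c for c in CATEGORIES if c not in gold.columns]
    if missing:
        raise ValueError(f"gold table missing categories: {missing}")
    return {
        str(wid): {cat: bool(row[cat]) for cat in CATEGORIES}
        for wid, row in gold.iterrows()
    }


def cross_validate(
    records: Sequence[WorkerRecord],
    gold: pd.DataFrame,
    cfg: RuleConfig = RuleConfig(),
    k: int = 5,
    seed: int = 0,
    sd_mode: str = "sample",
    unit: str = "worker",
) -> CVReport:
    """k-fold cross-validation of the rule engine against gold labels.

    The rule engine has no fitted parameters, so the per-fold "training"
    step is a structural no-op (a rule audit: the configuration is
    validated and training-fold prevalences are computed); the engine
    then classifies the held-out fold and per-category metrics are
    accumulated.  ``gold`` is indexed by worker id with one 0/1 column
    per category.  ``unit`` selects worker-level (default) or ear-level
    evaluation; ear-level expects the same gold labels applied per ear.
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError("sd_mode must be 'sample' or 'population'")
    if unit not in ("worker", "ear"):
        raise ValueError("unit must be 'worker' or 'ear'")
    gold_map = _gold_mapping(gold)
    ids = [r.worker_id for r in records]
    missing = set(ids) - set(gold_map)
    if missing:
        raise ValueError(f"missing gold labels for workers: {sorted(missing)}")

    # deterministic engine: classify once, reuse across folds
    diagnoses: dict[str, WorkerDiagnosis] = {
        r.worker_id: classify_worker(r, cfg) for r in records
    }

    def calls(wid: str) -> list[dict[str, bool]]:
        d = diagnoses[wid]
        if unit == "worker":
            return [{cat: d.worker[cat] for cat in CATEGORIES}]
        return [
            {cat: s[cat] for cat in CATEGORIES}
            for s in (d.left, d.right)
            if s is not None
        ]

    plan = kfold_plan(ids, k=k, seed=seed)
    fold_values: dict[str, dict[str, list[Optional[float]]]] = {
        cat: {m: [] for m in METRIC_NAMES} for cat in CATEGORIES
    }
    fold_sizes: list[int] = []
    for fold in range(k):
        test_ids = plan.fold_ids(fold)
        fold_sizes.append(len(test_ids))
        # "training" no-op audit on the remaining folds
        train_ids = [w for w in ids if plan.assignment[w] != fold]
        _audit_rules(cfg, train_ids, gold_map)
        for cat in CATEGORIES:
            tp = fp = fn = tn = 0
            for wid in test_ids:
                for call in calls(wid):
                    p, g = call[cat], gold_map[wid][cat]
                    tp += p and g
                    fp += p and not g
                    fn += (not p) and g
                    tn += (not p) and (not g)
            ms = metric_set(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
            for m in METRIC_NAMES:
                fold_values[cat][m].append(ms[m])

    mean: dict[str, dict[str, Optional[float]]] = {}
    sd: dict[str, dict[str, Optional[float]]] = {}
    n_excluded: dict[str, dict[str, int]] = {}
    for cat in CATEGORIES:
        mean[cat], sd[cat], n_excluded[cat] = {}, {}, {}
        for m in METRIC_NAMES:
            mu, sigma, excl = _aggregate(fold_values[cat][m], sd_mode)
            mean[cat][m] = mu
            sd[cat][m] = sigma
            n_excluded[cat][m] = excl

    pooled: dict[str, MetricSet] = {}
    pooled_pvalue: dict[str, Optional[float]] = {}
    for cat in CATEGORIES:
        tp = fp = fn = tn = 0
        for wid in ids:
            for call in calls(wid):
                p, g = call[cat], gold_map[wid][cat]
                tp += p and g
                fp += p and not g
                fn += (not p) and g
                tn += (not p) and (not g)
        table = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
        pooled[cat] = metric_set(table)
        pooled_pvalue[cat] = kappa_pvalue(table)

    return CVReport(
        k=k,
        seed=seed,
        sd_mode=sd_mode,
        categories=CATEGORIES,
        fold_sizes=fold_sizes,
        fold_values=fold_values,
        mean=mean,
        sd=sd,
        n_excluded=n_excluded,
        pooled=pooled,
        pooled_pvalue=pooled_pvalue,
    )


def _audit_rules(
    cfg: RuleConfig,
    train_ids: Sequence[str],
    gold_map: Mapping[str, Mapping[str, bool]],
) -> dict[str, float]:
    """The no-op "training" step: validate the config, log prevalences.

    The rules carry no fitted parameters; this audit exists so the
    harness structurally mirrors a train/test cross-validation loop.
    """
    n = len(train_ids)
    return {
        cat: sum(gold_map[w][cat] for w in train_ids) / n if n else math.nan
        for cat in CATEGORIES
    }
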
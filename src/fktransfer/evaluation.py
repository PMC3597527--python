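"""Evaluation designs: temporal holdout, k-fold CV, precision at fixed
recall, fold over random, and grouped median summaries.

Transferred annotations are never evaluation targets; leakage between a
round's training positives and its evaluation positives is checked
explicitly and fails loudly.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotations import Annotation, AnnotationSet, EXPERIMENTAL_CODES
from .errors import ConfigurationError, FktError


class LeakageError(FktError):
    """An evaluation positive appeared among training positives."""


SIZE_CLASSES = ("zero", "<=5", "<=15", "all")


def size_class_of(n_direct: int) -> str:
    """Finest annotation-size label of a term from its direct count."""
    if n_direct == 0:
        return "zero"
    if n_direct <= 5:
        return "<=5"
    if n_direct <= 15:
        return "<=15"
    return "all"


def size_class_groups(n_direct: int) -> Tuple[str, ...]:
    """Nested size groups a term belongs to (zero subset of <=5 subset of
    <=15 subset of all), mirroring how terms are grouped by annotation
    count in the comparative figures."""
    groups = ["all"]
    if n_direct <= 15:
        groups.append("<=15")
    if n_direct <= 5:
        groups.append("<=5")
    if n_direct == 0:
        groups.append("zero")
    return tuple(reversed(groups))


@dataclass
class EvaluationSplit:
    mode: str  # temporal | kfold
    train: AnnotationSet
    test: AnnotationSet
    cutoff_date: Optional[dt.date] = None
    fold: Optional[int] = None


@dataclass
class MetricRecord:
    term: str
    organism: str
    method: str
    n_direct_at_cutoff: int
    n_eval_positives: int
    precision_at_recall: float
    prior: float

    @property
    def fold_over_random(self) -> float:
        return fold_over_random(self.precision_at_recall, self.prior)

    @property
    def size_class(self) -> str:
        return size_class_of(self.n_direct_at_cutoff)

    def as_dict(self) -> Dict:
        return {
            "term": self.term,
            "organism": self.organism,
            "method": self.method,
            "n_direct_at_cutoff": self.n_direct_at_cutoff,
            "n_eval_positives": self.n_eval_positives,
            "size_class": self.size_class,
            "precision_at_recall": self.precision_at_recall,
            "prior": self.prior,
            "fold_over_random": self.fold_over_random,
        }


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def temporal_split(anns: AnnotationSet, cutoff: dt.date) -> EvaluationSplit:
    """Train on records dated <= cutoff; test on later direct experimental
    records whose (gene, term) is not already a training assignment.

    Transferred records never enter the test side.
    """
    for r in anns:
        if r.date is None:
            raise ConfigurationError(f"undated annotation: {r.gene} {r.term}")
    train = AnnotationSet(r for r in anns if r.date <= cutoff)
    train_pairs = {(r.gene, r.term) for r in train}
    test = AnnotationSet(
        r
        for r in anns
        if r.date > cutoff
        and r.provenance == "direct"
        and r.evidence in EXPERIMENTAL_CODES
        and not r.is_not
        and (r.gene, r.term) not in train_pairs
    )
    return EvaluationSplit("temporal", train, test, cutoff_date=cutoff)


def kfold_split(
    positives: Iterable[str], k: int = 3, seed: int = 0
) -> List[Tuple[FrozenSet[str], FrozenSet[str]]]:
    """Seeded partition of positive genes into k folds.

    Returns (train_genes, held_out_genes) per fold; held-out folds are
    pairwise disjoint and cover the positive set.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    genes = sorted(set(positives))
    if len(genes) < k:
        raise ConfigurationError(f"fewer positives ({len(genes)}) than folds ({k})")
    rng = np.random.RandomState(seed)
    order = rng.permutation(len(genes))
    folds: List[List[str]] = [[] for _ in range(k)]
    for pos, gi in enumerate(order):
        folds[pos % k].append(genes[gi])
    out = []
    for i in range(k):
        held = frozenset(folds[i])
        out.append((frozenset(genes) - held, held))
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def precision_at_recall(
    ranked: Sequence[str], positives: Iterable[str], recall_level: float = 0.10
) -> float:
    """Precision at the first rank where recall reaches ``recall_level``.

    The recall threshold is reached once ceil(recall_level * |positives|)
    positives have been retrieved; no interpolation.
    """
    pos = set(positives)
    if not pos:
        raise ConfigurationError("empty positive set")
    if not (0.0 < recall_level <= 1.0):
        raise ConfigurationError("recall_level must lie in (0, 1]")
    needed = math.ceil(recall_level * len(pos))
    tp = 0
    for rank, gene in enumerate(ranked, start=1):
        if gene in pos:
            tp += 1
            if tp >= needed:
                return tp / rank
    raise ConfigurationError(
        f"ranking exhausted before reaching recall {recall_level} "
        f"({tp}/{needed} positives found)"
    )


def fold_over_random(precision: float, prior: float) -> float:
    """Precision divided by the positive prevalence; 1.0 is random."""
    if prior <= 0:
        raise ConfigurationError("prior must be positive")
    return precision / prior


def check_no_leakage(
    train_positives: Iterable[str], eval_positives: Iterable[str]
) -> None:
    leaked = set(train_positives) & set(eval_positives)
    if leaked:
        raise LeakageError(
            f"evaluation positives found in training: {sorted(leaked)[:10]}"
        )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def records_frame(records: Iterable[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def summarize(
    records: pd.DataFrame | Iterable[MetricRecord],
    baseline: str = "none",
    metric: str = "fold_over_random",
) -> pd.DataFrame:
    """Per (organism, size_class, method) medians and percent change.

    Percent change = 100 * (median_method - median_baseline) /
    median_baseline, computed against ``baseline`` within each
    (organism, size_class) group; NaN where the baseline group is absent
    or has a zero median.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty:
        return pd.DataFrame(
            columns=["organism", "size_class", "method", "n_terms", f"median_{metric}", "pct_change"]
        )
    grouped = (
        df.groupby(["organism", "size_class", "method"], sort=True)[metric]
        .agg(["median", "count"])
        .reset_index()
        .rename(columns={"median": f"median_{metric}", "count": "n_terms"})
    )
    base = grouped[grouped["method"] == baseline].set_index(["organism", "size_class"])[
        f"median_{metric}"
    ]

    def pct(row):
        b = base.get((row["organism"], row["size_class"]), np.nan)
        if not np.isfinite(b) or b == 0:
            return np.nan
        return 100.0 * (row[f"median_{metric}"] - b) / b

    grouped["pct_change"] = grouped.apply(pct, axis=1)
    return grouped[
        ["organism", "size_class", "method", "n_terms", f"median_{metric}", "pct_change"]
    ]
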
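"""Regularized naive Bayes integration of discretized evidence into a
functional relationship network.

Each dataset D_k is a discretized pairwise evidence channel. Conditional
probability tables P(d_k | FR) are estimated from a pairwise gold standard
with a pseudocount n_s (default 3) spread uniformly over the |D_k| levels.
Redundancy between datasets is estimated as mutual information restricted
to unrelated (negative) gene pairs; each dataset's likelihood is
down-weighted by alpha_k = exp(-U_k), where U_k is the dataset's summed
shared information normalized by its own entropy. The posterior

    P(FR=1 | d) = prior * prod_k P(d_k|1)^alpha_k /
                  (prior * prod_k P(d_k|1)^alpha_k
                   + (1-prior) * prod_k P(d_k|0)^alpha_k)

is evaluated in log space; pairs with no observed evidence fall back to
the prior.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import _condensed
from .errors import ConfigurationError, EvidenceError, UndefinedMIError
from .evidence import Pair, PairwiseEvidence
from .gold import PairGoldStandard
from .network import FunctionalNetwork

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Helpers over condensed evidence
# ---------------------------------------------------------------------------

def _slots_for_pairs(ev: PairwiseEvidence, pairs: Iterable[Pair]) -> np.ndarray:
    """Condensed slots for the given pairs; pairs with unknown genes dropped."""
    idx = ev._index
    n = len(ev.genes)
    ii: List[int] = []
    jj: List[int] = []
    for a, b in pairs:
        ia = idx.get(a)
        ib = idx.get(b)
        if ia is None or ib is None or ia == ib:
            continue
        ii.append(ia)
        jj.append(ib)
    if not ii:
        return np.empty(0, dtype=np.int64)
    return _condensed.pair_index(np.array(ii), np.array(jj), n)


def _observed_levels(ev: PairwiseEvidence, pairs: Iterable[Pair]) -> np.ndarray:
    slots = _slots_for_pairs(ev, pairs)
    levels = ev.levels[slots]
    return levels[levels >= 0]


def entropy_bits(levels: np.ndarray, level_count: int) -> float:
    """Shannon entropy (bits) of an observed level distribution."""
    if levels.size == 0:
        raise UndefinedMIError("entropy undefined on empty support")
    counts = np.bincount(levels, minlength=level_count).astype(float)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def dataset_entropy(ev: PairwiseEvidence, negatives: Iterable[Pair]) -> float:
    return entropy_bits(_observed_levels(ev, negatives), ev.level_count)


def mutual_information_bits(joint: np.ndarray) -> float:
    """MI (bits) from a joint count table; zero cells contribute 0."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if total <= 0:
        raise UndefinedMIError("MI undefined on empty joint support")
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def dataset_mutual_information(
    a: PairwiseEvidence, b: PairwiseEvidence, negatives: Iterable[Pair]
) -> float:
    """MI between two datasets' levels over jointly observed negative pairs."""
    negatives = list(negatives)
    # align on pairs whose genes both datasets know
    shared = [
        p for p in negatives
        if p[0] in a._index and p[1] in a._index
        and p[0] in b._index and p[1] in b._index
    ]
    slots_a = _slots_for_pairs(a, shared)
    slots_b = _slots_for_pairs(b, shared)
    la = a.levels[slots_a]
    lb = b.levels[slots_b]
    ok = (la >= 0) & (lb >= 0)
    la, lb = la[ok], lb[ok]
    if la.size == 0:
        raise UndefinedMIError(
            f"no jointly observed negatives for {a.dataset_id}/{b.dataset_id}"
        )
    joint = np.zeros((a.level_count, b.level_count))
    np.add.at(joint, (la, lb), 1.0)
    return mutual_information_bits(joint)


def compute_alpha(
    k: PairwiseEvidence,
    others: Sequence[PairwiseEvidence],
    negatives: Iterable[Pair],
) -> float:
    """alpha_k = exp(-U_k) with U_k = sum_i I_neg(k, i) / H(D_k).

    A dataset sharing no information with any other keeps alpha_k = 1;
    a constant dataset (H = 0) cannot be weighted and is rejected.
    """
    negatives = list(negatives)
    h = dataset_entropy(k, negatives)
    if h <= 0:
        raise ConfigurationError(
            f"dataset {k.dataset_id} has zero entropy on negatives; rejected"
        )
    u = 0.0
    for other in others:
        if other is k or other.dataset_id == k.dataset_id:
            continue
        try:
            u += dataset_mutual_information(k, other, negatives) / h
        except UndefinedMIError:
            continue  # no joint support contributes nothing
    return math.exp(-u)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class NaiveBayesModel:
    """Fitted CPTs, weights and metadata for the integration."""

    prior: float
    pseudocount: float
    cpts: Dict[str, np.ndarray]  # dataset -> (level_count, 2) columns FR=0 / FR=1
    alphas: Dict[str, float]
    entropies: Dict[str, float]
    level_counts: Dict[str, int]
    bin_edges: Dict[str, Tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.prior < 1.0):
            raise ConfigurationError(f"prior must lie in (0,1), got {self.prior}")
        for ds, cpt in self.cpts.items():
            if np.any(cpt <= 0):
                raise ValueError(f"{ds}: CPT entries must be positive")
            if not np.allclose(cpt.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError(f"{ds}: CPT columns must sum to 1")
        for ds, a in self.alphas.items():
            if not (0.0 < a <= 1.0):
                raise ValueError(f"{ds}: alpha out of (0,1]: {a}")

    @property
    def datasets(self) -> List[str]:
        return list(self.cpts)

    def save(self, path) -> None:
        payload = {
            "prior": self.prior,
            "pseudocount": self.pseudocount,
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
            "alphas": self.alphas,
            "entropies": self.entropies,
            "level_counts": self.level_counts,
            "bin_edges": {k: list(v) for k, v in self.bin_edges.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "NaiveBayesModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            prior=payload["prior"],
            pseudocount=payload["pseudocount"],
            cpts={k: np.array(v) for k, v in payload["cpts"].items()},
            alphas=payload["alphas"],
            entropies=payload["entropies"],
            level_counts={k: int(v) for k, v in payload["level_counts"].items()},
            bin_edges={k: tuple(v) for k, v in payload["bin_edges"].items()},
        )


def fit_cpts(
    evidence: Sequence[PairwiseEvidence],
    gold: PairGoldStandard,
    n_s: float = 3.0,
    prior: float = 0.05,
    regularize: bool = True,
) -> NaiveBayesModel:
    """Estimate smoothed CPTs and redundancy weights from the gold standard.

    P(d_k = v | c) = (count_{v,c} + n_s/|D_k|) / (count_c + n_s). Datasets
    without observed gold-standard pairs in both classes are excluded.
    """
    related = sorted(gold.related)
    unrelated = sorted(gold.unrelated)
    kept: List[PairwiseEvidence] = []
    cpts: Dict[str, np.ndarray] = {}
    for ev in evidence:
        L = ev.level_count
        lr = _observed_levels(ev, related)
        lu = _observed_levels(ev, unrelated)
        if lr.size == 0 or lu.size == 0:
            logger.warning(
                "dataset %s has no gold-standard coverage in one class; excluded",
                ev.dataset_id,
            )
            continue
        cpt = np.empty((L, 2))
        for col, levels in ((1, lr), (0, lu)):
            counts = np.bincount(levels, minlength=L).astype(float)
            cpt[:, col] = (counts + n_s / L) / (counts.sum() + n_s)
        cpts[ev.dataset_id] = cpt
        kept.append(ev)
    if not cpts:
        raise ConfigurationError("no dataset overlaps the gold standard")

    alphas: Dict[str, float] = {}
    entropies: Dict[str, float] = {}
    for ev in kept:
        entropies[ev.dataset_id] = dataset_entropy(ev, unrelated)
        if regularize and len(kept) > 1:
            alphas[ev.dataset_id] = compute_alpha(ev, kept, unrelated)
        else:
            alphas[ev.dataset_id] = 1.0
    return NaiveBayesModel(
        prior=prior,
        pseudocount=n_s,
        cpts=cpts,
        alphas=alphas,
        entropies=entropies,
        level_counts={ev.dataset_id: ev.level_count for ev in kept},
        bin_edges={ev.dataset_id: ev.bin_edges for ev in kept},
    )


def posterior(
    model: NaiveBayesModel,
    observed: Mapping[str, int],
    prior_override: Optional[float] = None,
) -> float:
    """Weighted naive Bayes posterior for one pair's observed levels.

    Datasets absent from ``observed`` are omitted from the product; with no
    observations the posterior equals the prior.
    """
    prior = model.prior if prior_override is None else prior_override
    if not (0.0 < prior < 1.0):
        raise ConfigurationError(f"prior must lie in (0,1), got {prior}")
    logit = math.log(prior) - math.log1p(-prior)
    for ds, level in observed.items():
        if ds not in model.cpts:
            raise EvidenceError(f"unknown dataset {ds!r}")
        cpt = model.cpts[ds]
        if not (0 <= level < cpt.shape[0]):
            raise EvidenceError(
                f"level {level} out of range [0, {cpt.shape[0]}) for dataset {ds!r}"
            )
        a = model.alphas[ds]
        logit += a * (math.log(cpt[level, 1]) - math.log(cpt[level, 0]))
    return 1.0 / (1.0 + math.exp(-logit))


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class RegularizedNaiveBayes(BaseEstimator):
    """sklearn-style estimator wrapping the regularized naive Bayes integration.

    Parameters
    ----------
    prior : float, default 0.05
        P(FR=1); the gold-standard class balance is curation-dependent so
        the prior is a configuration choice, not estimated from counts.
    pseudocount : float, default 3.0
        Total smoothing mass n_s spread uniformly over a dataset's levels.
    regularize : bool, default True
        Apply the mutual-information alpha down-weighting.
    """

    def __init__(self, prior: float = 0.05, pseudocount: float = 3.0, regularize: bool = True):
        self.prior = prior
        self.pseudocount = pseudocount
        self.regularize = regularize

    def fit(self, evidence: Sequence[PairwiseEvidence], gold: PairGoldStandard):
        self.model_ = fit_cpts(
            evidence,
            gold,
            n_s=self.pseudocount,
            prior=self.prior,
            regularize=self.regularize,
        )
        self.datasets_ = self.model_.datasets
        return self

    def predict_pair(self, observed: Mapping[str, int]) -> float:
        return posterior(self.model_, observed)

    def predict_network(
        self,
        evidence: Sequence[PairwiseEvidence],
        organism: Optional[str] = None,
        genes: Optional[Sequence[str]] = None,
    ) -> FunctionalNetwork:
        """Posterior probability for every gene pair of the universe."""
        model = self.model_
        usable = [ev for ev in evidence if ev.dataset_id in model.cpts]
        if organism is None:
            organisms = {ev.organism for ev in usable}
            if len(organisms) != 1:
                raise ConfigurationError(f"ambiguous organism: {sorted(organisms)}")
            organism = organisms.pop()
        if genes is None:
            genes = sorted(set().union(*(set(ev.genes) for ev in usable)))
        genes = list(genes)
        n = len(genes)
        gidx = {g: i for i, g in enumerate(genes)}
        base = math.log(model.prior) - math.log1p(-model.prior)
        logit = np.full(_condensed.n_pairs(n), base)
        for ev in usable:
            cpt = model.cpts[ev.dataset_id]
            a = model.alphas[ev.dataset_id]
            llr = a * (np.log(cpt[:, 1]) - np.log(cpt[:, 0]))
            local = np.array([gidx[g] for g in ev.genes])
            ii, jj = _condensed.pair_arrays(len(ev.genes))
            slots = _condensed.pair_index(local[ii], local[jj], n)
            obs = ev.levels >= 0
            logit[slots[obs]] += llr[ev.levels[obs]]
        probs = 1.0 / (1.0 + np.exp(-logit))
        return FunctionalNetwork.from_condensed(organism, genes, probs)
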
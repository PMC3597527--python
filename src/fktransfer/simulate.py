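"""Synthetic multi-organism worlds with planted families, pathways,
evidence, and asymmetric annotation depth.

The generator emulates the study design the pipeline is built for:
several organisms share a family vocabulary; co-functional gene modules
(pathways) are planted and expressed as elevated pairwise evidence
scores; a fraction of family copies are functionally diverged (same
family, different function); and annotation depth is asymmetric, with a
rotating well-annotated source organism per pathway, one organism with
zero direct annotations, and sparsely annotated organisms in between.
Ground truth (pathway membership, analog pairs, diverged pairs) is
retained so evaluation can score against planted truth rather than
annotations.

Evidence is generated at the pairwise-score level by default; an
expression-matrix mode generates gene x condition matrices for
end-to-end I/O tests.
"""
from __future__ import annotations

import datetime as dt
import itertools
import json
import os
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import _condensed
from .annotations import Annotation, AnnotationSet, EXPERIMENTAL_CODES
from .errors import ConfigurationError
from .evidence import ExpressionDataset, PairwiseEvidence, coexpression_evidence, quantile_bin_edges
from .evaluation import MetricRecord, check_no_leakage, precision_at_recall
from .families import FamilyMap, HomologPair
from .ontology import OntologyDAG

_EVIDENCE_CODE_POOL = tuple(sorted(EXPERIMENTAL_CODES))


@dataclass
class WorldConfig:
    """Generator parameters; defaults are the benchmark's study conditions.

    Evidence scores are on a correlation-like scale: background pairs
    center at ``background_edge_probability_mean`` and within-pathway
    pairs are shifted toward ``within_pathway_edge_probability_mean``,
    scaled by per-family participation weights (core vs peripheral
    pathway members), with Gaussian noise ``edge_noise_sd``.
    """

    seed: int
    n_organisms: int = 3
    genes_per_organism: int = 600
    n_families: int = 560
    paralog_probability: float = 0.10  # family-size distribution: extra within-organism copy
    n_pathways: int = 40
    pathway_size_distribution: Tuple[int, int] = (8, 14)
    # pathways decompose into tightly connected sub-modules (complexes)
    # coupled by weaker cross-edges; sub-module structure is family-
    # conserved across organisms
    submodule_size: int = 4
    inter_submodule_factor: float = 0.7
    within_pathway_edge_probability_mean: float = 0.80
    background_edge_probability_mean: float = 0.30
    edge_noise_sd: float = 0.15
    participation_range: Tuple[float, float] = (0.7, 1.0)
    n_datasets_per_organism: int = 3
    # organism-specific latent co-function modules (multi-functionality):
    # genes co-occur in processes other than the evaluated pathways, which
    # makes rankings from very few positives genuinely ambiguous
    n_latent_modules: int = 50
    latent_size_distribution: Tuple[int, int] = (5, 9)
    latent_participation_range: Tuple[float, float] = (0.5, 1.0)
    fraction_diverged_paralogs: float = 0.15
    source_annotation_density: float = 0.90
    target_annotation_density: float = 0.20
    #: chance that a non-source organism beyond the designated zero one
    #: also carries no direct annotations for a term (understudied depth
    #: varies per organism)
    extra_zero_probability: float = 0.35
    cutoff_date_fraction: float = 0.70
    quantile_edges: Tuple[float, ...] = (0.5, 0.8, 0.95, 0.99)
    evidence_mode: str = "pairwise"  # pairwise | expression
    n_conditions: int = 30
    nonexperimental_rate: float = 0.05
    not_qualifier_rate: float = 0.02

    def validate(self) -> None:
        if self.n_organisms < 1:
            raise ConfigurationError("need at least one organism")
        lo, hi = self.pathway_size_distribution
        if hi > self.genes_per_organism:
            raise ConfigurationError("pathway larger than organism")
        if lo < 2 or hi < lo:
            raise ConfigurationError("bad pathway size distribution")
        if self.n_pathways * hi > self.n_families:
            raise ConfigurationError(
                "not enough families to host the planted pathways"
            )
        if self.n_families > self.genes_per_organism:
            raise ConfigurationError("more families than genes per organism")
        for p in (
            self.paralog_probability,
            self.fraction_diverged_paralogs,
            self.source_annotation_density,
            self.target_annotation_density,
            self.cutoff_date_fraction,
        ):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability out of [0,1]: {p}")
        if self.evidence_mode not in ("pairwise", "expression"):
            raise ConfigurationError(f"bad evidence_mode {self.evidence_mode!r}")


#: all synthetic dates are placed around this fixed cutoff
SYNTHETIC_CUTOFF = dt.date(2010, 1, 1)
ROOT_TERM = "BP:ROOT"


@dataclass
class SyntheticWorld:
    config: WorldConfig
    organisms: List[str]
    genes: Dict[str, List[str]]
    family_map: FamilyMap
    pathway_terms: List[str]
    membership: Dict[Tuple[str, str], FrozenSet[str]]  # (organism, term) -> genes
    analog_truth: FrozenSet[Tuple[str, str]]
    diverged_truth: FrozenSet[Tuple[str, str]]
    homolog_candidates: List[HomologPair]
    rbh_pairs: List[Tuple[str, str, str, str]]
    #: organism-specific latent co-function modules: organism -> list of
    #: (member gene tuple, per-gene participation weight)
    latent_modules: Dict[str, List[Tuple[Tuple[str, ...], Dict[str, float]]]]
    #: pathway member gene -> family-conserved sub-module index
    submodule_of: Dict[str, int]
    evidence: Dict[str, List[PairwiseEvidence]]
    annotations: AnnotationSet
    ontology: OntologyDAG
    cutoff_date: dt.date

    def universe(self, organism: str) -> FrozenSet[str]:
        return frozenset(self.genes[organism])

    def members(self, organism: str, term: str) -> FrozenSet[str]:
        return self.membership.get((organism, term), frozenset())

    def n_direct(self, organism: str, term: str, at_cutoff: bool = True) -> int:
        """Direct experimental annotations of a term (optionally pre-cutoff)."""
        return len(
            {
                r.gene
                for r in self.annotations
                if r.organism == organism
                and r.term == term
                and r.provenance == "direct"
                and r.evidence in EXPERIMENTAL_CODES
                and not r.is_not
                and (not at_cutoff or r.date <= self.cutoff_date)
            }
        )


def _gene_id(org: str, idx: int) -> str:
    return f"{org}:g{idx:04d}"


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Deterministically generate a world from a seeded config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    organisms = [f"org{i + 1}" for i in range(cfg.n_organisms)]
    genes = {org: [_gene_id(org, i) for i in range(cfg.genes_per_organism)] for org in organisms}

    families = [f"FAM{i:04d}" for i in range(cfg.n_families)]
    lo, hi = cfg.pathway_size_distribution
    pathway_sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    pathway_terms = [f"BP:{i:04d}" for i in range(cfg.n_pathways)]

    # family -> pathway (first sum(sizes) families host the pathways);
    # within a pathway, families split into sub-modules of ~submodule_size
    family_pathway: Dict[str, Optional[str]] = {f: None for f in families}
    family_submodule: Dict[str, int] = {}
    cursor = 0
    for term, size in zip(pathway_terms, pathway_sizes):
        for pos, f in enumerate(families[cursor : cursor + size]):
            family_pathway[f] = term
            family_submodule[f] = pos // cfg.submodule_size
        cursor += int(size)

    # family copies: base copy per organism is gene index = family index;
    # paralog copies consume the spare gene indices beyond n_families.
    assignments: Dict[str, str] = {}
    copies: Dict[str, List[Tuple[str, str]]] = {f: [] for f in families}  # (org, gene)
    spare = {org: cfg.n_families for org in organisms}
    for fi, fam in enumerate(families):
        for org in organisms:
            g = genes[org][fi]
            assignments[g] = fam
            copies[fam].append((org, g))
        if rng.random() < cfg.paralog_probability:
            org = organisms[int(rng.integers(cfg.n_organisms))]
            if spare[org] < cfg.genes_per_organism:
                g = genes[org][spare[org]]
                spare[org] += 1
                assignments[g] = fam
                copies[fam].append((org, g))
    family_map = FamilyMap(assignments)

    # divergence flags and pathway membership
    in_pathway: Dict[str, bool] = {}
    membership: Dict[Tuple[str, str], Set[str]] = {
        (org, t): set() for org in organisms for t in pathway_terms
    }
    participation: Dict[str, float] = {}
    submodule_of: Dict[str, int] = {}
    plow, phigh = cfg.participation_range
    for fam in families:
        term = family_pathway[fam]
        if term is None:
            continue
        u = float(rng.uniform(plow, phigh))
        for org, g in copies[fam]:
            diverged = rng.random() < cfg.fraction_diverged_paralogs
            in_pathway[g] = not diverged
            if not diverged:
                membership[(org, term)].add(g)
                participation[g] = u
                submodule_of[g] = family_submodule[fam]

    # homolog candidates and truth labels
    homologs: List[HomologPair] = []
    analog_truth: Set[Tuple[str, str]] = set()
    diverged_truth: Set[Tuple[str, str]] = set()
    for fam in families:
        term = family_pathway[fam]
        for (org_a, ga), (org_b, gb) in itertools.combinations(copies[fam], 2):
            relation = "ortholog" if org_a != org_b else "paralog"
            homologs.append(HomologPair(ga, org_a, gb, org_b, fam, relation))
            if term is not None:
                a_in = in_pathway.get(ga, False)
                b_in = in_pathway.get(gb, False)
                pair = tuple(sorted((ga, gb)))
                if a_in and b_in:
                    analog_truth.add(pair)
                elif a_in != b_in:
                    diverged_truth.add(pair)

    rbh: List[Tuple[str, str, str, str]] = []
    for fam in families:
        base: Dict[str, str] = {}
        for org, g in copies[fam]:
            base.setdefault(org, g)  # first (base) copy is the reciprocal best hit
        for org_a, org_b in itertools.combinations(organisms, 2):
            if org_a in base and org_b in base:
                rbh.append((base[org_a], org_a, base[org_b], org_b))

    # organism-specific latent co-function modules: every gene can take part
    # in processes beyond the planted pathways; these modules elevate
    # evidence just like pathways but carry no annotations, are never
    # evaluated, and do not conserve across organisms.
    latent_modules: Dict[str, List[Tuple[Tuple[str, ...], Dict[str, float]]]] = {}
    llo, lhi = cfg.latent_size_distribution
    ulo, uhi = cfg.latent_participation_range
    for org in organisms:
        mods: List[Tuple[Tuple[str, ...], Dict[str, float]]] = []
        for _ in range(cfg.n_latent_modules):
            size = int(rng.integers(llo, lhi + 1))
            chosen = rng.choice(cfg.genes_per_organism, size=size, replace=False)
            members = tuple(genes[org][int(i)] for i in sorted(chosen))
            weights = {g: float(rng.uniform(ulo, uhi)) for g in members}
            mods.append((members, weights))
        latent_modules[org] = mods

    # evidence
    evidence: Dict[str, List[PairwiseEvidence]] = {org: [] for org in organisms}
    for org in organisms:
        builder = (_pairwise_evidence if cfg.evidence_mode == "pairwise"
                   else _expression_evidence)
        evidence[org] = builder(
            cfg, rng, org, genes[org], membership, participation,
            pathway_terms, latent_modules[org], submodule_of
        )

    # annotations with rotating source organism per term
    records: List[Annotation] = []
    for ti, term in enumerate(pathway_terms):
        rotation = [organisms[(ti + k) % cfg.n_organisms] for k in range(cfg.n_organisms)]
        densities: Dict[str, float] = {rotation[0]: cfg.source_annotation_density}
        if cfg.n_organisms > 1:
            densities[rotation[1]] = 0.0
        for org in rotation[2:]:
            # understudied organisms mostly hold 1-2 direct annotations;
            # a minority of terms are moderately covered
            if rng.random() < cfg.extra_zero_probability:
                densities[org] = 0.0
            elif rng.random() < 0.75:
                densities[org] = float(rng.uniform(0.03, cfg.target_annotation_density))
            else:
                densities[org] = float(
                    rng.uniform(
                        1.4 * cfg.target_annotation_density,
                        min(0.9, 2.3 * cfg.target_annotation_density),
                    )
                )
        for org in organisms:
            density = densities[org]
            for g in sorted(membership[(org, term)]):
                if rng.random() >= density:
                    continue
                if rng.random() < cfg.cutoff_date_fraction:
                    date = SYNTHETIC_CUTOFF - dt.timedelta(days=int(rng.integers(1, 366)))
                else:
                    date = SYNTHETIC_CUTOFF + dt.timedelta(days=int(rng.integers(1, 366)))
                if rng.random() < cfg.nonexperimental_rate:
                    code = "IEA"
                else:
                    code = _EVIDENCE_CODE_POOL[int(rng.integers(len(_EVIDENCE_CODE_POOL)))]
                qualifier = "NOT" if rng.random() < cfg.not_qualifier_rate else ""
                records.append(
                    Annotation(
                        gene=g, organism=org, term=term, evidence=code,
                        date=date, qualifier=qualifier,
                    )
                )

    ontology = OntologyDAG({t: {ROOT_TERM} for t in pathway_terms})
    return SyntheticWorld(
        config=cfg,
        organisms=organisms,
        genes=genes,
        family_map=family_map,
        pathway_terms=pathway_terms,
        membership={k: frozenset(v) for k, v in membership.items()},
        analog_truth=frozenset(analog_truth),
        diverged_truth=frozenset(diverged_truth),
        homolog_candidates=homologs,
        rbh_pairs=rbh,
        latent_modules=latent_modules,
        submodule_of=submodule_of,
        evidence=evidence,
        annotations=AnnotationSet(records),
        ontology=ontology,
        cutoff_date=SYNTHETIC_CUTOFF,
    )


def _elevate_group(rng, cfg, values, n, gidx, members, weights, submodule=None):
    """Raise the pairwise scores of a co-functioning gene group.

    With ``submodule`` given, pairs in different sub-modules receive only
    ``inter_submodule_factor`` of the full signal gap.
    """
    if len(members) < 2:
        return
    gap = (cfg.within_pathway_edge_probability_mean
           - cfg.background_edge_probability_mean)
    idx = np.array([gidx[g] for g in members])
    u = np.array([weights[g] for g in members])
    ii, jj = np.triu_indices(len(idx), k=1)
    slots = _condensed.pair_index(idx[ii], idx[jj], n)
    effect = gap * u[ii] * u[jj]
    if submodule is not None:
        sub = np.array([submodule[g] for g in members])
        effect = np.where(sub[ii] == sub[jj], effect,
                          effect * cfg.inter_submodule_factor)
    means = cfg.background_edge_probability_mean + effect
    values[slots] = rng.normal(means, cfg.edge_noise_sd)


def _pairwise_evidence(cfg, rng, org, org_genes, membership, participation,
                       pathway_terms, latents, submodule_of):
    n = len(org_genes)
    gidx = {g: i for i, g in enumerate(org_genes)}
    datasets = []
    for d in range(cfg.n_datasets_per_organism):
        values = rng.normal(cfg.background_edge_probability_mean,
                            cfg.edge_noise_sd, _condensed.n_pairs(n))
        # latent modules first: a pair in both a latent module and a
        # pathway keeps the pathway's (conserved) signal
        for members, weights in latents:
            _elevate_group(rng, cfg, values, n, gidx, members, weights)
        for term in pathway_terms:
            members = sorted(membership[(org, term)])
            _elevate_group(rng, cfg, values, n, gidx, members, participation,
                           submodule=submodule_of)
        edges = quantile_bin_edges(values, cfg.quantile_edges)
        datasets.append(
            PairwiseEvidence(f"{org}-ds{d}", org, org_genes, values, edges)
        )
    return datasets


def _expression_evidence(cfg, rng, org, org_genes, membership, participation,
                         pathway_terms, latents, submodule_of):
    n = len(org_genes)
    gidx = {g: i for i, g in enumerate(org_genes)}
    inter_loading = float(np.sqrt(cfg.inter_submodule_factor))
    datasets = []
    for d in range(cfg.n_datasets_per_organism):
        mat = rng.normal(0.0, 1.0, (n, cfg.n_conditions))
        for members, weights in latents:
            factor = rng.normal(0.0, 1.0, cfg.n_conditions)
            for g in members:
                mat[gidx[g]] += 1.5 * weights[g] * factor
        for term in pathway_terms:
            # shared pathway factor (weak) plus per-sub-module factors
            shared = rng.normal(0.0, 1.0, cfg.n_conditions)
            subs = sorted({submodule_of[g] for g in membership[(org, term)]})
            sub_factors = {s: rng.normal(0.0, 1.0, cfg.n_conditions) for s in subs}
            for g in membership[(org, term)]:
                u = 1.5 * participation[g]
                mat[gidx[g]] += u * inter_loading * shared
                mat[gidx[g]] += u * sub_factors[submodule_of[g]]
        ds = ExpressionDataset(
            f"{org}-expr{d}", org,
            pd.DataFrame(mat, index=org_genes,
                         columns=[f"c{i}" for i in range(cfg.n_conditions)]),
        )
        datasets.append(coexpression_evidence(ds, quantiles=cfg.quantile_edges))
    return datasets


# ---------------------------------------------------------------------------
# Truth-based metrics
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    organism: str
    term: str
    method: str
    ranking: pd.DataFrame  # from classifiers.rank_genes
    training_positives: FrozenSet[str]
    #: genes excluded from evaluation (defaults to the training positives;
    #: set to the union over compared modes for paired comparisons)
    eval_exclusions: Optional[FrozenSet[str]] = None


def world_truth_metrics(
    world: SyntheticWorld,
    predictions: Iterable[PredictionResult],
    recall_level: float = 0.10,
) -> List[MetricRecord]:
    """Score predictions against planted pathway membership.

    Evaluation positives are planted members minus the excluded genes (at
    least the training positives; for mode comparisons the union of
    training positives across modes, so compared methods face identical
    targets). Excluded genes are removed from the ranking before the
    metric is computed, and the leakage check runs on every record.
    """
    out: List[MetricRecord] = []
    for pred in predictions:
        excl = pred.eval_exclusions or pred.training_positives
        excl = frozenset(excl) | pred.training_positives
        truth = world.members(pred.organism, pred.term) - excl
        if not truth:
            continue
        check_no_leakage(pred.training_positives, truth)
        mask = ~pred.ranking["gene"].isin(excl)
        ranked = list(pred.ranking.loc[mask, "gene"])
        if not ranked:
            continue
        prec = precision_at_recall(ranked, truth, recall_level)
        prior = len(truth) / len(ranked)
        out.append(
            MetricRecord(
                term=pred.term,
                organism=pred.organism,
                method=pred.method,
                n_direct_at_cutoff=world.n_direct(pred.organism, pred.term),
                n_eval_positives=len(truth),
                precision_at_recall=prec,
                prior=prior,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Serialization (same dialects the real pipeline reads)
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, outdir) -> None:
    from .io import write_gaf, write_evidence_tsv
    from .families import write_homolog_pairs

    os.makedirs(outdir, exist_ok=True)
    world.ontology.to_obo(os.path.join(outdir, "ontology.obo"))
    write_gaf(world.annotations, os.path.join(outdir, "annotations.gaf"))
    world.family_map.write_tsv(os.path.join(outdir, "families.tsv"))
    write_homolog_pairs(world.homolog_candidates, os.path.join(outdir, "homologs.tsv"))
    with open(os.path.join(outdir, "rbh.tsv"), "w") as fh:
        for ga, oa, gb, ob in sorted(world.rbh_pairs):
            fh.write(f"{ga}\t{oa}\t{gb}\t{ob}\n")
    for org, datasets in world.evidence.items():
        for ev in datasets:
            write_evidence_tsv(ev, os.path.join(outdir, f"{ev.dataset_id}.pairs.tsv"))
    truth = {
        "organisms": world.organisms,
        "pathway_terms": world.pathway_terms,
        "membership": {
            f"{org}|{term}": sorted(gs) for (org, term), gs in world.membership.items()
        },
        "analog_truth": sorted(map(list, world.analog_truth)),
        "diverged_truth": sorted(map(list, world.diverged_truth)),
        "cutoff_date": world.cutoff_date.isoformat(),
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
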
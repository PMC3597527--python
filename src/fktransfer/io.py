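"""Readers and writers for the pipeline's text formats.

GAF 2.x (15 tab-separated columns) for annotations, OBO for the ontology
(via :mod:`ontology`), DAT-style three-column TSV for networks, and plain
TSV for evidence tables, families, and homolog pairs.
"""
from __future__ import annotations

import csv
import datetime as dt
import logging
from typing import Dict, List, Optional, Sequence, Tuple

from .annotations import Annotation, AnnotationSet
from .errors import ConfigurationError, EvidenceError
from .evidence import (
    ExpressionDataset,
    PairwiseEvidence,
    PhenotypeCollection,
    canonical_pair,
    discretize,
)
from .network import FunctionalNetwork

logger = logging.getLogger(__name__)

GAF_COLUMNS = 15


# ---------------------------------------------------------------------------
# GAF
# ---------------------------------------------------------------------------

def _parse_gaf_date(raw: str) -> dt.date:
    return dt.datetime.strptime(raw, "%Y%m%d").date()


def read_annotations(path, require_date: bool = True) -> AnnotationSet:
    """Parse a GAF 2.x file; comment lines (!) skipped, malformed rows logged.

    Column map (1-based): 2 gene id, 4 qualifier, 5 term, 7 evidence code,
    8 with/from (source gene for transferred records), 13 taxon/organism,
    14 date (YYYYMMDD), 15 assigned-by (carries transfer provenance).
    """
    records: List[Annotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < GAF_COLUMNS:
                logger.warning("%s:%d: %d columns, expected >=%d; row skipped",
                               path, lineno, len(cols), GAF_COLUMNS)
                continue
            try:
                date = _parse_gaf_date(cols[13])
            except ValueError:
                if require_date:
                    raise ConfigurationError(
                        f"{path}:{lineno}: bad or missing date {cols[13]!r}"
                    ) from None
                logger.warning("%s:%d: bad date %r; row skipped", path, lineno, cols[13])
                continue
            assigned = cols[14]
            if assigned.startswith("transferred"):
                provenance = "transferred"
                source_org = assigned.partition(":")[2] or None
                source_gene = cols[7] or None
            else:
                provenance = "direct"
                source_org = None
                source_gene = None
            organism = cols[12].removeprefix("taxon:")
            try:
                records.append(
                    Annotation(
                        gene=cols[1],
                        organism=organism,
                        term=cols[4],
                        evidence=cols[6],
                        date=date,
                        qualifier=cols[3],
                        provenance=provenance,
                        source_gene=source_gene,
                        source_organism=source_org,
                    )
                )
            except ValueError as exc:
                logger.warning("%s:%d: %s; row skipped", path, lineno, exc)
    return AnnotationSet(records)


def write_gaf(anns: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for r in sorted(
            anns, key=lambda r: (r.organism, r.gene, r.term, r.date, r.evidence)
        ):
            assigned = (
                f"transferred:{r.source_organism or ''}"
                if r.provenance == "transferred"
                else "direct"
            )
            cols = [
                "SYN", r.gene, r.gene, r.qualifier, r.term, "REF:0000001",
                r.evidence, r.source_gene or "", "P", "", "", "gene",
                f"taxon:{r.organism}", r.date.strftime("%Y%m%d"), assigned,
            ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Networks (DAT-style TSV)
# ---------------------------------------------------------------------------

def write_network(net: FunctionalNetwork, path) -> None:
    """Canonical form: lexicographically ordered pairs, 6-decimal probability."""
    edges = net.edges()
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\t{edges[(a, b)]:.6f}\n")


def read_network(path, organism: str = "organism") -> FunctionalNetwork:
    edges: Dict[Tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ConfigurationError(f"{path}:{lineno}: expected 3 columns")
            a, b, raw = parts
            if a == b:
                raise ConfigurationError(f"{path}:{lineno}: self-edge {a!r}")
            p = float(raw)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"{path}:{lineno}: probability {p} outside [0, 1]"
                )
            pair = canonical_pair(a, b)
            if pair in edges and edges[pair] != p:
                raise ConfigurationError(
                    f"{path}:{lineno}: conflicting duplicate edge {pair}"
                )
            edges[pair] = p
    return FunctionalNetwork.from_edges(organism, edges)


# ---------------------------------------------------------------------------
# Evidence tables
# ---------------------------------------------------------------------------

def write_evidence_tsv(ev: PairwiseEvidence, path) -> None:
    fh_edges = ",".join(repr(e) for e in ev.bin_edges)
    score_map = ev.score_map()
    with open(path, "w") as fh:
        fh.write(f"#dataset={ev.dataset_id}\torganism={ev.organism}\tbin_edges={fh_edges}\n")
        for a, b in sorted(score_map):
            fh.write(f"{a}\t{b}\t{score_map[(a, b)]!r}\n")


def read_evidence_tsv(
    path,
    dataset_id: Optional[str] = None,
    organism: Optional[str] = None,
    bin_edges: Optional[Sequence[float]] = None,
) -> PairwiseEvidence:
    scores: Dict[Tuple[str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for field in line.lstrip("#").split("\t"):
                    key, _, val = field.partition("=")
                    if key == "dataset" and dataset_id is None:
                        dataset_id = val
                    elif key == "organism" and organism is None:
                        organism = val
                    elif key == "bin_edges" and bin_edges is None:
                        bin_edges = [float(x) for x in val.split(",")]
                continue
            a, b, raw = line.split("\t")
            scores[canonical_pair(a, b)] = float(raw)
    if bin_edges is None:
        raise ConfigurationError(f"{path}: no bin edges given or embedded")
    return discretize(
        scores, bin_edges, dataset_id=dataset_id or "dataset", organism=organism or "organism"
    )


def read_expression_tsv(path, dataset_id: str, organism: str) -> ExpressionDataset:
    """Genes in rows, header row of condition ids."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionDataset(dataset_id, organism, df.astype(float))


def read_interactions_tsv(path) -> List[Tuple[Tuple[str, str], str]]:
    """(gene_a, gene_b, assay_type, source) rows -> [(pair, assay_type)]."""
    records: List[Tuple[Tuple[str, str], str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            records.append(((row[0], row[1]), row[2] if len(row) > 2 else ""))
    return records


def read_motif_tsv(path):
    """Binary gene x motif matrix."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~df.isin([0, 1]).all(axis=None)
    if bad:
        raise EvidenceError(f"{path}: motif matrix must be binary")
    return df.astype(int)


def read_phenotypes_tsv(path) -> PhenotypeCollection:
    """Two-column (phenotype_id, gene) TSV."""
    sets: Dict[str, set] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            sets.setdefault(row[0], set()).add(row[1])
    return PhenotypeCollection({k: frozenset(v) for k, v in sets.items()})
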
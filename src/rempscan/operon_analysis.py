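"""Chaperone–CISM operon association analysis.

Classifies each chaperone locus as *cis* (inside the cognate enzyme
operon), *trans* (a complete cognate gene set exists elsewhere in the
genome) or *absent*; computes the frequency-of-gene-occurrence statistic
F^G = (n_gene / n_locus) / O over ORF-radius neighborhoods; positional
architecture fractions (e.g. how often narJ sits between narH and narI);
and phi-coefficient presence/absence correlations across genomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    AnnotationTable,
    GeneRecord,
    Neighborhood,
    OperonCall,
    operon_of,
)

__all__ = [
    "CognateSet",
    "CismDefinition",
    "AssociationResult",
    "UndefinedStatisticError",
    "classify_association",
    "gene_frequency",
    "positional_profile",
    "presence_correlation",
    "has_mobile_element",
    "gene_matches",
    "load_definitions",
    "DEFAULT_DEFINITIONS",
]

MOBILE_ELEMENT_RE = re.compile(r"transposase|integrase|insertion sequence", re.I)


class UndefinedStatisticError(ValueError):
    """A statistic was requested on an empty or degenerate input."""


@dataclass(frozen=True)
class CognateSet:
    """A named set of cognate enzyme gene symbols (e.g. torD_torAC -> torA,torC)."""

    label: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"cognate set {self.label!r} is empty")


@dataclass(frozen=True)
class CismDefinition:
    """Chaperone family with its candidate cognate enzyme gene sets, in
    priority order (set order breaks overlap ties deterministically)."""

    family: str
    cognate_sets: tuple[CognateSet, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.cognate_sets]
        if len(labels) != len(set(labels)):
            raise ValueError(f"{self.family}: duplicate cognate-set labels")


@dataclass
class AssociationResult:
    genome_id: str
    locus_tag: str
    family: str
    matched_set_label: str | None
    mode: str  # cis | trans | absent
    evidence: list[tuple[str, str]] = field(default_factory=list)
    flanked_by: tuple[str | None, str | None] | None = None
    mobile_element: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans", "absent"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if (self.mode == "absent") != (self.matched_set_label is None):
            raise ValueError("mode=absent iff matched_set_label is None")


def gene_matches(record: GeneRecord, symbol: str) -> bool:
    """Gene identity: symbol equals gene_name, else case-insensitive
    substring of the product text."""
    sym = symbol.lower()
    if record.gene_name.lower() == sym:
        return True
    return bool(record.product) and sym in record.product.lower()


def has_mobile_element(neighborhood: Neighborhood) -> bool:
    """True if any neighbor's product looks like a transposase/integrase/IS."""
    return any(
        MOBILE_ELEMENT_RE.search(rec.product or "") for rec in neighborhood.neighbors
    )


def classify_association(
    table: AnnotationTable,
    operons: Sequence[OperonCall],
    locus_tag: str,
    definition: CismDefinition,
) -> AssociationResult:
    """Classify one chaperone locus as cis / trans / absent.

    cis: at least one gene of any cognate set shares the focal gene's
    operon call (incomplete operons still count); the matched set is the
    one with the largest in-operon overlap, ties broken by definition
    order. trans: no cognate gene co-operonic, but some cognate set is
    *complete* anywhere in the genome. absent: otherwise.
    """
    focal = table.get(locus_tag)
    focal_op = operon_of(operons, locus_tag)
    members = [table.get(t) for t in focal_op.member_locus_tags if t != locus_tag]

    best: CognateSet | None = None
    best_hits: list[tuple[str, str]] = []
    for cset in definition.cognate_sets:
        hits = [
            (sym, rec.locus_tag)
            for sym in cset.genes
            for rec in members
            if gene_matches(rec, sym)
        ]
        n_genes_hit = len({sym for sym, _ in hits})
        if n_genes_hit > 0 and (best is None or n_genes_hit > len({s for s, _ in best_hits})):
            best, best_hits = cset, hits

    flanks = _flanking_symbols(table, focal_op, focal)

    if best is not None:
        return AssociationResult(
            genome_id=table.genome_id,
            locus_tag=locus_tag,
            family=definition.family,
            matched_set_label=best.label,
            mode="cis",
            evidence=best_hits,
            flanked_by=flanks,
        )

    # trans: first definition-order set complete anywhere in the genome
    others = [r for r in table.records if r.locus_tag != locus_tag]
    for cset in definition.cognate_sets:
        evidence: list[tuple[str, str]] = []
        complete = True
        for sym in cset.genes:
            match = next((r for r in others if gene_matches(r, sym)), None)
            if match is None:
                complete = False
                break
            evidence.append((sym, match.locus_tag))
        if complete:
            return AssociationResult(
                genome_id=table.genome_id,
                locus_tag=locus_tag,
                family=definition.family,
                matched_set_label=cset.label,
                mode="trans",
                evidence=evidence,
                flanked_by=flanks,
            )

    return AssociationResult(
        genome_id=table.genome_id,
        locus_tag=locus_tag,
        family=definition.family,
        matched_set_label=None,
        mode="absent",
        flanked_by=flanks,
    )


def _flanking_symbols(
    table: AnnotationTable, operon: OperonCall, focal: GeneRecord
) -> tuple[str | None, str | None]:
    """Gene symbols of the operon members immediately before/after the
    focal gene in coordinate order (None at operon edges)."""
    tags = list(operon.member_locus_tags)
    i = tags.index(focal.locus_tag)
    before = table.get(tags[i - 1]).gene_name if i > 0 else None
    after = table.get(tags[i + 1]).gene_name if i < len(tags) - 1 else None
    return (before or None, after or None)


def gene_frequency(
    family: str,
    neighborhoods: Sequence[Neighborhood],
    n_operons: int,
    symbols: Iterable[str],
) -> pd.DataFrame:
    """Frequency-of-gene-occurrence table for one chaperone family.

    For each symbol, ``n_gene`` counts neighborhoods (loci) whose radius
    window contains the gene at least once — duplicates within one
    neighborhood count once. ``raw_fraction = n_gene / n_locus``;
    ``f_g = raw_fraction / n_operons`` (the statistic divides the locus
    fraction by the number of family operons examined).
    """
    n_locus = len(neighborhoods)
    if n_locus == 0 or n_operons == 0:
        raise UndefinedStatisticError(
            f"{family}: gene_frequency needs >=1 locus and >=1 operon"
        )
    rows = []
    for sym in symbols:
        n_gene = sum(
            any(gene_matches(rec, sym) for rec in nb.neighbors)
            for nb in neighborhoods
        )
        raw = n_gene / n_locus
        rows.append(
            {
                "family": family,
                "gene_symbol": sym,
                "n_gene": n_gene,
                "n_locus": n_locus,
                "n_operons": n_operons,
                "raw_fraction": raw,
                "f_g": raw / n_operons,
            }
        )
    return pd.DataFrame(rows)


def positional_profile(
    results: Sequence[AssociationResult],
    family: str,
    flank_pair: tuple[str, str],
) -> float:
    """Fraction of *cis* loci of ``family`` flanked by the unordered pair."""
    cis = [r for r in results if r.family == family and r.mode == "cis"]
    if not cis:
        raise UndefinedStatisticError(f"{family}: no cis loci to profile")
    want = frozenset(s.lower() for s in flank_pair)
    hits = sum(
        1
        for r in cis
        if r.flanked_by is not None
        and frozenset(s.lower() for s in r.flanked_by if s) == want
    )
    return hits / len(cis)


def presence_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between binary presence/absence columns (phi coefficients).

    Rows are genomes, columns operon-type or gene-set labels, cells 0/1.
    Constant columns yield NaN (undefined), never 0; the diagonal is 1
    wherever the column varies.
    """
    if matrix.shape[0] < 2:
        raise UndefinedStatisticError("need >= 2 genomes (rows)")
    if matrix.shape[1] < 2:
        raise UndefinedStatisticError("need >= 2 columns")
    x = matrix.to_numpy(dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("presence matrix must be binary")
    centered = x - x.mean(axis=0)
    sd = x.std(axis=0)
    n = x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = centered.T @ centered / n
        r = cov / np.outer(sd, sd)
    r[np.isclose(np.outer(sd, sd), 0.0)] = np.nan
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(r, index=matrix.columns, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Definitions


def load_definitions(path_or_mapping) -> list[CismDefinition]:
    """Load chaperone-family cognate definitions from YAML/JSON or a mapping.

    Layout::

        narJ:
          narJ_narGHI: [narG, narH, narI]
        torD:
          torD_torAC: [torA, torC]
          torD_fdh: [fdhG, fdhH, fdhI]
    """
    if isinstance(path_or_mapping, Mapping):
        data = path_or_mapping
    else:
        with open(path_or_mapping) as fh:
            data = yaml.safe_load(fh)
    defs = []
    for family, sets in data.items():
        defs.append(
            CismDefinition(
                family=family,
                cognate_sets=tuple(
                    CognateSet(label, tuple(genes)) for label, genes in sets.items()
                ),
            )
        )
    return defs


#: Cognate gene sets of the five characterized chaperone families, as
#: observed in prokaryotic genome neighborhoods: nitrate reductases for
#: NarJ/NarW, DMSO/selenate/formate systems for DmsD, TMAO/formate and the
#: nrfD-hybA-bisC operon for TorD, and the Zn-enzyme operons for YcdY.
DEFAULT_DEFINITIONS: dict[str, dict[str, list[str]]] = {
    "narJ": {
        "narJ_narGHI": ["narG", "narH", "narI"],
    },
    "narW": {
        "narW_narZYV": ["narZ", "narY", "narV"],
    },
    "dmsD": {
        "dmsD_dmsABC": ["dmsA", "dmsB", "dmsC"],
        "dmsD_ynf": ["ynfE", "ynfF", "ynfG", "ynfH"],
        "dmsD_fdh": ["fdhG", "fdhH", "fdhI"],
        "dmsD_bisC-nrfD": ["nrfD", "hybA", "bisC"],
    },
    "torD": {
        "torD_torAC": ["torA", "torC"],
        "torD_fdh": ["fdhG", "fdhH", "fdhI"],
        "torD_bisC-nrfD": ["nrfD", "hybA", "bisC"],
    },
    "ycdY": {
        "ycdY_ycdX": ["ycdX"],
        "ycdY_hflC-mdaB": ["hflC", "mdaB"],
    },
}


def default_definitions() -> list[CismDefinition]:
    return load_definitions(DEFAULT_DEFINITIONS)
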
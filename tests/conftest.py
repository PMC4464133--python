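"""Shared fixtures: toy annotation tables and an independent
Nei–Gojobori enumeration oracle.

The oracle is written directly from the counting definition — synonymous
site fractions by enumerating single-nucleotide mutants, substitution
pathways by recursive enumeration — using Biopython's translator, so it
shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import pytest
from Bio.Seq import Seq

from rempscan.annotation_io import AnnotationTable, GeneRecord

NUCS = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def oracle_codons():
    """All 61 sense codons under table 11."""
    return [
        "".join(c)
        for c in itertools.product(NUCS, repeat=3)
        if _aa("".join(c)) != "*"
    ]


def oracle_sites(codon: str) -> tuple[float, float]:
    """Synonymous/non-synonymous site counts by mutant enumeration."""
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        fates = []
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            mut_aa = _aa(codon[:pos] + nt + codon[pos + 1 :])
            if mut_aa != "*":
                fates.append(mut_aa == aa)
        if fates:
            s += sum(fates) / len(fates)
    return s, 3.0 - s


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) by recursive pathway enumeration."""
    paths: list[tuple[float, float]] = []

    def walk(cur: str, sd: float, nd: float) -> None:
        if cur == b:
            paths.append((sd, nd))
            return
        for pos in range(3):
            if cur[pos] == b[pos]:
                continue
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                continue
            if _aa(nxt) == _aa(cur):
                walk(nxt, sd + 1, nd)
            else:
                walk(nxt, sd, nd + 1)

    walk(a, 0.0, 0.0)
    if not paths:
        return None  # all pathways stop-blocked; implementation falls back
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@pytest.fixture(scope="session")
def ng_oracle():
    class Oracle:
        codons = staticmethod(oracle_codons)
        sites = staticmethod(oracle_sites)
        differences = staticmethod(oracle_differences)

    return Oracle


def make_table(
    genes,
    genome_id="G1",
    contig="c1",
    start=100,
    gap=50,
    length=300,
):
    """Build a toy AnnotationTable from (gene_name, strand[, product]) tuples.

    ``gap`` may be an int or a list of per-gene leading gaps.
    """
    records = []
    pos = start
    for i, g in enumerate(genes):
        name, strand = g[0], g[1]
        product = g[2] if len(g) > 2 else (f"{name} protein" if name else "hypothetical protein")
        this_gap = gap[i] if isinstance(gap, (list, tuple)) else gap
        if i > 0:
            pos = records[-1].end + 1 + this_gap
        records.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=contig,
                locus_tag=f"{genome_id}_{i:04d}",
                gene_name=name,
                product=product,
                start=pos,
                end=pos + length - 1,
                strand=strand,
            )
        )
    return AnnotationTable(genome_id, records)


@pytest.fixture
def toy_table():
    return make_table


@pytest.fixture(scope="session")
def small_dataset():
    """A small deterministic synthetic dataset shared across tests."""
    from rempscan.synthetic_data import EvolutionConfig, generate_dataset

    return generate_dataset(12, seed=11, evolution=EvolutionConfig(length=120))
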
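"""Synthetic annotated genomes and codon alignments.

Generates genomes whose gene neighborhoods reproduce the operon
architectures observed around NarJ-subfamily chaperone loci
(narGHJI ± narK/narU/ppiC, narZYWV + narU, dmsABC(D), ynfEFGHI,
torACD ± torRST, ycdXY, hflC–mdaB, fdhGHI ± DUF3305/DUF3306/hybA,
nrfD–hybA–bisC), with configurable cis/trans placement fractions,
flanking-position probabilities and transposase insertions — plus codon
sequences diverged from family ancestors under a configurable dN/dS
(omega), so the whole analysis pipeline is testable without downloads.

Everything is deterministic for a fixed integer seed
(``numpy.random.default_rng``); indels are off by default so the protein
MSA is exact by construction and needs no aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_io import AnnotationTable, GeneRecord
from .codon_evolution import (
    GAP_CODON,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
)

__all__ = [
    "GeneSpec",
    "OperonVariant",
    "OperonLayout",
    "GenomeTemplate",
    "EvolutionConfig",
    "GenomeSim",
    "Dataset",
    "generate_genome",
    "evolve_pair",
    "random_cds",
    "generate_dataset",
    "default_template_library",
    "PRODUCTS",
    "DEFAULT_FAMILY_OMEGA",
]

_NUCS = "ACGT"

#: Product annotations attached to generated genes, mirroring common
#: prokaryotic annotation phrasing so product-text matching is exercised.
PRODUCTS: dict[str, str] = {
    "narG": "nitrate reductase alpha subunit",
    "narH": "nitrate reductase beta iron-sulfur subunit",
    "narI": "nitrate reductase gamma membrane anchor subunit",
    "narJ": "nitrate reductase delta subunit chaperone",
    "narK": "nitrate/nitrite MFS transporter",
    "narU": "nitrate/nitrite MFS transporter NarU",
    "narZ": "nitrate reductase Z alpha subunit",
    "narY": "nitrate reductase Z beta subunit",
    "narV": "nitrate reductase Z gamma subunit",
    "narW": "nitrate reductase Z delta subunit chaperone",
    "ppiC": "parvulin-like peptidyl-prolyl isomerase",
    "dmsA": "DMSO reductase alpha molybdoenzyme subunit",
    "dmsB": "DMSO reductase beta iron-sulfur subunit",
    "dmsC": "DMSO reductase membrane anchor subunit",
    "dmsD": "DMSO reductase maturation chaperone",
    "ynfE": "putative selenate reductase subunit YnfE",
    "ynfF": "putative selenate reductase subunit YnfF",
    "ynfG": "putative selenate reductase iron-sulfur subunit",
    "ynfH": "putative selenate reductase membrane anchor",
    "torA": "TMAO reductase I catalytic subunit",
    "torC": "TMAO reductase c-type cytochrome",
    "torD": "TMAO reductase maturation chaperone",
    "torR": "two-component response regulator TorR",
    "torS": "sensory histidine kinase TorS",
    "torT": "periplasmic TMAO sensor TorT",
    "fdhG": "formate dehydrogenase-N alpha molybdoenzyme subunit",
    "fdhH": "formate dehydrogenase-N beta iron-sulfur subunit",
    "fdhI": "formate dehydrogenase-N gamma membrane anchor subunit",
    "hybA": "hydrogenase 4Fe-4S ferredoxin-type component",
    "nrfD": "polysulfide reductase/formate-dependent nitrite reductase membrane component",
    "bisC": "biotin sulfoxide reductase family molybdoenzyme",
    "ycdX": "zinc-binding alkaline phosphatase/hydrolase",
    "ycdY": "zinc-enzyme maturation chaperone YcdY",
    "hflC": "FtsH protease membrane modulator HflC",
    "mdaB": "NADPH-quinone reductase MdaB",
    "duf3305": "membrane protein of unknown function DUF3305",
    "duf3306": "membrane protein of unknown function DUF3306",
    "tnp": "IS family transposase",
    "filler": "hypothetical protein",
}


@dataclass(frozen=True)
class GeneSpec:
    """A gene slot in an operon layout, included with probability ``prob``."""

    symbol: str
    prob: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"{self.symbol}: prob must be in [0,1]")


def _as_spec(g) -> GeneSpec:
    return g if isinstance(g, GeneSpec) else GeneSpec(g)


@dataclass(frozen=True)
class OperonVariant:
    """One discrete gene order for a layout, drawn with probability ``prob``."""

    prob: float
    genes: tuple[GeneSpec, ...]


@dataclass
class OperonLayout:
    """An operon architecture carrying (optionally) one chaperone gene.

    ``variants`` are alternative gene orders (probabilities must sum to
    1); each lists the chaperone at its canonical slot. ``cis_prob`` is
    the probability the chaperone is placed cis (in the operon) versus
    trans (elsewhere on the contig); ``placement="absent"`` drops it
    entirely. ``flank_prob`` is the probability a cis chaperone keeps its
    canonical slot rather than moving to a random other slot.
    """

    variants: list[OperonVariant]
    chaperone: str | None = None
    strand: str = "+"
    cis_prob: float | None = None  # None: use `placement` deterministically
    placement: str = "cis"  # cis | trans | absent
    flank_prob: float = 1.0
    transposase_prob: float = 0.0

    @classmethod
    def simple(cls, genes: Sequence, **kwargs) -> "OperonLayout":
        return cls(variants=[OperonVariant(1.0, tuple(_as_spec(g) for g in genes))], **kwargs)

    def __post_init__(self) -> None:
        total = sum(v.prob for v in self.variants)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant probabilities sum to {total}, expected 1")
        if self.placement not in ("cis", "trans", "absent"):
            raise ValueError(f"invalid placement {self.placement!r}")
        if self.chaperone is not None:
            for v in self.variants:
                if self.chaperone not in [g.symbol for g in v.genes]:
                    raise ValueError(
                        f"chaperone {self.chaperone!r} missing from a variant"
                    )


@dataclass
class GenomeTemplate:
    """Blueprint for one synthetic genome."""

    phylum: str
    layouts: list[OperonLayout]
    gap_range: tuple[int, int] = (20, 120)  # intra-operon intergenic gaps, bp
    spacer_gap_range: tuple[int, int] = (250, 450)  # between blocks (> max_gap)
    filler_between: tuple[int, int] = (12, 16)  # filler genes between blocks
    gene_length_range: tuple[int, int] = (300, 900)  # bp, rounded to codons

    def __post_init__(self) -> None:
        if self.gap_range[0] > self.gap_range[1] or self.gap_range[0] < 0:
            raise ValueError("invalid gap_range")
        if self.spacer_gap_range[0] <= 150:
            raise ValueError("spacer gaps must exceed the operon-calling max_gap")


@dataclass
class EvolutionConfig:
    """Codon divergence settings for :func:`evolve_pair`.

    ``omega`` is the target dN/dS; ``subs_per_codon`` the expected number
    of proposed single-nucleotide changes per codon (the divergence
    dial — realized substitutions are fewer when omega < 1); ``length``
    the ancestor length in codons. Genetic code: table 11, fixed.
    """

    omega: float = 0.5
    subs_per_codon: float = 0.8
    length: int = 300
    seed: int = 0
    frozen_columns: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.length < 1:
            raise ValueError("length must be >= 1")


# ---------------------------------------------------------------------------
# Genome generation


@dataclass
class GenomeSim:
    """A generated genome: annotation table (+ contig sequence), the
    chaperone loci by family, and the placement actually realized."""

    table: AnnotationTable
    chaperone_loci: dict[str, list[str]]
    placements: dict[str, str]  # locus_tag -> cis | trans
    phylum: str


def _gene_length(rng: np.random.Generator, template: GenomeTemplate) -> int:
    lo, hi = template.gene_length_range
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    return 3 * n_codons


def generate_genome(
    template: GenomeTemplate, seed: int, genome_id: str = "synth"
) -> GenomeSim:
    """Generate one annotated genome (single contig) from a template.

    Deterministic for a fixed seed. Operon genes are contiguous on one
    strand with intra-operon gaps from ``gap_range``; filler genes with
    neutral products separate blocks with spacer gaps large enough that
    operon calls never merge blocks. Trans-placed chaperones land among
    distant fillers; transposase products are inserted next to a
    chaperone's operon with the layout's configured probability.
    """
    rng = np.random.default_rng(seed)
    # plan: list of blocks; each block = (list of (symbol, is_chaperone), strand)
    blocks: list[tuple[list[tuple[str, bool]], str]] = []
    trans_queue: list[str] = []
    chap_block_idx: dict[int, str] = {}

    def filler_block() -> tuple[list[tuple[str, bool]], str]:
        n = int(rng.integers(template.filler_between[0], template.filler_between[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        return ([("filler", False)] * n, strand)

    blocks.append(filler_block())
    for layout in template.layouts:
        # pick a gene-order variant
        u = rng.random()
        acc = 0.0
        variant = layout.variants[-1]
        for v in layout.variants:
            acc += v.prob
            if u < acc:
                variant = v
                break
        genes = [
            g.symbol
            for g in variant.genes
            if g.prob >= 1.0 or g.symbol == layout.chaperone or rng.random() < g.prob
        ]
        placement = layout.placement
        if layout.chaperone is not None and layout.cis_prob is not None:
            placement = "cis" if rng.random() < layout.cis_prob else "trans"
        if layout.chaperone is not None and placement != "cis":
            genes = [g for g in genes if g != layout.chaperone]
            if placement == "trans":
                trans_queue.append(layout.chaperone)
        elif layout.chaperone is not None and placement == "cis":
            if rng.random() >= layout.flank_prob and len(genes) > 1:
                # move the chaperone to a random other slot
                i = genes.index(layout.chaperone)
                genes.pop(i)
                j = int(rng.integers(0, len(genes) + 1))
                while j == i:
                    j = int(rng.integers(0, len(genes) + 1))
                genes.insert(j, layout.chaperone)
        block = [(g, g == layout.chaperone) for g in genes]
        if block:
            blocks.append((block, layout.strand))
            if layout.chaperone is not None and rng.random() < layout.transposase_prob:
                blocks.append(([("tnp", False)], "+" if rng.random() < 0.5 else "-"))
        blocks.append(filler_block())
    for chap in trans_queue:
        blocks.append(([(chap, True)], "+" if rng.random() < 0.5 else "-"))
        blocks.append(filler_block())

    # lay the blocks down on one contig
    contig = f"{genome_id}_c1"
    records: list[GeneRecord] = []
    chaperone_loci: dict[str, list[str]] = {}
    placements: dict[str, str] = {}
    pos = int(rng.integers(100, 400))
    idx = 0
    seq_parts: list[str] = []
    last_end = 0

    def random_seq(n: int) -> str:
        return "".join(np.array(list(_NUCS))[rng.integers(0, 4, size=n)])

    for bi, (block, strand) in enumerate(blocks):
        for gi, (symbol, is_chap) in enumerate(block):
            if gi > 0:
                gap = int(rng.integers(template.gap_range[0], template.gap_range[1] + 1))
                pos = records[-1].end + 1 + gap
            length = _gene_length(rng, template)
            idx += 1
            tag = f"{genome_id}_{idx:05d}"
            rec = GeneRecord(
                genome_id=genome_id,
                contig_id=contig,
                locus_tag=tag,
                gene_name=symbol.lower() if symbol not in ("filler", "tnp") else "",
                product=PRODUCTS.get(symbol, PRODUCTS["filler"]),
                start=pos,
                end=pos + length - 1,
                strand=strand,
            )
            records.append(rec)
            if is_chap:
                chaperone_loci.setdefault(symbol, []).append(tag)
                # a chaperone alone in its block was placed trans
                placements[tag] = "cis" if len(block) > 1 else "trans"
            seq_parts.append(random_seq(rec.start - 1 - last_end))
            seq_parts.append(random_seq(length))
            last_end = rec.end
        gap = int(rng.integers(template.spacer_gap_range[0], template.spacer_gap_range[1] + 1))
        pos = records[-1].end + 1 + gap
    seq_parts.append(random_seq(200))
    sequence = "".join(seq_parts)
    table = AnnotationTable(genome_id, records, {contig: sequence})
    return GenomeSim(
        table=table,
        chaperone_loci=chaperone_loci,
        placements=placements,
        phylum=template.phylum,
    )


# ---------------------------------------------------------------------------
# Codon evolution simulator


def random_cds(length: int, rng: np.random.Generator) -> list[str]:
    """A random stop-free CDS of ``length`` codons starting with ATG."""
    codons = ["ATG"]
    pool = [c for c in SENSE_CODONS if c != "ATG"]
    picks = rng.integers(0, len(pool), size=length - 1)
    codons.extend(pool[i] for i in picks)
    return codons


def evolve_pair(
    ancestor: Sequence[str],
    cfg: EvolutionConfig,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Evolve a descendant from an ancestor codon sequence.

    Single-nucleotide changes are proposed uniformly at the configured
    expected rate; proposals creating stop codons are rejected.
    Synonymous proposals are accepted with probability 1 (scaled by
    1/omega when omega > 1); non-synonymous proposals with probability
    min(omega, 1) — so the realized dN/dS tracks omega. Codons listed in
    ``cfg.frozen_columns`` never change (planted conserved positions).
    The descendant is always stop-free.
    """
    if any(GENETIC_CODE.get(c, "*") == "*" for c in ancestor):
        raise ValueError("ancestor contains a stop or ambiguous codon")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    desc = list(ancestor)
    n = len(desc)
    p_syn = 1.0 if cfg.omega <= 1.0 else 1.0 / cfg.omega
    p_non = min(cfg.omega, 1.0)
    n_events = int(rng.poisson(cfg.subs_per_codon * n))
    for _ in range(n_events):
        ci = int(rng.integers(0, n))
        if ci in cfg.frozen_columns:
            continue
        codon = desc[ci]
        pos = int(rng.integers(0, 3))
        alternatives = [nt for nt in _NUCS if nt != codon[pos]]
        nt = alternatives[int(rng.integers(0, 3))]
        mut = codon[:pos] + nt + codon[pos + 1 :]
        if GENETIC_CODE[mut] == "*":
            continue  # stop proposals rejected
        syn = GENETIC_CODE[mut] == GENETIC_CODE[codon]
        if rng.random() < (p_syn if syn else p_non):
            desc[ci] = mut
    return desc


# ---------------------------------------------------------------------------
# Whole datasets


@dataclass
class Dataset:
    """Synthetic genomes plus the matching alignment-level inputs."""

    genomes: list[GenomeSim]
    protein_msa: dict[str, str]
    cds: dict[str, str]
    groups: dict[str, tuple[str, str]]  # id -> (family, phylum)
    ancestors: dict[str, list[str]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome TSV+GFF3(+fna), MSA, CDS and group map to disk."""
        outdir = Path(outdir)
        gdir = outdir / "genomes"
        gdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        annot_paths = []
        for sim in self.genomes:
            gid = sim.table.genome_id
            tsv = gdir / f"{gid}.tsv"
            df = sim.table.to_frame().drop(columns=["rank"])
            df.to_csv(tsv, sep="\t", index=False)
            write_gff3(sim.table, gdir / f"{gid}.gff3")
            annot_paths.append(tsv)
        paths["genome_tables"] = gdir
        msa_path = outdir / "msa.faa"
        _write_fasta(msa_path, self.protein_msa)
        paths["msa"] = msa_path
        cds_path = outdir / "cds.fna"
        _write_fasta(cds_path, self.cds)
        paths["cds"] = cds_path
        groups_path = outdir / "groups.tsv"
        with open(groups_path, "w") as fh:
            fh.write("id\tfamily\tphylum\n")
            for sid, (fam, phy) in self.groups.items():
                fh.write(f"{sid}\t{fam}\t{phy}\n")
        paths["groups"] = groups_path
        return paths


def _write_fasta(path: Path, seqs: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(table: AnnotationTable, path: str | Path) -> None:
    """Minimal GFF3 emission: CDS features with locus_tag/gene/product."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in table.records:
            attrs = f"ID={r.locus_tag};locus_tag={r.locus_tag}"
            if r.gene_name:
                attrs += f";gene={r.gene_name}"
            if r.product:
                attrs += f";product={r.product}"
            fh.write(
                "\t".join(
                    [
                        r.contig_id,
                        "rempscan_sim",
                        "CDS",
                        str(r.start),
                        str(r.end),
                        ".",
                        r.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


#: Family dN/dS targets used as generator defaults, matching the
#: purifying-selection regimes reported for these chaperone families.
DEFAULT_FAMILY_OMEGA: dict[str, float] = {
    "narJ": 0.65,
    "narW": 0.65,
    "dmsD": 0.57,
    "torD": 0.65,
    "ycdY": 0.24,
}


def default_template_library() -> list[GenomeTemplate]:
    """Templates mirroring the architectures and frequencies observed
    around NarJ-subfamily loci.

    narGHJI carries narK/narU (independent inclusion p = 0.35 each, i.e.
    at least one ~58 % of the time) and ppiC (52 %); narJ is cis 91.7 %
    of the time, flanked narH–narJ–narI at 98 %. dmsD is cis 80 %, after
    dmsC in Gram-negative templates (65 %) and before dmsA in
    Gram-positives (61 %) / Archaea (85 %), with transposases near dmsD
    at 21 %. torD splits between torACD (Gram-negative, cis ~50 %) and
    the nrfD–hybA–bisC operon (Gram-positive/Archaea); ycdY sits in
    ycdXY or the hflC–mdaB operon.
    """
    gram_negative = GenomeTemplate(
        phylum="Gammaproteobacteria",
        layouts=[
            OperonLayout(
                variants=[
                    OperonVariant(
                        1.0,
                        (
                            GeneSpec("narK", 0.35),
                            GeneSpec("narU", 0.35),
                            GeneSpec("narG"),
                            GeneSpec("narH"),
                            GeneSpec("narJ"),
                            GeneSpec("narI"),
                            GeneSpec("ppiC", 0.52),
                        ),
                    )
                ],
                chaperone="narJ",
                cis_prob=0.917,
                flank_prob=0.98,
            ),
            OperonLayout(
                variants=[
                    OperonVariant(
                        0.65,
                        (
                            GeneSpec("dmsA"),
                            GeneSpec("dmsB"),
                            GeneSpec("dmsC"),
                            GeneSpec("dmsD"),
                        ),
                    ),
                    OperonVariant(
                        0.35,
                        (
                            GeneSpec("dmsD"),
                            GeneSpec("dmsA"),
                            GeneSpec("dmsB"),
                            GeneSpec("dmsC"),
                        ),
                    ),
                ],
                chaperone="dmsD",
                cis_prob=0.80,
                transposase_prob=0.21,
            ),
            OperonLayout(
                variants=[
                    OperonVariant(
                        1.0,
                        (
                            GeneSpec("torR", 0.48),
                            GeneSpec("torS", 0.48),
                            GeneSpec("torT", 0.48),
                            GeneSpec("torA"),
                            GeneSpec("torC"),
                            GeneSpec("torD"),
                        ),
                    )
                ],
                chaperone="torD",
                cis_prob=0.5,
                transposase_prob=0.01,
            ),
            OperonLayout.simple(
                ["ycdX", "ycdY"], chaperone="ycdY", cis_prob=0.9
            ),
        ],
    )
    gram_positive = GenomeTemplate(
        phylum="Bacilli",
        layouts=[
            OperonLayout(
                variants=[
                    OperonVariant(
                        1.0,
                        (
                            GeneSpec("narK", 0.35),
                            GeneSpec("narG"),
                            GeneSpec("narH"),
                            GeneSpec("narJ"),
                            GeneSpec("narI"),
                        ),
                    )
                ],
                chaperone="narJ",
                cis_prob=0.917,
                flank_prob=0.98,
            ),
            OperonLayout(
                variants=[
                    OperonVariant(
                        0.61,
                        (
                            GeneSpec("dmsD"),
                            GeneSpec("dmsA"),
                            GeneSpec("dmsB"),
                            GeneSpec("dmsC", 0.7),
                        ),
                    ),
                    OperonVariant(
                        0.39,
                        (
                            GeneSpec("dmsA"),
                            GeneSpec("dmsB"),
                            GeneSpec("dmsC", 0.7),
                            GeneSpec("dmsD"),
                        ),
                    ),
                ],
                chaperone="dmsD",
                cis_prob=0.80,
                transposase_prob=0.21,
            ),
            OperonLayout.simple(
                ["nrfD", "hybA", "bisC", "torD"], chaperone="torD", cis_prob=0.9
            ),
        ],
    )
    archaea = GenomeTemplate(
        phylum="Euryarchaea",
        layouts=[
            OperonLayout.simple(
                ["narG", "narH", "narJ", "narI"],
                chaperone="narJ",
                cis_prob=0.917,
                flank_prob=0.98,
            ),
            OperonLayout(
                variants=[
                    OperonVariant(
                        0.85,
                        (
                            GeneSpec("dmsD"),
                            GeneSpec("dmsA"),
                            GeneSpec("dmsB"),
                            GeneSpec("dmsC"),
                        ),
                    ),
                    OperonVariant(
                        0.15,
                        (
                            GeneSpec("dmsA"),
                            GeneSpec("dmsB"),
                            GeneSpec("dmsC"),
                            GeneSpec("dmsD"),
                        ),
                    ),
                ],
                chaperone="dmsD",
                cis_prob=0.80,
            ),
            OperonLayout(
                variants=[
                    OperonVariant(
                        1.0,
                        (
                            GeneSpec("duf3305", 0.6),
                            GeneSpec("duf3306", 0.6),
                            GeneSpec("hybA", 0.6),
                            GeneSpec("fdhG"),
                            GeneSpec("fdhH"),
                            GeneSpec("fdhI"),
                            GeneSpec("torD"),
                        ),
                    )
                ],
                chaperone="torD",
                cis_prob=0.9,
            ),
        ],
    )
    return [gram_negative, gram_positive, archaea]


def generate_dataset(
    n_genomes: int,
    templates: Sequence[GenomeTemplate] | None = None,
    evolution: EvolutionConfig | None = None,
    seed: int = 0,
    family_omega: Mapping[str, float] | None = None,
) -> Dataset:
    """Generate genomes plus a matching protein MSA / CDS / group map.

    One ancestor CDS per chaperone family (all of ``evolution.length``
    codons, so the indel-free protein MSA has exactly that width); every
    chaperone locus in every genome receives a descendant diverged under
    the family's omega (``family_omega``, defaulting to the purifying
    regimes in :data:`DEFAULT_FAMILY_OMEGA`). Sequence ids equal the
    chaperone locus tags. Deterministic for fixed seed.
    """
    templates = list(templates) if templates is not None else default_template_library()
    evolution = evolution or EvolutionConfig()
    omegas = dict(DEFAULT_FAMILY_OMEGA)
    if family_omega:
        omegas.update(family_omega)
    master = np.random.default_rng(seed)
    anc_rng = np.random.default_rng(master.integers(0, 2**31 - 1))

    families = sorted(
        {l.chaperone for t in templates for l in t.layouts if l.chaperone is not None}
    )
    ancestors = {fam: random_cds(evolution.length, anc_rng) for fam in families}

    genomes: list[GenomeSim] = []
    protein_msa: dict[str, str] = {}
    cds: dict[str, str] = {}
    groups: dict[str, tuple[str, str]] = {}
    for i in range(n_genomes):
        template = templates[i % len(templates)]
        gseed = int(master.integers(0, 2**31 - 1))
        sim = generate_genome(template, gseed, genome_id=f"g{i:03d}")
        genomes.append(sim)
        evo_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        for fam, loci in sim.chaperone_loci.items():
            for tag in loci:
                cfg = replace(evolution, omega=omegas.get(fam, evolution.omega))
                desc = evolve_pair(ancestors[fam], cfg, rng=evo_rng)
                cds[tag] = "".join(desc)
                protein_msa[tag] = "".join(GENETIC_CODE[c] for c in desc)
                groups[tag] = (fam, sim.phylum)
    return Dataset(
        genomes=genomes,
        protein_msa=protein_msa,
        cds=cds,
        groups=groups,
        ancestors=ancestors,
    )
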
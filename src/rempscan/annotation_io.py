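"""Genome annotation, sequence and alignment I/O.

Reads per-genome gene tables (GFF3 CDS features or a simple TSV dialect),
extracts ORF-count neighborhoods around a focal locus, and segments gene
tables into operons by a same-strand / maximum-intergenic-gap rule.

Coordinates are 1-based inclusive everywhere (GFF3 convention); no
half-open representation is ever exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "GeneRecord",
    "AnnotationTable",
    "Neighborhood",
    "OperonCall",
    "AnnotationError",
    "AnnotationParseError",
    "UnknownLocusError",
    "read_annotation",
    "extract_neighborhood",
    "call_operons",
    "read_msa",
    "read_cds",
    "write_report",
    "read_report",
    "TSV_COLUMNS",
]

TSV_COLUMNS = [
    "genome_id",
    "contig_id",
    "locus_tag",
    "gene_name",
    "product",
    "start",
    "end",
    "strand",
]


class AnnotationError(ValueError):
    """Invalid annotation content (bad coordinates, duplicate tags...)."""


class AnnotationParseError(AnnotationError):
    """A file could not be parsed under the requested dialect."""


class UnknownLocusError(KeyError):
    """A locus tag was requested that is not in the table."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene (CDS) on a contig, 1-based inclusive coordinates."""

    genome_id: str
    contig_id: str
    locus_tag: str
    gene_name: str  # lower-case gene symbol, may be empty
    product: str
    start: int
    end: int
    strand: str  # "+" or "-"
    rank: int = -1  # 0-based index in coordinate order on its contig

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(
                f"{self.locus_tag}: start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise AnnotationError(
                f"{self.locus_tag}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationTable:
    """Ordered gene records of one genome, optionally with contig sequences.

    Records are canonically sorted by (contig_id, start) and carry
    consecutive per-contig ranks, regardless of input order.
    """

    genome_id: str
    records: list[GeneRecord]
    sequences: dict[str, str] | None = None
    _by_locus: dict[str, GeneRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.records = _canonicalize(self.records)
        self._by_locus = {}
        for rec in self.records:
            if rec.locus_tag in self._by_locus:
                raise AnnotationError(
                    f"duplicate locus_tag {rec.locus_tag!r} in genome "
                    f"{self.genome_id!r}"
                )
            self._by_locus[rec.locus_tag] = rec
        if self.sequences is not None:
            missing = {r.contig_id for r in self.records} - set(self.sequences)
            if missing:
                raise AnnotationError(
                    f"contigs without sequence: {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_locus

    def get(self, locus_tag: str) -> GeneRecord:
        try:
            return self._by_locus[locus_tag]
        except KeyError:
            raise UnknownLocusError(
                f"locus_tag {locus_tag!r} not in genome {self.genome_id!r}"
            ) from None

    def contig_records(self, contig_id: str) -> list[GeneRecord]:
        return [r for r in self.records if r.contig_id == contig_id]

    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.contig_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome_id": r.genome_id,
                    "contig_id": r.contig_id,
                    "locus_tag": r.locus_tag,
                    "gene_name": r.gene_name,
                    "product": r.product,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "rank": r.rank,
                }
                for r in self.records
            ]
        )


def _canonicalize(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Sort by (contig, start) and assign consecutive per-contig ranks."""
    out: list[GeneRecord] = []
    ordered = sorted(records, key=lambda r: (r.contig_id, r.start, r.end))
    counters: dict[str, int] = {}
    for rec in ordered:
        rank = counters.get(rec.contig_id, 0)
        counters[rec.contig_id] = rank + 1
        if rec.rank != rank:
            rec = GeneRecord(
                rec.genome_id,
                rec.contig_id,
                rec.locus_tag,
                rec.gene_name,
                rec.product,
                rec.start,
                rec.end,
                rec.strand,
                rank,
            )
        out.append(rec)
    return out


@dataclass(frozen=True)
class Neighborhood:
    """The +/- ``radius`` ORF window around a focal gene on its contig.

    ``upstream`` and ``downstream`` are ordered by increasing rank
    distance from the focal gene; each side is shorter than ``radius``
    only at a contig boundary.
    """

    focal: GeneRecord
    upstream: tuple[GeneRecord, ...]
    downstream: tuple[GeneRecord, ...]
    radius: int

    @property
    def neighbors(self) -> tuple[GeneRecord, ...]:
        return self.upstream + self.downstream


@dataclass(frozen=True)
class OperonCall:
    """A maximal same-strand, small-gap run of genes on one contig."""

    contig_id: str
    strand: str
    member_locus_tags: tuple[str, ...]
    span: tuple[int, int]

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self.member_locus_tags

    def __len__(self) -> int:
        return len(self.member_locus_tags)


# ---------------------------------------------------------------------------
# Readers


def read_annotation(
    path: str | Path,
    dialect: str = "gff3",
    genome_id: str | None = None,
    with_sequences: bool = False,
) -> AnnotationTable:
    """Read a gene table into a canonical :class:`AnnotationTable`.

    ``dialect="gff3"`` reads CDS features (attributes ``locus_tag``,
    ``gene``, ``product``); ``dialect="tsv"`` reads the documented
    tab-separated dialect with columns ``genome_id, contig_id, locus_tag,
    gene_name, product, start, end, strand``. Gene names are lower-cased;
    products preserved verbatim. ``with_sequences`` additionally loads a
    sibling ``.fna`` FASTA (GFF3 dialect only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gff3":
        table = _read_gff3(path, genome_id)
        if with_sequences:
            fna = path.with_suffix(".fna")
            if not fna.exists():
                raise FileNotFoundError(fna)
            seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fna), "fasta")}
            table = AnnotationTable(table.genome_id, table.records, seqs)
        return table
    if dialect == "tsv":
        return _read_tsv(path, genome_id)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'gff3' or 'tsv')")


def _read_gff3(path: Path, genome_id: str | None) -> AnnotationTable:
    import gffutils

    # cheap structural pre-check so malformed lines are reported by number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated GFF3 "
                    f"columns, found {len(fields)}"
                )
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises various types
        raise AnnotationParseError(f"{path}: not valid GFF3: {exc}") from exc

    gid = genome_id or path.stem
    records = []
    for feat in db.features_of_type("CDS"):
        locus = _first_attr(feat, "locus_tag") or _first_attr(feat, "ID")
        if locus is None:
            raise AnnotationParseError(
                f"{path}: CDS at {feat.seqid}:{feat.start}-{feat.end} lacks "
                "both locus_tag and ID attributes"
            )
        if feat.strand not in ("+", "-"):
            raise AnnotationParseError(
                f"{path}: CDS {locus}: strand must be + or -, got {feat.strand!r}"
            )
        records.append(
            GeneRecord(
                genome_id=gid,
                contig_id=feat.seqid,
                locus_tag=locus,
                gene_name=(_first_attr(feat, "gene") or "").lower(),
                product=_first_attr(feat, "product") or "",
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return AnnotationTable(gid, records)


def _first_attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def _read_tsv(path: Path, genome_id: str | None) -> AnnotationTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise AnnotationParseError(f"{path}: not valid TSV: {exc}") from exc
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationParseError(
            f"{path}: missing TSV columns: {sorted(missing)}"
        )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                GeneRecord(
                    genome_id=row["genome_id"],
                    contig_id=row["contig_id"],
                    locus_tag=row["locus_tag"],
                    gene_name=row["gene_name"].lower(),
                    product=row["product"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                )
            )
        except (ValueError, AnnotationError) as exc:
            raise AnnotationParseError(
                f"{path}: line {i + 2}: {exc}"
            ) from exc
    gids = {r.genome_id for r in records}
    if genome_id is None:
        if len(gids) != 1:
            raise AnnotationParseError(
                f"{path}: expected a single genome_id per file, found {sorted(gids)}"
            )
        genome_id = records[0].genome_id
    return AnnotationTable(genome_id, records)


# ---------------------------------------------------------------------------
# Neighborhoods and operons


def extract_neighborhood(
    table: AnnotationTable, locus_tag: str, radius: int = 10
) -> Neighborhood:
    """Up to ``radius`` genes on each side of the focal locus, by rank.

    Inclusion ignores strand and bp distance; windows truncate at contig
    boundaries.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    focal = table.get(locus_tag)
    contig = table.contig_records(focal.contig_id)
    i = focal.rank
    upstream = tuple(contig[j] for j in range(i - 1, max(i - radius, 0) - 1, -1))
    downstream = tuple(contig[i + 1 : i + 1 + radius])
    return Neighborhood(focal=focal, upstream=upstream, downstream=downstream, radius=radius)


def call_operons(table: AnnotationTable, max_gap: int = 150) -> list[OperonCall]:
    """Segment each contig into operons.

    Maximal runs of same-strand genes whose successive intergenic gaps are
    <= ``max_gap`` bp; singletons form singleton operons. The calls
    partition the genes of every contig.
    """
    calls: list[OperonCall] = []
    for contig in table.contigs():
        run: list[GeneRecord] = []
        for rec in table.contig_records(contig):
            if run:
                prev = run[-1]
                gap = rec.start - prev.end - 1
                if rec.strand == prev.strand and gap <= max_gap:
                    run.append(rec)
                    continue
                calls.append(_close_run(run))
                run = []
            run.append(rec)
        if run:
            calls.append(_close_run(run))
    return calls


def _close_run(run: Sequence[GeneRecord]) -> OperonCall:
    return OperonCall(
        contig_id=run[0].contig_id,
        strand=run[0].strand,
        member_locus_tags=tuple(r.locus_tag for r in run),
        span=(min(r.start for r in run), max(r.end for r in run)),
    )


def operon_of(operons: Iterable[OperonCall], locus_tag: str) -> OperonCall:
    """The unique operon call containing ``locus_tag``."""
    for op in operons:
        if locus_tag in op:
            return op
    raise UnknownLocusError(f"locus_tag {locus_tag!r} not in any operon call")


# ---------------------------------------------------------------------------
# Alignments, CDS and reports


def read_msa(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered ``{id: aligned sequence}`` map."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AnnotationParseError(f"{path}: not a valid alignment: {exc}") from exc
    out = {rec.id: str(rec.seq).upper() for rec in aln}
    widths = {len(s) for s in out.values()}
    if len(widths) > 1:
        raise AnnotationParseError(f"{path}: ragged alignment widths {sorted(widths)}")
    return out


def read_cds(path: str | Path) -> dict[str, str]:
    """Read an (unaligned) nucleotide FASTA into ``{id: sequence}``."""
    out = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not out:
        raise AnnotationParseError(f"{path}: no FASTA records found")
    return out


def check_ids_match(msa: Mapping[str, str], cds: Mapping[str, str]) -> None:
    """Every MSA identifier must have a CDS sequence."""
    missing = sorted(set(msa) - set(cds))
    if missing:
        raise AnnotationError(
            f"CDS file is missing {len(missing)} MSA identifier(s): {missing}"
        )


def write_report(df: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a report losslessly as TSV or JSON (records orientation)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t", keep_default_na=False)
    if format == "json":
        return pd.DataFrame(json.loads(Path(path).read_text()))
    raise ValueError(f"unknown report format {format!r}")
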
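"""Codon-level synonymous / non-synonymous substitution analysis.

Threads coding sequences onto a protein multiple sequence alignment
(back-translation without an aligner), then computes pairwise dN/dS by
Nei–Gojobori counting: per-codon synonymous site fractions, pathway-
averaged substitution counts (Sd, Nd), proportions pS = Sd/S and
pN = Nd/N, Jukes–Cantor multiple-hit correction
d = -(3/4) ln(1 - (4/3) p), and the ratio dN/dS. Pairs whose pS (or pN)
reaches the Jukes–Cantor cutoff of 0.75 cannot be corrected and are
flagged invalid rather than dropped silently.

Site counting excludes mutations to stop codons and renormalizes so that
S + N = 3 per codon exactly; pathway averaging over the orderings of the
differing positions likewise excludes pathways passing through a stop,
re-weighting the remainder equally. The genetic code is NCBI translation
table 11 (bacteria/archaea), fixed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CodonAlignment",
    "PairwiseDnDs",
    "GroupSummary",
    "SdProfile",
    "ThreadingError",
    "thread_codons",
    "codon_sites",
    "codon_differences",
    "jc_correct",
    "pairwise_dnds",
    "all_pairwise",
    "group_summary",
    "sd_profile",
]

_TABLE = CodonTable.unambiguous_dna_by_id[11]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*")
)
START_CODONS: frozenset[str] = frozenset(_TABLE.start_codons)
GAP_CODON = "---"
_NUCS = "ACGT"


class ThreadingError(ValueError):
    """CDS could not be threaded onto the protein alignment."""


# ---------------------------------------------------------------------------
# Codon alignment


@dataclass
class CodonAlignment:
    """Codon columns threaded under a protein MSA.

    ``codons[id]`` is a list of W cells, each a sense codon or ``"---"``;
    every non-gap cell translates (table 11) to the residue at the same
    protein MSA column. ``column_to_protein_col`` maps alignment columns
    to protein MSA columns (identity unless columns were trimmed).
    """

    ids: list[str]
    codons: dict[str, list[str]]
    column_to_protein_col: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        widths = {len(v) for v in self.codons.values()}
        if len(widths) > 1:
            raise ValueError(f"ragged codon alignment: widths {sorted(widths)}")
        if not self.column_to_protein_col and self.codons:
            self.column_to_protein_col = list(range(self.width))

    @property
    def width(self) -> int:
        return len(next(iter(self.codons.values()))) if self.codons else 0

    def __len__(self) -> int:
        return len(self.ids)


def thread_codons(
    protein_msa: Mapping[str, str],
    cds_map: Mapping[str, str],
    allow_alternative_start: bool = True,
) -> CodonAlignment:
    """Back-translate a protein MSA into a codon alignment.

    Each CDS must be 3x its ungapped protein length (a single terminal
    stop codon is trimmed if present) and translate to the ungapped
    protein under table 11. Gap residues become gap codons. With
    ``allow_alternative_start`` a first-position mismatch is tolerated
    when the protein starts with M and the codon is a table-11 start
    codon (GTG/TTG starts are annotated as Met).
    """
    missing = sorted(set(protein_msa) - set(cds_map))
    if missing:
        raise ThreadingError(f"CDS missing for MSA id(s): {missing}")

    codons: dict[str, list[str]] = {}
    for sid, aligned in protein_msa.items():
        cds = cds_map[sid].upper().replace("U", "T")
        ungapped = aligned.replace("-", "")
        if len(cds) == 3 * (len(ungapped) + 1) and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]  # trim terminal stop
        if len(cds) != 3 * len(ungapped):
            raise ThreadingError(
                f"{sid}: CDS length {len(cds)} is not 3 x {len(ungapped)} "
                f"ungapped residues (offset {len(cds) - 3 * len(ungapped)})"
            )
        triplets = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for i, (cod, aa) in enumerate(zip(triplets, ungapped)):
            trans = GENETIC_CODE.get(cod)
            if trans == "*":
                raise ThreadingError(f"{sid}: internal stop codon {cod} at codon {i}")
            ok = trans == aa or (
                i == 0
                and allow_alternative_start
                and aa == "M"
                and cod in START_CODONS
            )
            if not ok:
                raise ThreadingError(
                    f"{sid}: translation mismatch at residue {i}: codon {cod} "
                    f"-> {trans}, protein has {aa}"
                )
        it = iter(triplets)
        codons[sid] = [GAP_CODON if aa == "-" else next(it) for aa in aligned]
    return CodonAlignment(ids=list(protein_msa), codons=codons)


# ---------------------------------------------------------------------------
# Nei–Gojobori counting


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float] | None:
    """Synonymous / non-synonymous site counts (S, N) for one sense codon.

    Per position the synonymous fraction is computed over the *non-stop*
    single-nucleotide mutants, so S + N = 3 exactly. Returns None for
    stop or ambiguous codons (callers skip, never crash).
    """
    aa = GENETIC_CODE.get(codon)
    if aa is None or aa == "*":
        return None
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            maa = GENETIC_CODE[mut]
            if maa == "*":
                continue
            nonstop += 1
            if maa == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return (s, 3.0 - s)


@dataclass(frozen=True)
class CodonDiff:
    sd: float
    nd: float
    fallback: bool = False  # all pathways blocked by stops; per-position count used

    def __iter__(self):
        return iter((self.sd, self.nd))


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> CodonDiff:
    """Pathway-averaged synonymous / non-synonymous differences (Sd, Nd).

    Averages over every ordering of the k <= 3 differing positions;
    orderings whose intermediate codons are stops are excluded and the
    rest re-weighted equally, so Sd + Nd = k. If every pathway is
    blocked, each differing position is counted independently in both
    codon contexts (flagged via ``fallback``).
    """
    if GENETIC_CODE.get(codon_a, "*") == "*" or GENETIC_CODE.get(codon_b, "*") == "*":
        raise ValueError(f"codon_differences needs sense codons, got {codon_a},{codon_b}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return CodonDiff(0.0, 0.0)
    sd_tot = nd_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_tot += sd
            nd_tot += nd
            n_paths += 1
    if n_paths:
        return CodonDiff(sd_tot / n_paths, nd_tot / n_paths)
    # every ordering passes through a stop: count positions independently
    sd = nd = 0.0
    for pos in diff:
        # score the position's change in each codon context, averaging the two
        score = 0.0
        n_ctx = 0
        for src, dst_nt in ((codon_a, codon_b[pos]), (codon_b, codon_a[pos])):
            mut = src[:pos] + dst_nt + src[pos + 1 :]
            if GENETIC_CODE[mut] == "*":
                continue
            n_ctx += 1
            if GENETIC_CODE[mut] == GENETIC_CODE[src]:
                score += 1.0
        syn_frac = score / n_ctx if n_ctx else 0.0
        sd += syn_frac
        nd += 1.0 - syn_frac
    return CodonDiff(sd, nd, fallback=True)


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p).

    Undefined (NaN, not an exception) for p >= 0.75, where the log
    argument reaches zero.
    """
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


# ---------------------------------------------------------------------------
# Pairwise dN/dS


@dataclass
class PairwiseDnDs:
    """All quantities of one pairwise Nei–Gojobori comparison.

    ``valid`` is False when the ratio cannot be interpreted: pS or pN at
    or above the 0.75 Jukes–Cantor cutoff, no synonymous sites, or
    dS = 0 (identical-synonymous pairs; dS = 0 with dN > 0 is reported
    with ``ratio = inf`` as the "infinite" category, excluded from
    percentile summaries).
    """

    id_a: str
    id_b: str
    sd: float
    nd: float
    s_sites: float
    n_sites: float
    p_s: float
    p_n: float
    d_s: float
    d_n: float
    ratio: float
    valid: bool
    codons_compared: int
    n_fallback: int = 0


def _comparable(cell: str) -> bool:
    return cell != GAP_CODON and all(c in _NUCS for c in cell) and GENETIC_CODE[cell] != "*"


def pairwise_dnds(aln: CodonAlignment, id_a: str, id_b: str) -> PairwiseDnDs:
    """Nei–Gojobori dN/dS for one sequence pair of a codon alignment.

    Columns where either cell is a gap, contains a non-ACGT base, or is a
    stop codon are skipped (pairwise deletion). S and N are averaged over
    the two sequences; symmetric in (id_a, id_b).
    """
    a = aln.codons[id_a]
    b = aln.codons[id_b]
    sd = nd = s_a = n_a = s_b = n_b = 0.0
    n_cod = 0
    n_fallback = 0
    for ca, cb in zip(a, b):
        if not (_comparable(ca) and _comparable(cb)):
            continue
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        diff = codon_differences(ca, cb)
        sd += diff.sd
        nd += diff.nd
        n_fallback += diff.fallback
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        n_cod += 1
    if n_cod == 0:
        raise ValueError(f"{id_a} vs {id_b}: no comparable codon columns")
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    p_s = sd / s_sites if s_sites > 0 else math.nan
    p_n = nd / n_sites if n_sites > 0 else math.nan
    d_s = jc_correct(p_s) if not math.isnan(p_s) else math.nan
    d_n = jc_correct(p_n) if not math.isnan(p_n) else math.nan
    if not math.isnan(d_s) and d_s > 0 and not math.isnan(d_n):
        ratio = d_n / d_s
    elif d_s == 0 and d_n > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    valid = not (
        math.isnan(p_s)
        or p_s >= 0.75
        or (not math.isnan(p_n) and p_n >= 0.75)
        or s_sites == 0
        or d_s == 0
        or math.isnan(d_s)
    )
    return PairwiseDnDs(
        id_a=id_a,
        id_b=id_b,
        sd=sd,
        nd=nd,
        s_sites=s_sites,
        n_sites=n_sites,
        p_s=p_s,
        p_n=p_n,
        d_s=d_s,
        d_n=d_n,
        ratio=ratio,
        valid=valid,
        codons_compared=n_cod,
        n_fallback=n_fallback,
    )


def all_pairwise(
    aln: CodonAlignment, ids: Sequence[str] | None = None
) -> list[PairwiseDnDs]:
    """All unordered pairwise comparisons among ``ids`` (default: all)."""
    ids = list(ids) if ids is not None else list(aln.ids)
    return [
        pairwise_dnds(aln, a, b) for a, b in itertools.combinations(ids, 2)
    ]


def pairs_to_frame(pairs: Iterable[PairwiseDnDs]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs])


# ---------------------------------------------------------------------------
# Group summaries and per-codon Sd profiles


@dataclass
class GroupSummary:
    group: tuple[str, str]  # (family, phylum)
    values: list[float]
    minimum: float
    p25: float
    median: float
    p75: float
    maximum: float
    n_pairs: int
    n_invalid: int


def group_summary(
    pairs: Iterable[PairwiseDnDs],
    grouping: Mapping[str, tuple[str, str]] | Callable[[str], tuple[str, str]],
) -> list[GroupSummary]:
    """Five-point percentile summaries of valid dN/dS values per group.

    ``grouping`` assigns each sequence id a (family, phylum); only
    intra-group pairs contribute. Percentiles use linear interpolation
    between order statistics. Invalid pairs (Jukes–Cantor cutoff, dS = 0)
    are tallied separately; groups with no valid pair are omitted.
    """
    lookup = grouping if callable(grouping) else grouping.__getitem__
    buckets: dict[tuple[str, str], list[float]] = {}
    invalid: dict[tuple[str, str], int] = {}
    for p in pairs:
        ga, gb = lookup(p.id_a), lookup(p.id_b)
        if ga != gb:
            continue
        if p.valid and math.isfinite(p.ratio):
            buckets.setdefault(ga, []).append(p.ratio)
        else:
            invalid[ga] = invalid.get(ga, 0) + 1
            buckets.setdefault(ga, [])
    out = []
    for grp, vals in buckets.items():
        if not vals:
            continue
        q = np.percentile(vals, [0, 25, 50, 75, 100], method="linear")
        out.append(
            GroupSummary(
                group=grp,
                values=vals,
                minimum=float(q[0]),
                p25=float(q[1]),
                median=float(q[2]),
                p75=float(q[3]),
                maximum=float(q[4]),
                n_pairs=len(vals),
                n_invalid=invalid.get(grp, 0),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": s.group[0],
                "phylum": s.group[1],
                "min": s.minimum,
                "p25": s.p25,
                "median": s.median,
                "p75": s.p75,
                "max": s.maximum,
                "n_pairs": s.n_pairs,
                "n_invalid": s.n_invalid,
            }
            for s in summaries
        ]
    )


@dataclass
class SdProfile:
    """Per aligned codon column: mean (or summed) pathway-averaged Sd over
    contributing pairs, and the number of contributing pairs."""

    values: np.ndarray
    n_pairs: np.ndarray
    mode: str = "mean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(len(self.values)),
                f"sd_{self.mode}": self.values,
                "n_pairs": self.n_pairs,
            }
        )


def sd_profile(
    aln: CodonAlignment, ids: Sequence[str] | None = None, mode: str = "mean"
) -> SdProfile:
    """Observed synonymous substitutions (Sd) at each aligned codon column.

    For every intra-group pair with comparable codons in a column the
    pathway-averaged Sd contributes; ``mode="mean"`` divides by the pair
    count (``"sum"`` reports totals). Column means, weighted by pair
    counts, reconcile with the mean total Sd over pairs.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    ids = list(ids) if ids is not None else list(aln.ids)
    if len(ids) < 2:
        raise ValueError("sd_profile needs >= 2 sequences")
    w = aln.width
    totals = np.zeros(w)
    counts = np.zeros(w, dtype=int)
    for a, b in itertools.combinations(ids, 2):
        ca_row, cb_row = aln.codons[a], aln.codons[b]
        for col in range(w):
            ca, cb = ca_row[col], cb_row[col]
            if not (_comparable(ca) and _comparable(cb)):
                continue
            totals[col] += codon_differences(ca, cb).sd
            counts[col] += 1
    if mode == "mean":
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, totals / np.maximum(counts, 1), 0.0)
    else:
        values = totals
    return SdProfile(values=values, n_pairs=counts, mode=mode)
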
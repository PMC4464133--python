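"""Per-column identity profiles and tiered consensus motifs.

A motif is the set of alignment columns whose modal residue reaches an
identity threshold, rendered in two tiers — "normal" for identity in
[t1, t2) (default [0.60, 0.75)) and "bold" for identity >= t2 — and
numbered against a chosen reference sequence (columns where the
reference is gapped get insertion suffixes, e.g. 84a).

By default gaps count in the identity denominator, so a mostly-gapped
column can never become a motif position; ``count_gaps=False`` switches
to the ungapped-denominator convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "IdentityProfile",
    "Motif",
    "MotifEntry",
    "identity_profile",
    "extract_motif",
    "compare_motifs",
    "render_motif",
]

GAP = "-"


@dataclass
class IdentityProfile:
    """Per-column modal residue, identity fraction, gap and sequence counts."""

    modal: list[str]
    identity: list[float]
    n_gap: list[int]
    n_seq: int

    def __len__(self) -> int:
        return len(self.modal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": range(len(self.modal)),
                "modal_residue": self.modal,
                "identity": self.identity,
                "n_gap": self.n_gap,
                "n_seq": self.n_seq,
            }
        )


@dataclass(frozen=True)
class MotifEntry:
    position: int  # reference numbering (count of reference residues)
    insertion: str  # '' or 'a','b',... for reference-gap columns
    residue: str
    tier: str  # normal | bold
    column: int  # alignment column (0-based)

    @property
    def label(self) -> str:
        return f"{self.position}{self.insertion}"


@dataclass
class Motif:
    reference_id: str
    entries: list[MotifEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def by_label(self) -> dict[str, MotifEntry]:
        return {e.label: e for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": e.label,
                    "residue": e.residue,
                    "tier": e.tier,
                    "column": e.column,
                }
                for e in self.entries
            ]
        )


def identity_profile(
    msa: Mapping[str, str],
    subgroup: Sequence[str] | None = None,
    count_gaps: bool = True,
) -> IdentityProfile:
    """Column-wise consensus over a subgroup of an alignment.

    Modal residue over non-gap residues (ties broken alphabetically);
    identity = modal count / subgroup size when ``count_gaps`` (default),
    else modal count / non-gap count. All-gap columns get identity 0 and
    modal residue '-'.
    """
    ids = list(subgroup) if subgroup is not None else list(msa)
    if not ids:
        raise ValueError("empty subgroup")
    missing = [i for i in ids if i not in msa]
    if missing:
        raise KeyError(f"subgroup ids not in alignment: {missing}")
    rows = [msa[i] for i in ids]
    width = len(rows[0])
    n = len(rows)
    modal: list[str] = []
    identity: list[float] = []
    n_gap: list[int] = []
    for col in range(width):
        residues = [r[col] for r in rows]
        gaps = sum(1 for c in residues if c == GAP)
        counts = Counter(c for c in residues if c != GAP)
        if not counts:
            modal.append(GAP)
            identity.append(0.0)
            n_gap.append(gaps)
            continue
        top = max(counts.values())
        # tie-break alphabetically among equally common residues
        residue = min(r for r, c in counts.items() if c == top)
        denom = n if count_gaps else (n - gaps)
        modal.append(residue)
        identity.append(top / denom if denom else 0.0)
        n_gap.append(gaps)
    return IdentityProfile(modal=modal, identity=identity, n_gap=n_gap, n_seq=n)


def extract_motif(
    profile: IdentityProfile,
    msa: Mapping[str, str],
    reference_id: str,
    t1: float = 0.60,
    t2: float = 0.75,
) -> Motif:
    """Tiered consensus motif numbered against ``reference_id``.

    Columns with identity >= t1 are emitted; tier "bold" for identity
    >= t2, "normal" for [t1, t2). Position numbers count non-gap
    reference residues up to the column; reference-gap columns take the
    preceding residue number with insertion suffixes a, b, c...
    """
    if reference_id not in msa:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    if not (0 <= t1 <= t2 <= 1):
        raise ValueError("thresholds must satisfy 0 <= t1 <= t2 <= 1")
    ref = msa[reference_id]
    if len(ref) != len(profile):
        raise ValueError("profile width does not match alignment width")
    entries: list[MotifEntry] = []
    ref_pos = 0
    ins = 0
    for col in range(len(profile)):
        if ref[col] != GAP:
            ref_pos += 1
            ins = 0
            position, suffix = ref_pos, ""
        else:
            ins += 1
            position, suffix = ref_pos, _insertion_suffix(ins)
        ident = profile.identity[col]
        if ident >= t2:
            tier = "bold"
        elif ident >= t1:
            tier = "normal"
        else:
            continue
        entries.append(
            MotifEntry(
                position=position,
                insertion=suffix,
                residue=profile.modal[col],
                tier=tier,
                column=col,
            )
        )
    return Motif(reference_id=reference_id, entries=entries)


def _insertion_suffix(i: int) -> str:
    # 1 -> a, 26 -> z, 27 -> aa ...
    out = ""
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def compare_motifs(a: Motif, b: Motif) -> list[dict]:
    """Symmetric difference of two motifs sharing a numbering scheme.

    Returns entries ``{"kind": "substitution", "position", "residue_a",
    "residue_b"}`` for shared positions with different residues (the
    Fig.-style K37G/N notation is ``residue_a + position + residue_b``)
    and ``{"kind": "only_in_a"|"only_in_b", ...}`` for positions present
    in just one motif.
    """
    if a.reference_id != b.reference_id:
        raise ValueError(
            f"motifs use different references: {a.reference_id!r} vs {b.reference_id!r}"
        )
    map_a, map_b = a.by_label(), b.by_label()
    diffs: list[dict] = []
    for label in sorted(set(map_a) | set(map_b), key=_label_key):
        ea, eb = map_a.get(label), map_b.get(label)
        if ea is not None and eb is not None:
            if ea.residue != eb.residue:
                diffs.append(
                    {
                        "kind": "substitution",
                        "position": label,
                        "residue_a": ea.residue,
                        "residue_b": eb.residue,
                        "notation": f"{ea.residue}{label}{eb.residue}",
                    }
                )
        elif ea is not None:
            diffs.append({"kind": "only_in_a", "position": label, "residue_a": ea.residue})
        else:
            diffs.append({"kind": "only_in_b", "position": label, "residue_b": eb.residue})
    return diffs


def _label_key(label: str) -> tuple[int, str]:
    digits = "".join(c for c in label if c.isdigit())
    return (int(digits or 0), label[len(digits) :])


def render_motif(motif: Motif, width: int | None = None) -> str:
    """Text rendering: bold-tier residues uppercase with a trailing '*',
    normal-tier plain uppercase; gaps between non-adjacent columns as '-'."""
    parts: list[str] = []
    prev_col: int | None = None
    for e in motif.entries:
        if prev_col is not None and e.column > prev_col + 1:
            parts.append("-")
        parts.append(e.residue + ("*" if e.tier == "bold" else ""))
        prev_col = e.column
    return "".join(parts)
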
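"""Nei–Gojobori counting, Jukes–Cantor correction, codon threading,
pairwise dN/dS and per-codon Sd profiles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rempscan.codon_evolution import (
    CodonAlignment,
    SENSE_CODONS,
    ThreadingError,
    all_pairwise,
    codon_differences,
    codon_sites,
    group_summary,
    jc_correct,
    pairwise_dnds,
    sd_profile,
    thread_codons,
)

# ---------------------------------------------------------------------------
# site and difference counting


def test_phe_codon_site_partition():
    # TTT: only third-position TTC is synonymous; TTA/TTG change Phe->Leu
    s, n = codon_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_trp_codon_has_no_synonymous_sites():
    s, n = codon_sites("TGG")
    assert s == 0.0 and n == 3.0


def test_sites_sum_to_three_for_all_sense_codons():
    for codon in SENSE_CODONS:
        s, n = codon_sites(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        assert s >= 0


def test_stop_and_ambiguous_codons_signal_skip():
    assert codon_sites("TAA") is None
    assert codon_sites("ANT") is None


def test_single_synonymous_difference():
    d = codon_differences("TTT", "TTC")
    assert (d.sd, d.nd) == (1.0, 0.0)


def test_identity_has_no_differences():
    assert tuple(codon_differences("TTT", "TTT")) == (0.0, 0.0)


def test_differences_match_enumeration_oracle_everywhere(ng_oracle):
    for a, b in itertools.combinations_with_replacement(ng_oracle.codons(), 2):
        expected = ng_oracle.differences(a, b)
        got = codon_differences(a, b)
        if expected is None:
            assert got.fallback
        else:
            assert got.sd == pytest.approx(expected[0], abs=1e-9)
            assert got.nd == pytest.approx(expected[1], abs=1e-9)
            k = sum(x != y for x, y in zip(a, b))
            assert got.sd + got.nd == pytest.approx(k, abs=1e-9)


def test_sites_match_enumeration_oracle(ng_oracle):
    for codon in ng_oracle.codons():
        s, n = ng_oracle.sites(codon)
        got = codon_sites(codon)
        assert got[0] == pytest.approx(s, abs=1e-9)
        assert got[1] == pytest.approx(n, abs=1e-9)


# ---------------------------------------------------------------------------
# Jukes–Cantor


def test_jc_zero_and_cutoff():
    assert jc_correct(0.0) == 0.0
    assert math.isnan(jc_correct(0.75))
    assert math.isnan(jc_correct(0.9))
    assert jc_correct(0.5) == pytest.approx(-0.75 * math.log(1 / 3), abs=1e-12)


@given(st.floats(min_value=0.0, max_value=0.745))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_jc_is_increasing_and_dominates_p(p):
    d = jc_correct(p)
    assert d >= p * (1 - 1e-12)  # equality up to float rounding at tiny p
    eps = 1e-4
    if p + eps < 0.75:
        assert jc_correct(p + eps) > d


# ---------------------------------------------------------------------------
# threading


def test_thread_simple_gap():
    aln = thread_codons({"x": "M-A"}, {"x": "ATGGCT"})
    assert aln.codons["x"] == ["ATG", "---", "GCT"]


def test_thread_trims_terminal_stop():
    aln = thread_codons({"x": "MA"}, {"x": "ATGGCTTAA"})
    assert aln.codons["x"] == ["ATG", "GCT"]


def test_thread_internal_stop_rejected():
    with pytest.raises(ThreadingError, match="stop"):
        thread_codons({"x": "M*A"}, {"x": "ATGTAAGCT"})
    with pytest.raises(ThreadingError, match="stop"):
        thread_codons({"x": "MKA"}, {"x": "ATGTAAGCT"})


def test_thread_length_mismatch_names_id():
    with pytest.raises(ThreadingError, match="'?x"):
        thread_codons({"x": "MAA"}, {"x": "ATGGCT"})


def test_thread_translation_mismatch_reports_position():
    with pytest.raises(ThreadingError, match="residue 1"):
        thread_codons({"x": "MK"}, {"x": "ATGGCT"})


def test_thread_missing_cds_id_listed():
    with pytest.raises(ThreadingError, match="y"):
        thread_codons({"x": "M", "y": "M"}, {"x": "ATG"})


def test_thread_alternative_start_codon_accepted():
    aln = thread_codons({"x": "MA"}, {"x": "GTGGCT"})
    assert aln.codons["x"][0] == "GTG"


# ---------------------------------------------------------------------------
# pairwise dN/dS


def _aln(seq_a, seq_b):
    return CodonAlignment(ids=["a", "b"], codons={"a": list(seq_a), "b": list(seq_b)})


def test_identical_sequences_are_invalid_zero_over_zero():
    codons = ["ATG", "GCT", "AAA"] * 10
    p = pairwise_dnds(_aln(codons, codons), "a", "b")
    assert p.sd == 0 and p.nd == 0
    assert p.p_s == 0 and p.p_n == 0
    assert not p.valid
    assert math.isnan(p.ratio)


def test_single_synonymous_change_gives_ratio_zero():
    a = ["TTT"] * 100
    b = ["TTC"] + ["TTT"] * 99
    p = pairwise_dnds(_aln(a, b), "a", "b")
    assert p.nd == 0 and p.d_n == 0
    assert p.valid
    assert p.ratio == 0.0


def test_gap_and_ambiguous_columns_skipped():
    a = ["ATG", "---", "GCT", "ANA"]
    b = ["ATG", "AAA", "---", "AAA"]
    p = pairwise_dnds(_aln(a, b), "a", "b")
    assert p.codons_compared == 1


def test_high_divergence_hits_jc_cutoff():
    # alternate synonymous serine codon families to force huge pS
    a = ["TCT"] * 60
    b = ["AGC"] * 60  # Ser too, but 3 nt differences each
    p = pairwise_dnds(_aln(a, b), "a", "b")
    assert p.p_s >= 0.75
    assert not p.valid


def test_pairwise_symmetry(small_dataset):
    from rempscan.codon_evolution import thread_codons as tc

    aln = tc(small_dataset.protein_msa, small_dataset.cds)
    ids = aln.ids[:6]
    for x, y in itertools.combinations(ids, 2):
        p = pairwise_dnds(aln, x, y)
        q = pairwise_dnds(aln, y, x)
        for f in ("sd", "nd", "s_sites", "n_sites", "p_s", "p_n"):
            assert getattr(p, f) == pytest.approx(getattr(q, f), abs=1e-12)


def test_sd_plus_nd_equals_nucleotide_differences(small_dataset):
    aln = thread_codons(small_dataset.protein_msa, small_dataset.cds)
    a, b = aln.ids[0], aln.ids[1]
    p = pairwise_dnds(aln, a, b)
    diffs = sum(
        sum(x != y for x, y in zip(ca, cb))
        for ca, cb in zip(aln.codons[a], aln.codons[b])
        if "-" not in ca and "-" not in cb
    )
    assert p.sd + p.nd == pytest.approx(diffs, abs=1e-9)
    assert p.s_sites + p.n_sites == pytest.approx(3 * p.codons_compared, abs=1e-9)


def test_zero_comparable_codons_errors():
    with pytest.raises(ValueError, match="comparable"):
        pairwise_dnds(_aln(["---"], ["ATG"]), "a", "b")


# ---------------------------------------------------------------------------
# summaries and profiles


def test_group_summary_percentiles():
    class P:
        def __init__(self, a, b, ratio):
            self.id_a, self.id_b, self.ratio, self.valid = a, b, ratio, True

    pairs = [P("a", "b", v) for v in (0.2, 0.4, 0.6, 0.8, 1.0)]
    out = group_summary(pairs, lambda _: ("fam", "phy"))
    s = out[0]
    assert (s.minimum, s.median, s.maximum) == (0.2, 0.6, 1.0)
    assert s.p25 == pytest.approx(0.4) and s.p75 == pytest.approx(0.8)
    assert s.n_pairs == 5


def test_group_summary_single_pair_collapses():
    class P:
        id_a, id_b, ratio, valid = "a", "b", 0.3, True

    s = group_summary([P()], lambda _: ("f", "p"))[0]
    assert s.minimum == s.p25 == s.median == s.p75 == s.maximum == 0.3


def test_group_summary_excludes_cross_group_and_invalid():
    class P:
        def __init__(self, a, b, ratio, valid=True):
            self.id_a, self.id_b, self.ratio, self.valid = a, b, ratio, valid

    grouping = {"a": ("f", "x"), "b": ("f", "x"), "c": ("f", "y")}
    out = group_summary(
        [P("a", "b", 0.5), P("a", "c", 9.9), P("a", "b", 1.0, valid=False)],
        grouping,
    )
    assert len(out) == 1
    assert out[0].values == [0.5]
    assert out[0].n_invalid == 1


def test_sd_profile_invariant_column_is_zero_and_totals_reconcile():
    a = ["TTT", "GCT", "AAA"]
    b = ["TTC", "GCT", "AAG"]
    c = ["TTT", "GCT", "AAA"]
    aln = CodonAlignment(ids=["a", "b", "c"], codons={"a": a, "b": b, "c": c})
    prof = sd_profile(aln)
    assert prof.values[1] == 0.0  # invariant column
    pairs = all_pairwise(aln)
    mean_total_sd = np.mean([p.sd for p in pairs])
    weighted = float(np.sum(prof.values * prof.n_pairs)) / len(pairs)
    assert weighted == pytest.approx(mean_total_sd, abs=1e-9)


def test_sd_profile_finds_planted_synonymous_hot_column():
    rng = np.random.default_rng(0)
    base = ["ATG"] + ["GCT"] * 19
    seqs = {}
    syn_pool = ["GGT", "GGC", "GGA", "GGG"]  # Gly codons at the hot column
    for i in range(6):
        s = list(base)
        s[10] = syn_pool[rng.integers(0, 4)]
        seqs[f"s{i}"] = s
    aln = CodonAlignment(ids=list(seqs), codons=seqs)
    prof = sd_profile(aln)
    assert int(np.argmax(prof.values)) == 10
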
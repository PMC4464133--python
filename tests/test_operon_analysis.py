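"""cis/trans/absent classification, F^G statistic, positional profiles,
and phi-coefficient presence correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rempscan.annotation_io import call_operons, extract_neighborhood
from rempscan.operon_analysis import (
    CismDefinition,
    CognateSet,
    UndefinedStatisticError,
    classify_association,
    default_definitions,
    gene_frequency,
    has_mobile_element,
    positional_profile,
    presence_correlation,
)
from conftest import make_table

NARJ_DEF = CismDefinition("narJ", (CognateSet("narJ_narGHI", ("narG", "narH", "narI")),))
TORD_DEF = CismDefinition(
    "torD",
    (
        CognateSet("torD_torAC", ("torA", "torC")),
        CognateSet("torD_fdh", ("fdhG", "fdhH", "fdhI")),
    ),
)


def test_cis_classification_with_flanks():
    table = make_table([("narg", "+"), ("narh", "+"), ("narj", "+"), ("nari", "+")])
    ops = call_operons(table)
    res = classify_association(table, ops, "G1_0002", NARJ_DEF)
    assert res.mode == "cis"
    assert res.matched_set_label == "narJ_narGHI"
    assert tuple(s.lower() for s in res.flanked_by) == ("narh", "nari")


def test_trans_requires_complete_cognate_set_elsewhere():
    # torD alone in its operon; torA+torC co-operonic on another contig
    from rempscan.annotation_io import AnnotationTable, GeneRecord

    recs = [
        GeneRecord("G1", "c1", "t_d", "tord", "TMAO reductase chaperone", 100, 400, "+"),
        GeneRecord("G1", "c2", "t_a", "tora", "TMAO reductase catalytic subunit", 100, 400, "+"),
        GeneRecord("G1", "c2", "t_c", "torc", "cytochrome", 450, 700, "+"),
    ]
    table = AnnotationTable("G1", recs)
    ops = call_operons(table)
    res = classify_association(table, ops, "t_d", TORD_DEF)
    assert res.mode == "trans"
    assert res.matched_set_label == "torD_torAC"


def test_absent_when_no_cognate_genes():
    table = make_table([("tord", "+"), ("", "+"), ("", "-")])
    ops = call_operons(table)
    res = classify_association(table, ops, "G1_0000", TORD_DEF)
    assert res.mode == "absent"
    assert res.matched_set_label is None


def test_cis_accepts_incomplete_cognate_operon():
    # only narH co-operonic (narG/narI missing genome-wide) still counts cis
    table = make_table([("narh", "+"), ("narj", "+")])
    ops = call_operons(table)
    res = classify_association(table, ops, "G1_0001", NARJ_DEF)
    assert res.mode == "cis"


def test_classification_exhaustive_and_exclusive(small_dataset):
    defs = {d.family: d for d in default_definitions()}
    modes = set()
    for sim in small_dataset.genomes:
        ops = call_operons(sim.table)
        for fam, loci in sim.chaperone_loci.items():
            for tag in loci:
                res = classify_association(sim.table, ops, tag, defs[fam])
                assert res.mode in ("cis", "trans", "absent")
                assert (res.mode == "absent") == (res.matched_set_label is None)
                modes.add(res.mode)
    assert "cis" in modes  # templates place most chaperones cis


def test_gene_frequency_direct_substitution():
    # 3 narJ loci; narK within radius of 2 of them; O = 3
    tables = [
        make_table([("nark", "+"), ("narj", "+")], genome_id=f"g{i}")
        for i in range(2)
    ] + [make_table([("", "+"), ("narj", "+")], genome_id="g2")]
    nbs = [extract_neighborhood(t, f"{t.genome_id}_0001", radius=10) for t in tables]
    df = gene_frequency("narJ", nbs, 3, ["narK"])
    row = df.iloc[0]
    assert row["n_gene"] == 2 and row["n_locus"] == 3
    assert row["raw_fraction"] == pytest.approx(2 / 3)
    assert row["f_g"] == pytest.approx(2 / 9)


def test_gene_frequency_extremes_and_duplicates():
    table = make_table([("nark", "+"), ("narj", "+"), ("nark", "-")])
    nb = extract_neighborhood(table, "G1_0001")
    df = gene_frequency("narJ", [nb], 1, ["narK", "narU"])
    by = df.set_index("gene_symbol")
    # narK occurs twice in one neighborhood but counts once
    assert by.loc["narK", "n_gene"] == 1
    assert by.loc["narK", "raw_fraction"] == 1.0 and by.loc["narK", "f_g"] == 1.0
    assert by.loc["narU", "n_gene"] == 0 and by.loc["narU", "f_g"] == 0.0


def test_gene_frequency_zero_operons_error():
    table = make_table([("narj", "+")])
    nb = extract_neighborhood(table, "G1_0000")
    with pytest.raises(UndefinedStatisticError):
        gene_frequency("narJ", [nb], 0, ["narK"])


def test_gene_frequency_invariant_to_neighborhood_order():
    tables = [
        make_table([("nark", "+"), ("narj", "+")], genome_id=f"g{i}") for i in range(4)
    ]
    nbs = [extract_neighborhood(t, f"{t.genome_id}_0001") for t in tables]
    a = gene_frequency("narJ", nbs, 2, ["narK"])
    b = gene_frequency("narJ", nbs[::-1], 2, ["narK"])
    assert a.equals(b)


def test_positional_profile_fraction_and_error(toy_table):
    results = []
    for i in range(10):
        genes = (
            [("narg", "+"), ("narh", "+"), ("narj", "+"), ("nari", "+")]
            if i < 9
            else [("narg", "+"), ("narj", "+"), ("narh", "+"), ("nari", "+")]
        )
        t = make_table(genes, genome_id=f"g{i}")
        ops = call_operons(t)
        tag = [r.locus_tag for r in t.records if r.gene_name == "narj"][0]
        results.append(classify_association(t, ops, tag, NARJ_DEF))
    assert positional_profile(results, "narJ", ("narH", "narI")) == pytest.approx(0.9)
    with pytest.raises(UndefinedStatisticError):
        positional_profile([], "narJ", ("narH", "narI"))


def test_presence_correlation_exact_cases():
    m = pd.DataFrame(
        {"a": [1, 1, 0, 0], "same": [1, 1, 0, 0], "opp": [0, 0, 1, 1]},
        index=[f"g{i}" for i in range(4)],
    )
    r = presence_correlation(m)
    assert r.loc["a", "same"] == pytest.approx(1.0)
    assert r.loc["a", "opp"] == pytest.approx(-1.0)


def test_presence_correlation_phi_from_contingency():
    # 2x2 table (3,1;1,3) over 8 genomes -> phi = 0.5
    a = [1, 1, 1, 1, 0, 0, 0, 0]
    b = [1, 1, 1, 0, 1, 0, 0, 0]
    m = pd.DataFrame({"a": a, "b": b})
    r = presence_correlation(m)
    assert r.loc["a", "b"] == pytest.approx(0.5)


def test_presence_correlation_matches_contingency_phi_oracle():
    rng = np.random.default_rng(2)
    m = pd.DataFrame(rng.integers(0, 2, size=(40, 5)), columns=list("abcde"))
    r = presence_correlation(m)
    for i in "abcde":
        for j in "abcde":
            if i == j:
                continue
            tab = pd.crosstab(m[i], m[j]).reindex(
                index=[0, 1], columns=[0, 1], fill_value=0
            ).to_numpy()
            n = tab.sum()
            num = tab[1, 1] * tab[0, 0] - tab[1, 0] * tab[0, 1]
            den = math.sqrt(
                tab[1].sum() * tab[0].sum() * tab[:, 1].sum() * tab[:, 0].sum()
            )
            if den == 0:
                assert math.isnan(r.loc[i, j])
            else:
                assert r.loc[i, j] == pytest.approx(num / den, abs=1e-12)


def test_presence_correlation_constant_column_is_nan_not_zero():
    m = pd.DataFrame({"a": [1, 0, 1], "const": [1, 1, 1]})
    r = presence_correlation(m)
    assert math.isnan(r.loc["a", "const"])
    assert math.isnan(r.loc["const", "const"])
    assert r.loc["a", "a"] == 1.0


def test_presence_correlation_needs_two_rows():
    with pytest.raises(UndefinedStatisticError):
        presence_correlation(pd.DataFrame({"a": [1], "b": [0]}))


def test_mobile_element_flagging():
    table = make_table(
        [("narj", "+"), ("", "+", "IS5 family transposase"), ("", "+")]
    )
    nb = extract_neighborhood(table, "G1_0000")
    assert has_mobile_element(nb)
    table2 = make_table([("narj", "+"), ("", "+"), ("", "+")])
    assert not has_mobile_element(extract_neighborhood(table2, "G1_0000"))
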
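"""Synthetic genome and codon-divergence generator contracts."""

import numpy as np
import pytest

from rempscan.annotation_io import call_operons
from rempscan.codon_evolution import (
    CodonAlignment,
    GENETIC_CODE,
    pairwise_dnds,
)
from rempscan.operon_analysis import classify_association, default_definitions
from rempscan.synthetic_data import (
    EvolutionConfig,
    GenomeTemplate,
    OperonLayout,
    default_template_library,
    evolve_pair,
    generate_dataset,
    generate_genome,
    random_cds,
)

DEFS = {d.family: d for d in default_definitions()}


def narj_template(cis_prob=None, placement="cis", flank_prob=1.0):
    return GenomeTemplate(
        phylum="TestPhylum",
        layouts=[
            OperonLayout.simple(
                ["narG", "narH", "narJ", "narI"],
                chaperone="narJ",
                cis_prob=cis_prob,
                placement=placement,
                flank_prob=flank_prob,
            )
        ],
    )


def test_cis_layout_roundtrips_through_classification():
    sim = generate_genome(narj_template(), seed=1)
    tag = sim.chaperone_loci["narJ"][0]
    ops = call_operons(sim.table)
    res = classify_association(sim.table, ops, tag, DEFS["narJ"])
    assert res.mode == "cis"
    assert tuple(s.lower() for s in res.flanked_by) == ("narh", "nari")


def test_trans_placement_roundtrips():
    tmpl = GenomeTemplate(
        phylum="T",
        layouts=[
            OperonLayout.simple(
                ["torA", "torC", "torD"], chaperone="torD", placement="trans"
            )
        ],
    )
    sim = generate_genome(tmpl, seed=2)
    tag = sim.chaperone_loci["torD"][0]
    assert sim.placements[tag] == "trans"
    ops = call_operons(sim.table)
    res = classify_association(sim.table, ops, tag, DEFS["torD"])
    assert res.mode == "trans"
    assert res.matched_set_label == "torD_torAC"


def test_absent_placement_removes_chaperone():
    sim = generate_genome(narj_template(placement="absent"), seed=3)
    assert "narJ" not in sim.chaperone_loci


def test_same_seed_is_byte_identical():
    a = generate_genome(narj_template(), seed=42)
    b = generate_genome(narj_template(), seed=42)
    assert a.table.to_frame().equals(b.table.to_frame())
    assert a.table.sequences == b.table.sequences
    d1 = generate_dataset(4, seed=9, evolution=EvolutionConfig(length=60))
    d2 = generate_dataset(4, seed=9, evolution=EvolutionConfig(length=60))
    assert d1.cds == d2.cds and d1.protein_msa == d2.protein_msa


@pytest.mark.parametrize("seed", range(6))
def test_generated_annotations_satisfy_table_invariants(seed):
    tmpl = default_template_library()[seed % 3]
    sim = generate_genome(tmpl, seed=seed)
    recs = sim.table.records
    for contig in sim.table.contigs():
        crecs = sim.table.contig_records(contig)
        assert [r.rank for r in crecs] == list(range(len(crecs)))
        starts = [r.start for r in crecs]
        assert starts == sorted(starts)
        for prev, nxt in zip(crecs, crecs[1:]):
            assert nxt.start > prev.end  # non-overlapping
    assert len({r.locus_tag for r in recs}) == len(recs)
    # contig sequence covers every gene
    for contig, seq in sim.table.sequences.items():
        assert len(seq) >= max(r.end for r in sim.table.contig_records(contig))


def test_rate_zero_returns_identical_descendant():
    rng = np.random.default_rng(0)
    anc = random_cds(50, rng)
    cfg = EvolutionConfig(omega=0.5, subs_per_codon=0.0, length=50)
    assert evolve_pair(anc, cfg, rng=rng) == anc


def test_omega_zero_yields_only_synonymous_changes():
    rng = np.random.default_rng(1)
    anc = random_cds(200, rng)
    cfg = EvolutionConfig(omega=0.0, subs_per_codon=1.0, length=200)
    desc = evolve_pair(anc, cfg, rng=rng)
    assert desc != anc
    for ca, cb in zip(anc, desc):
        assert GENETIC_CODE[ca] == GENETIC_CODE[cb]
    aln = CodonAlignment(ids=["a", "b"], codons={"a": anc, "b": desc})
    p = pairwise_dnds(aln, "a", "b")
    assert p.nd == 0 and p.d_n == 0


def test_descendant_is_always_stop_free():
    rng = np.random.default_rng(2)
    for _ in range(5):
        anc = random_cds(100, rng)
        desc = evolve_pair(
            anc, EvolutionConfig(omega=1.0, subs_per_codon=2.0, length=100), rng=rng
        )
        assert all(GENETIC_CODE[c] != "*" for c in desc)


def test_frozen_columns_never_mutate():
    rng = np.random.default_rng(3)
    anc = random_cds(100, rng)
    frozen = frozenset(range(10, 20))
    cfg = EvolutionConfig(
        omega=1.0, subs_per_codon=3.0, length=100, frozen_columns=frozen
    )
    desc = evolve_pair(anc, cfg, rng=rng)
    for i in frozen:
        assert desc[i] == anc[i]


def test_synonymous_fraction_rises_as_omega_falls():
    fractions = []
    for omega in (1.0, 0.5, 0.1):
        rng = np.random.default_rng(7)
        syn = non = 0
        for _ in range(10):
            anc = random_cds(200, rng)
            desc = evolve_pair(
                anc,
                EvolutionConfig(omega=omega, subs_per_codon=0.5, length=200),
                rng=rng,
            )
            for ca, cb in zip(anc, desc):
                if ca != cb:
                    if GENETIC_CODE[ca] == GENETIC_CODE[cb]:
                        syn += 1
                    else:
                        non += 1
        fractions.append(syn / (syn + non))
    assert fractions[0] < fractions[1] < fractions[2]


def test_indel_free_msa_width_equals_ancestor_length(small_dataset):
    widths = {len(s) for s in small_dataset.protein_msa.values()}
    assert widths == {120}
    for sid, seq in small_dataset.protein_msa.items():
        assert "-" not in seq
        assert len(small_dataset.cds[sid]) == 3 * len(seq)


def test_dataset_group_map_covers_all_sequences(small_dataset):
    assert set(small_dataset.groups) == set(small_dataset.protein_msa)
    fams = {fam for fam, _ in small_dataset.groups.values()}
    assert fams <= {"narJ", "narW", "dmsD", "torD", "ycdY"}


def test_dataset_write_roundtrip(tmp_path, small_dataset):
    from rempscan.annotation_io import read_annotation, read_cds, read_msa

    paths = small_dataset.write(tmp_path)
    msa = read_msa(paths["msa"])
    cds = read_cds(paths["cds"])
    assert msa == small_dataset.protein_msa
    assert cds == small_dataset.cds
    gid = small_dataset.genomes[0].table.genome_id
    via_tsv = read_annotation(paths["genome_tables"] / f"{gid}.tsv", dialect="tsv")
    via_gff = read_annotation(paths["genome_tables"] / f"{gid}.gff3", dialect="gff3", genome_id=gid)
    assert via_tsv.to_frame().equals(small_dataset.genomes[0].table.to_frame())
    assert via_gff.to_frame().drop(columns="genome_id").equals(
        small_dataset.genomes[0].table.to_frame().drop(columns="genome_id")
    )


def test_impossible_layout_rejected():
    with pytest.raises(ValueError):
        OperonLayout.simple(["narG", "narH"], chaperone="narJ")
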
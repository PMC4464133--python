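# rempscan

Genomic-context and molecular-evolution analysis of **redox enzyme
maturation protein (REMP) chaperones** of the NarJ subfamily — NarJ,
NarW, DmsD, TorD and YcdY — the system-specific cytoplasmic chaperones
that fold, load cofactors into, and target complex iron–sulfur
molybdoenzyme (CISM) respiratory enzymes (nitrate reductase NarGHI,
DMSO reductase DmsABC, TMAO reductase TorAC, formate dehydrogenase
FdhGHI, ...) to the twin-arginine translocase.

The package is for microbial comparative genomicists who want to ask,
for a set of annotated genomes and a chaperone protein alignment:

* **Is each chaperone gene *cis* or *trans* to its cognate enzyme
  operon?** (*cis* = inside the operon; *trans* = the complete enzyme
  gene set exists elsewhere in the genome; otherwise *absent*.)
* **Which genes co-occur near chaperone loci**, quantified by the
  frequency-of-gene-occurrence statistic over ±10-ORF neighborhoods:

  F^G = (n_gene / n_locus) / O

  where n_gene counts loci whose neighborhood contains the gene,
  n_locus the chaperone loci examined, and O the chaperone operons
  examined (the raw fraction n_gene / n_locus is reported alongside).
* **What selection pressure acts on each family**, via pairwise
  Nei–Gojobori dN/dS on a codon alignment threaded from the protein
  MSA: per-codon synonymous site fractions (S + N = 3, stop-codon
  mutants excluded and renormalized), pathway-averaged substitution
  counts Sd/Nd, proportions pS = Sd/S and pN = Nd/N, Jukes–Cantor
  correction d = −(3/4)·ln(1 − (4/3)·p) (undefined at p ≥ 0.75), and
  dN/dS = dN/dS with five-point percentile summaries per
  family × phylum, plus per-codon Sd profiles.
* **Which residues define each family**, as two-tier consensus motifs:
  bold for column identity ≥ 75 %, normal for [60 %, 75 %), numbered
  against a reference sequence (insertion suffixes at reference gaps).
* **How operon types co-distribute across genomes**, as phi-coefficient
  (binary Pearson) presence/absence correlations.

A bundled synthetic-genome generator emulates the observed operon
architectures (narGHJI ± narK/narU/ppiC, dmsABC(D), torACD ± torRST,
ycdXY, hflC–mdaB, fdhGHI, nrfD–hybA–bisC), configurable cis/trans
fractions, transposase insertions, and codon divergence under a target
dN/dS, so the whole pipeline is testable end-to-end without downloads.

## Worked example

```pycon
>>> import numpy as np
>>> from rempscan import (CodonAlignment, EvolutionConfig, pairwise_dnds)
>>> from rempscan.synthetic_data import evolve_pair, random_cds
>>> rng = np.random.default_rng(42); ratios = []
>>> for _ in range(30):
...     anc = random_cds(300, rng)
...     desc = evolve_pair(anc, EvolutionConfig(omega=0.25, subs_per_codon=0.8), rng=rng)
...     aln = CodonAlignment(ids=["a", "b"], codons={"a": anc, "b": desc})
...     p = pairwise_dnds(aln, "a", "b")
...     if p.valid: ratios.append(p.ratio)
>>> round(float(np.median(ratios)), 3)
0.265
```

Thirty ancestor/descendant pairs of 300 codons simulated at
omega = 0.25 give a median pairwise dN/dS of 0.265 — the counting and
Jukes–Cantor correction recover the simulated purifying-selection
strength. The `examples/` directory has one short script per
capability; `examples/02_cis_trans_and_gene_frequency.py` prints, for
30 generated genomes:

```
narJ loci: 30, cis 90.0% (configured 91.7%)
narJ between narH and narI: 96.3% of cis loci
```

i.e. the classifier reads back the cis fraction and narH–narJ–narI
flanking arrangement the generator planted, within sampling noise.

## Command line

A thin CLI wraps the library:

```bash
rempscan simulate --n-genomes 12 --seed 17 --out sim/
rempscan neighborhood --gff sim/genomes/g000.tsv --dialect tsv --locus g000_00018
rempscan operon --gff sim/genomes/g000.tsv --dialect tsv
rempscan dnds --msa sim/msa.faa --cds sim/cds.fna --groups sim/groups.tsv
rempscan motif --msa sim/msa.faa --reference <id>
rempscan pipeline --config run.yaml
```

`rempscan pipeline` writes association, F^G, dN/dS pair/summary,
Sd-profile, motif and correlation TSVs plus a manifest with input
checksums; re-runs with the same seed are bit-identical.

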
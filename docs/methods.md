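# Methods

## Scope and data model

The package analyses three inputs: per-genome annotated gene tables
(GFF3 CDS features or a documented TSV dialect), a protein multiple
sequence alignment of chaperone homologues with matching unaligned CDS
nucleotide sequences, and a configuration mapping chaperone families to
their cognate enzyme gene sets. Coordinates are 1-based inclusive
(GFF3 convention) throughout. Gene tables are canonicalized on load:
records sorted by (contig, start), consecutive per-contig ranks
assigned, locus tags checked unique — so parsing is insensitive to
input row order.

Dataset assembly (homology searches, clustering, alignment
construction) is out of scope: the MSA is consumed as input, and the
configured e-value note (≤ 1e-4) is recorded in the run manifest as
provenance only. Trees are never inferred; an optional Newick input is
only decorated leaf-by-leaf with operon classes.

## Neighborhoods and operons

A neighborhood is the ±r ORF window (default r = 10) around a focal
locus, counted by rank on the same contig, ignoring strand and bp
distance, truncating at contig ends. Neighborhood membership is
therefore symmetric.

Genome annotations rarely state operon boundaries, so operons are
called with a standard heuristic: maximal runs of same-strand genes
whose successive intergenic gaps are ≤ `max_gap` (default 150 bp).
Singletons form singleton operons; the calls partition every contig.
The gap threshold is configurable precisely because it is a heuristic
stand-in for manual annotation inspection.

## cis / trans / absent classification

For each chaperone locus and its family definition (an ordered list of
named cognate gene sets):

* **cis** — at least one cognate gene of any set shares the focal
  gene's operon call. One gene suffices because real genomes carry
  incomplete enzyme operons (e.g. DMSO-reductase operons lacking the
  membrane-anchor gene) that still establish the association. The
  matched set is the one with the largest in-operon overlap; ties break
  by definition order (deterministic).
* **trans** — no cognate gene is co-operonic, but some cognate set is
  *complete* somewhere in the genome (completeness mirrors verifying a
  system's presence by whole-genome search before declaring absence).
* **absent** — otherwise.

Gene identity matches the lower-cased gene symbol first and falls back
to a case-insensitive substring match against the product text, since
annotation practice varies. Neighborhoods whose products match
/transposase|integrase|insertion sequence/i are flagged as containing
mobile elements. Classification is exhaustive and mutually exclusive by
construction, which the property tests assert.

The positional profile reports, over cis loci of a family, the fraction
flanked by a given unordered gene pair (e.g. narH–narJ–narI).

### Frequency of gene occurrence

F^G = (n_gene / n_locus) / O, where n_gene counts *loci* whose
neighborhood contains the gene (a gene occurring twice in one window
counts once), n_locus the family loci examined, and O the family
operons examined. Because dividing a fraction by an operon count yields
non-intuitive units, the raw fraction n_gene / n_locus is always
reported alongside; co-occurrence thresholds quoted as percentages
apply to the raw fraction. Frequencies are computed over loci; a
species contributing several loci contributes each of them (callers can
pass one neighborhood per genome to get per-genome figures instead).

### Presence/absence correlation

Binary genome × operon-type matrices are correlated with Pearson r on
0/1 columns, which equals the phi coefficient of the 2×2 contingency
table (asserted against a contingency oracle in the tests). Constant
columns have undefined correlation and yield NaN — never 0 — including
on the diagonal.

## Codon alignment and dN/dS

CDS sequences are threaded under the protein MSA (back-translation): a
CDS must be exactly 3× its ungapped protein length after optional
terminal-stop trimming and must translate to the protein under NCBI
table 11 (bacteria/archaea, fixed — the analysis targets prokaryotes).
A first-residue mismatch is tolerated when the protein has M and the
codon is a table-11 start codon (GTG/TTG starts are annotated as Met).
Gap residues become `---` codons; internal stops are errors.

Counting follows the Nei–Gojobori (1986) pathway method:

* **Sites.** Per codon position, the synonymous fraction is the share
  of the single-nucleotide mutants that are synonymous, with mutants
  creating stop codons excluded from the denominator, so S + N = 3
  exactly per codon. (The original convention counts stop mutants as
  non-synonymous; the renormalized variant is used here because it
  pairs exactly with the stop-rejecting mutation process of the
  simulator — proposals to stops never happen, and the sites
  normalization agrees, making realized dN/dS track the simulated
  omega.)
* **Differences.** For codons differing at k ≤ 3 positions, Sd and Nd
  average over all k! orderings of the changes; orderings passing
  through a stop codon are excluded and the remainder re-weighted
  equally, so Sd + Nd = k. If *every* ordering is blocked (possible for
  a handful of codon pairs), each differing position is scored
  independently in both codon contexts and the result flagged
  (`fallback`); the enumeration oracle in the tests confirms which
  pairs these are.
* **Pairwise comparison.** Columns with a gap, a non-ACGT base, or a
  stop in either cell are skipped (pairwise deletion). S and N are
  averaged over the two sequences; pS = Sd/S and pN = Nd/N are
  Jukes–Cantor corrected, d = −(3/4)·ln(1 − (4/3)p), undefined for
  p ≥ 0.75. A pair is **invalid** when pS or pN reaches the 0.75
  cutoff, when S = 0, or when dS = 0; dS = 0 with dN > 0 is reported as
  the infinite category but excluded from percentile summaries (the
  summaries describe bounded distributions). The cutoff applies to pN
  as well as pS for symmetry — a saturated numerator is as
  uninterpretable as a saturated denominator.

Group summaries take intra-group pairs only (group = family × phylum)
and report min / 25th / median / 75th / max of the valid ratios with
linear interpolation between order statistics (the convention is
configurable nowhere — it is documented here instead, since percentile
conventions differ across tools). The per-codon Sd profile reports, per
aligned codon column, the mean (or, by flag, the sum) of
pathway-averaged Sd over contributing pairs; column means weighted by
pair counts reconcile exactly (1e-9) with mean total Sd across pairs.

## Conservation motifs

Per-column identity is the modal non-gap residue's share of the
subgroup, ties broken alphabetically. Gaps count in the denominator by
default (a mostly-gapped column should not become a motif position,
consistent with trimming poorly aligned regions before motif work);
`count_gaps=False` gives the ungapped-denominator convention since
alignment viewers differ on this.

Motif tiers: **bold** for identity ≥ 0.75, **normal** for
[0.60, 0.75). The verbal convention "60–74 % and >75 %" leaves
[0.74, 0.75) unassigned; the half-open implementation makes the tiers
partition — a deliberate, documented divergence. Positions are numbered
by the count of non-gap reference residues up to the column; columns
where the reference is gapped take the preceding number with insertion
suffixes (84a, 84b, ...), the standard reference-numbering practice.
Motif comparison emits substitutions at shared positions (K37G-style
notation) and presence differences, and requires both motifs to share
the reference.

Raising either threshold can only remove entries (monotonicity —
property-tested).

## Synthetic data generator

The generator defines the test conditions; its defaults encode the
observed architecture statistics rather than convenient values:

* narGHJI with narJ cis 91.7 % and flanked narH–narJ–narI at 98 %;
  narK/narU included independently at p = 0.35 each (reproducing the
  ~58 % at-least-one-transporter frequency; the joint frequency is not
  separately matched), ppiC at 52 %.
* dmsABC(D) with dmsD cis 80 %; dmsD after dmsC in Gram-negative
  templates (65 %) and before dmsA in Gram-positive (61 %) and Archaeal
  (85 %) templates; transposase insertion near dmsD at 21 % (1 % near
  torD).
* torACD ± torRST (48 %) in Gram-negatives; torD with nrfD–hybA–bisC
  in Gram-positives and fdhGHI ± DUF3305/DUF3306/hybA in Archaea;
  ycdXY for ycdY.
* Per-family omega defaults 0.65 (narJ, narW, torD), 0.57 (dmsD),
  0.24 (ycdY) — the purifying regimes characteristic of each family.

Genomes are single contigs: operon blocks (intra-operon gaps uniform
20–120 bp) separated by 12–16 filler genes with spacer gaps of
250–450 bp, which exceed the operon-calling `max_gap` so blocks never
merge. Trans-placed chaperones land as singletons among distant
fillers. Gene lengths are uniform multiples of 3 in 300–900 bp; contig
sequence is uniform random nucleotide filler (the analysis reads
annotations and the separate CDS FASTA, not the contig sequence).

Codon divergence: each proposal picks a uniform codon, position and
alternative nucleotide; proposals creating stops are rejected;
synonymous proposals are accepted with probability 1 (scaled by 1/omega
when omega > 1) and non-synonymous with probability min(omega, 1).
`subs_per_codon` is the expected number of *proposals* per codon (the
divergence dial; default 0.8, giving pairwise pS well below the 0.75
cutoff at 300 codons). Because the proposal process excludes stops
exactly as the site counting does, realized dN/dS tracks omega; the
acceptance tests verify medians within ±0.15 at omega 0.25/0.6/1.0 and
strict ordering. Mutation is nucleotide-uniform (no transition bias) —
a documented divergence from real data. Indels are off by default, so
the protein MSA is exact by construction (width = ancestor length in
codons) and no aligner is needed; `frozen_columns` plants fully
conserved positions for motif-recovery tests. All randomness flows
through `numpy.random.default_rng` integer seeds; identical seeds give
byte-identical output.

### What the generator does *not* emulate

No phylogenetic structure (all descendants radiate from one family
ancestor, so intra-family pairs are star-shaped); no indel process by
default; no transition/transversion or codon-usage bias; no intergenic
sequence realism; annotation products are clean and consistent, unlike
real misannotation. Passing tests therefore demonstrate correctness of
the *measurements* under known conditions — not that real genomes
satisfy those conditions.

## Pipeline and reproducibility

`run_pipeline` executes load → association (+neighborhood mobile-
element flags) → gene frequency → dN/dS (+Sd profile) → motif →
correlation (→ optional tree-leaf decoration), each stage wrapped so
errors surface with the stage name. All intermediates are plain TSV; a
JSON manifest records version, seed, full config and SHA-256 input
checksums. Re-running with identical inputs and seed reproduces every
report byte-for-byte (timestamp aside).

Problem sizes in tests and in `scripts/acceptance.py` — 12–60 genomes,
60–300-codon chaperones, 30 replicate pairs per omega level — were
chosen as the smallest sizes at which the stochastic checks are stable
across seeds; the whole acceptance run completes in seconds.

## Numerical choices and edge cases

* Conservation identities use absolute tolerance 1e-9.
* jc_correct uses log1p for accuracy at small p; jc(p) ≥ p holds to
  float rounding.
* Identical sequences give pS = pN = 0, hence dS = 0 and an undefined
  ratio (invalid), not 0/0 crashes.
* Degenerate statistics (zero loci, zero operons, zero cis loci, <2
  genomes) raise `UndefinedStatisticError` rather than returning 0.
* Modal-residue ties and multi-set association ties break
  deterministically (alphabetical; definition order).

## Known limitations

Nei–Gojobori counting with equal pathway weights and Jukes–Cantor
correction is approximate relative to maximum-likelihood omega
estimation (out of scope by design); very close pairs have noisy ratios
(few substitutions) and saturated pairs are excluded by the 0.75
cutoff, both of which bias family summaries in opposite directions.
The operon gap rule is a heuristic; genomes with unusual intergenic
spacing may need a different `max_gap`. GenBank flat files,
eukaryotic multi-exon features and gene calling from raw sequence are
out of scope.
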
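"""Gene neighborhoods and operon calls on a synthetic genome.

Generates one annotated genome carrying a narGHJI operon, extracts the
+/-10 ORF window around the narJ locus, and segments the contig into
operons. The printed window shows the chaperone's genomic context; the
operon sizes show how the same-strand / <=150 bp gap rule groups genes.
"""

from rempscan.annotation_io import call_operons, extract_neighborhood
from rempscan.synthetic_data import GenomeTemplate, OperonLayout, generate_genome

template = GenomeTemplate(
    phylum="Gammaproteobacteria",
    layouts=[
        OperonLayout.simple(
            ["narK", "narG", "narH", "narJ", "narI"], chaperone="narJ"
        )
    ],
)
sim = generate_genome(template, seed=7, genome_id="demo")
narj_tag = sim.chaperone_loci["narJ"][0]

nb = extract_neighborhood(sim.table, narj_tag, radius=10)
print(f"focal locus {narj_tag} ({nb.focal.gene_name})")
print(f"upstream ({len(nb.upstream)} genes, nearest first):",
      [r.gene_name or r.product[:20] for r in nb.upstream[:5]], "...")
print(f"downstream ({len(nb.downstream)} genes):",
      [r.gene_name or r.product[:20] for r in nb.downstream[:5]], "...")

calls = call_operons(sim.table, max_gap=150)
sizes = sorted((len(c) for c in calls), reverse=True)
print(f"{len(calls)} operon calls; largest contains {sizes[0]} genes "
      "(the nar operon plus its transporter)")
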
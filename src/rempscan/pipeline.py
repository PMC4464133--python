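"""End-to-end analysis pipeline.

Runs neighborhoods -> operon association -> gene-frequency (F^G) ->
pairwise dN/dS + per-codon Sd profile -> consensus motifs -> presence
correlations from one configuration, writing plain-TSV reports and a
JSON run manifest (config, seed, input checksums) so any stage can be
audited or re-run from intermediates. Re-running with identical inputs
and seed is bit-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    AnnotationTable,
    call_operons,
    extract_neighborhood,
    read_annotation,
    read_cds,
    read_msa,
    check_ids_match,
)
from .codon_evolution import (
    all_pairwise,
    group_summary,
    pairs_to_frame,
    sd_profile,
    summaries_to_frame,
    thread_codons,
)
from .conservation_motif import extract_motif, identity_profile, render_motif
from .operon_analysis import (
    classify_association,
    default_definitions,
    gene_frequency,
    has_mobile_element,
    load_definitions,
    presence_correlation,
)

log = logging.getLogger("rempscan")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage, wrapping the original cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline settings; mirrors the YAML config file layout.

    ``homology_evalue_note`` records the upstream homology-search cutoff
    used to assemble real datasets (<= 1e-4); it is provenance only —
    no searches are run here.
    """

    annotations: list[str] = field(default_factory=list)  # GFF3 or TSV paths
    annotation_dialect: str = "tsv"
    msa: str | None = None
    cds: str | None = None
    groups: str | None = None  # TSV: id, family, phylum
    definitions: str | None = None  # YAML; None -> built-in defaults
    reference_id: str | None = None  # motif numbering reference
    tree: str | None = None  # optional Newick; leaves annotated, never inferred
    radius: int = 10
    max_gap: int = 150
    motif_t1: float = 0.60
    motif_t2: float = 0.75
    jc_cutoff: float = 0.75  # fixed; recorded for provenance
    homology_evalue_note: float = 1e-4
    seed: int = 0
    outdir: str = "rempscan_out"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        for name in ("motif_t1", "motif_t2", "jc_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the report bundle paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
            timings[name] = round(time.perf_counter() - t0, 4)
            log.info("stage %s done in %.2fs", name, timings[name])
            return result

        return deco

    @stage("load")
    def _loaded():
        tables = [
            read_annotation(p, dialect=cfg.annotation_dialect) for p in cfg.annotations
        ]
        if not tables:
            raise ValueError("no annotation inputs configured")
        defs = (
            load_definitions(cfg.definitions)
            if cfg.definitions
            else default_definitions()
        )
        groups = None
        if cfg.groups:
            gdf = pd.read_csv(cfg.groups, sep="\t", dtype=str)
            groups = {
                r["id"]: (r["family"], r["phylum"]) for _, r in gdf.iterrows()
            }
        return tables, defs, groups

    tables, definitions, groups = _loaded

    @stage("operon")
    def _assoc():
        rows = []
        results = []
        neighborhoods = {}  # family -> list of Neighborhood
        operon_counts = {}  # family -> operon tally
        for table in tables:
            operons = call_operons(table, max_gap=cfg.max_gap)
            fam_loci = _find_family_loci(table, definitions)
            for definition in definitions:
                for tag in fam_loci.get(definition.family, []):
                    res = classify_association(table, operons, tag, definition)
                    nb = extract_neighborhood(table, tag, radius=cfg.radius)
                    res.mobile_element = has_mobile_element(nb)
                    results.append(res)
                    neighborhoods.setdefault(definition.family, []).append(nb)
                    operon_counts[definition.family] = (
                        operon_counts.get(definition.family, 0) + 1
                    )
                    rows.append(
                        {
                            "genome_id": res.genome_id,
                            "locus_tag": res.locus_tag,
                            "family": res.family,
                            "mode": res.mode,
                            "matched_set_label": res.matched_set_label or "",
                            "flank_before": (res.flanked_by or (None, None))[0] or "",
                            "flank_after": (res.flanked_by or (None, None))[1] or "",
                            "mobile_element": res.mobile_element,
                        }
                    )
        df = pd.DataFrame(rows)
        path = outdir / "associations.tsv"
        df.to_csv(path, sep="\t", index=False)
        return results, neighborhoods, operon_counts, path

    assoc_results, neighborhoods, operon_counts, bundle_path = _assoc
    bundle["associations"] = bundle_path

    @stage("gene_frequency")
    def _freq():
        frames = []
        for definition in definitions:
            fam = definition.family
            nbs = neighborhoods.get(fam)
            if not nbs:
                continue
            symbols = sorted(
                {g for cset in definition.cognate_sets for g in cset.genes}
            )
            frames.append(
                gene_frequency(fam, nbs, operon_counts[fam], symbols)
            )
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=[
                    "family",
                    "gene_symbol",
                    "n_gene",
                    "n_locus",
                    "n_operons",
                    "raw_fraction",
                    "f_g",
                ]
            )
        )
        path = outdir / "gene_frequency.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    bundle["gene_frequency"] = _freq

    @stage("dnds")
    def _dnds():
        if not (cfg.msa and cfg.cds):
            raise FileNotFoundError("dnds stage needs both `msa` and `cds` inputs")
        msa = read_msa(cfg.msa)
        cds = read_cds(cfg.cds)
        check_ids_match(msa, cds)
        aln = thread_codons(msa, cds)
        if groups:
            pairs = []
            by_group: dict[tuple[str, str], list[str]] = {}
            for sid in aln.ids:
                if sid in groups:
                    by_group.setdefault(groups[sid], []).append(sid)
            for ids in by_group.values():
                if len(ids) >= 2:
                    pairs.extend(all_pairwise(aln, ids))
        else:
            pairs = all_pairwise(aln)
        pdf = pairs_to_frame(pairs)
        ppath = outdir / "dnds_pairs.tsv"
        pdf.to_csv(ppath, sep="\t", index=False)
        spath = outdir / "dnds_summary.tsv"
        if groups:
            summaries_to_frame(group_summary(pairs, groups)).to_csv(
                spath, sep="\t", index=False
            )
        else:
            summaries_to_frame(
                group_summary(pairs, lambda _sid: ("all", "all"))
            ).to_csv(spath, sep="\t", index=False)
        prof = sd_profile(aln)
        sdpath = outdir / "sd_profile.tsv"
        prof.to_frame().to_csv(sdpath, sep="\t", index=False)
        return msa, ppath, spath, sdpath

    msa, p1, p2, p3 = _dnds
    bundle["dnds_pairs"], bundle["dnds_summary"], bundle["sd_profile"] = p1, p2, p3

    @stage("motif")
    def _motif():
        ref = cfg.reference_id or next(iter(msa))
        prof = identity_profile(msa)
        motif = extract_motif(prof, msa, ref, t1=cfg.motif_t1, t2=cfg.motif_t2)
        mpath = outdir / "motif.tsv"
        motif.to_frame().to_csv(mpath, sep="\t", index=False)
        (outdir / "motif.txt").write_text(render_motif(motif) + "\n")
        prof.to_frame().to_csv(outdir / "identity_profile.tsv", sep="\t", index=False)
        return mpath

    bundle["motif"] = _motif

    @stage("correlation")
    def _corr():
        # presence/absence of each cognate operon type per genome
        rows: dict[str, dict[str, int]] = {}
        labels = sorted(
            {
                cset.label
                for definition in definitions
                for cset in definition.cognate_sets
            }
        )
        for res in assoc_results:
            row = rows.setdefault(res.genome_id, {lab: 0 for lab in labels})
            if res.matched_set_label:
                row[res.matched_set_label] = 1
        m = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        path = outdir / "presence_correlation.tsv"
        if m.shape[0] >= 2 and m.shape[1] >= 2:
            presence_correlation(m).to_csv(path, sep="\t")
        else:
            pd.DataFrame().to_csv(path, sep="\t")
        m.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        return path

    bundle["correlation"] = _corr

    if cfg.tree:

        @stage("tree")
        def _tree():
            path = outdir / "tree_operon_class.tsv"
            annotate_tree_leaves(cfg.tree, assoc_results, path)
            return path

        bundle["tree"] = _tree

    manifest = {
        "tool": "rempscan",
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [*cfg.annotations, cfg.msa, cfg.cds, cfg.groups, cfg.definitions]
            if p
        },
        "timings_s": timings,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    bundle["manifest"] = mpath
    return bundle


def annotate_tree_leaves(newick_path, results, out_path) -> None:
    """Decorate the leaves of an existing Newick tree with operon class.

    Leaf names are matched to chaperone locus tags; no inference is
    performed — the tree is read-only input and the output a plain TSV
    of leaf, family, mode, matched set.
    """
    from Bio import Phylo

    tree = Phylo.read(str(newick_path), "newick")
    by_locus = {r.locus_tag: r for r in results}
    rows = []
    for leaf in tree.get_terminals():
        res = by_locus.get(leaf.name)
        rows.append(
            {
                "leaf": leaf.name,
                "family": res.family if res else "",
                "operon_class": (res.matched_set_label or res.mode) if res else "",
                "mode": res.mode if res else "",
            }
        )
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)


def _find_family_loci(
    table: AnnotationTable, definitions: Sequence
) -> dict[str, list[str]]:
    """Chaperone loci per family, matched by gene symbol."""
    out: dict[str, list[str]] = {}
    for definition in definitions:
        fam = definition.family.lower()
        out[definition.family] = [
            r.locus_tag for r in table.records if r.gene_name.lower() == fam
        ]
    return out
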
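"""End-to-end orchestration: screen -> annotate -> ortholog -> date.

``run_pipeline`` chains the stages over one or two genome FASTA files,
writes every stage's tables under the configured output directory and
records a manifest (input hashes, config snapshot, per-stage status and
output hashes). Reruns with identical inputs and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

from . import annotate, dating, io, ortholog, screen
from .config import PipelineConfig, dump_config

log = logging.getLogger("paleofv")


class StageFailure(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _annotate_locus(genome: str, locus: screen.ProviralLocus, cfg: PipelineConfig,
                    reference_proteins: dict[str, list[tuple[str, str]]] | None):
    ext = cfg.ltr_flank_extension
    s = max(0, locus.start - ext)
    e = min(len(genome), locus.end + ext)
    sub = genome[s:e]
    pair = annotate.detect_ltr_pair(sub, min_len=cfg.ltr_min_len, max_len=cfg.ltr_max_len,
                                    min_identity=cfg.ltr_min_identity)
    pair_genome = None
    if pair is not None:
        pair_genome = dataclasses.replace(
            pair, ltr5_start=pair.ltr5_start + s, ltr5_end=pair.ltr5_end + s,
            ltr3_start=pair.ltr3_start + s, ltr3_end=pair.ltr3_end + s)
    genes = []
    if reference_proteins:
        genes = annotate.annotate_coding_regions(sub, reference_proteins)
        genes = [dataclasses.replace(g, start=g.start + s, end=g.end + s,
                                     blocks=[(bs + s, be + s, f) for bs, be, f in g.blocks])
                 for g in genes]
    flags = annotate.flag_repeat_artifacts(
        sub, min_len=cfg.artifact_min_len, min_identity=cfg.artifact_min_identity,
        max_adjacency_gap=cfg.artifact_max_adjacency_gap, ltr_pair=pair)
    flags = [annotate.ArtifactFlag(
        source_span=(f.source_span[0] + s, f.source_span[1] + s),
        duplicate_span=(f.duplicate_span[0] + s, f.duplicate_span[1] + s),
        identity=f.identity, adjacency_gap=f.adjacency_gap) for f in flags]
    return pair_genome, genes, flags


def run_pipeline(cfg: PipelineConfig, genome_paths: dict[str, str | Path],
                 probe_path: str | Path,
                 gene_probe_path: str | Path | None = None) -> dict:
    """Run the full discovery chain and return the manifest dict.

    ``genome_paths`` maps genome ids to FASTA paths (one or two genomes; the
    ortholog stage needs two). ``probe_path`` holds the screening probe
    proteins; ``gene_probe_path`` (default: same file) supplies gene-labelled
    probes for coding-region annotation, labels taken from a ``gene=`` tag in
    the FASTA description or the suffix after the last '.' in the id.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "inputs": {}, "stages": {}, "outputs": {},
    }
    for gid, p in genome_paths.items():
        manifest["inputs"][str(p)] = _sha256(Path(p))
    manifest["inputs"][str(probe_path)] = _sha256(Path(probe_path))
    dump_config(cfg, outdir / "effective_config.yaml")

    genomes: dict[str, str] = {}
    for gid, p in genome_paths.items():
        recs = io.read_fasta(p)
        if len(recs) != 1:
            # multi-contig assemblies are screened contig by contig; the
            # bundled scenarios emit single-contig genomes
            log.warning("genome %s has %d contigs; concatenation not applied", gid, len(recs))
        genomes[gid] = next(iter(recs.values()))
    probes = screen.ProbeSet.from_fasta(probe_path)
    gene_probes = _load_gene_probes(gene_probe_path or probe_path)

    loci_by_genome: dict[str, list[screen.ProviralLocus]] = {}
    annotations: dict[str, dict[str, dict]] = {}
    ltr_pairs: dict[str, annotate.LTRPair | None] = {}
    try:
        for gid, genome in genomes.items():
            t0 = time.monotonic()
            hits = screen.translated_search(
                genome, probes, screen.SearchParams(report_max_e=cfg.screen_report_max_e),
                genome_id=gid, contig_id="chr1")
            kept = screen.filter_hits(hits, cfg.screen_min_identity,
                                      cfg.screen_min_coverage, cfg.screen_max_e)
            loci = screen.merge_hits_to_loci(kept, cfg.merge_max_gap_bp)
            for loc in loci:
                loc.locus_id = f"{gid}.{loc.locus_id}"
            loci_by_genome[gid] = loci
            io.hits_to_frame(kept).to_csv(outdir / f"{gid}.hits.tsv", sep="\t", index=False)
            io.write_hits_gff3(kept, outdir / f"{gid}.hits.gff3")
            manifest["stages"][f"screen.{gid}"] = {
                "status": "ok", "n_hits": len(kept), "n_loci": len(loci),
                "seconds": round(time.monotonic() - t0, 3)}
            log.info("screen %s: %d hits -> %d loci", gid, len(kept), len(loci))

        all_loci = [l for ls in loci_by_genome.values() for l in ls]
        if all_loci:
            screen.cluster_lineages(all_loci, genomes, cfg.lineage_identity_threshold)

        for gid, loci in loci_by_genome.items():
            t0 = time.monotonic()
            annotations[gid] = {}
            for loc in loci:
                pair, genes, flags = _annotate_locus(genomes[gid], loc, cfg, gene_probes)
                annotations[gid][loc.locus_id] = {
                    "ltr_pair": pair, "genes": genes, "artifacts": flags}
                ltr_pairs[loc.locus_id] = pair
            io.loci_to_frame(loci).to_csv(outdir / f"{gid}.loci.tsv", sep="\t", index=False)
            io.write_loci_gff3(loci, outdir / f"{gid}.loci.gff3", annotations[gid])
            manifest["stages"][f"annotate.{gid}"] = {
                "status": "ok", "n_ltr_pairs": sum(
                    1 for l in loci if annotations[gid][l.locus_id]["ltr_pair"]),
                "seconds": round(time.monotonic() - t0, 3)}

        if len(genomes) == 2:
            t0 = time.monotonic()
            (gid_a, gid_b) = list(genomes)
            matrix = ortholog.ortholog_matrix(
                loci_by_genome[gid_a], loci_by_genome[gid_b],
                genomes[gid_a], genomes[gid_b], flank_len=cfg.flank_len,
                min_identity=cfg.ortholog_min_identity,
                min_coverage=cfg.ortholog_min_coverage,
                min_block=cfg.ortholog_min_block)
            matrix.to_frame().to_csv(outdir / "ortholog_calls.tsv", sep="\t", index=False)
            ortholog.export_synteny_map(matrix.calls).to_csv(
                outdir / "synteny_links.tsv", sep="\t", index=False)
            manifest["stages"]["ortholog"] = {
                "status": "ok", "n_pairs_evaluated": len(matrix.calls),
                "n_mutual_orthologs": len(matrix.mutual_pairs),
                "seconds": round(time.monotonic() - t0, 3)}

        params = dating.DatingParams(R=cfg.substitution_rate, model=cfg.dating_model)
        results = dating.date_all(ltr_pairs, params)
        dating.write_report(results, outdir / "dating.tsv", outdir / "dating.json")
        manifest["stages"]["dating"] = {
            "status": "ok",
            "n_dated": sum(1 for r in results if r.status == "dated"),
            "n_undatable": sum(1 for r in results if r.status == "undatable")}
    except Exception as exc:  # record partial manifest, then re-raise
        manifest["stages"]["FAILED"] = {"status": "error", "message": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise StageFailure(str(exc)) from exc

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _load_gene_probes(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Gene-labelled probes: {gene: [(probe_id, protein), ...]}."""
    from Bio import SeqIO

    out: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = None
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        if gene is None and "." in rec.id:
            gene = rec.id.rsplit(".", 1)[1]
        if gene is None:
            gene = rec.id
        out.setdefault(gene, []).append((rec.id, str(rec.seq)))
    return out


def summarize_run(outdir: str | Path) -> dict:
    """Merge a run's tables into one JSON-ready summary dict."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    summary = {"stages": manifest["stages"], "outputs": sorted(manifest["outputs"])}
    dating_json = outdir / "dating.json"
    if dating_json.exists():
        summary["dating"] = json.loads(dating_json.read_text())
    return summary
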
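"""FASTA / GFF3 / TSV input-output.

Internal coordinates are 0-based half-open everywhere; GFF3 is written with
its native 1-based inclusive convention, converted only at this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .annotate import LTRPair
from .screen import HomologyHit, ProviralLocus


class ParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {record_id: uppercase sequence}."""
    try:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no sequences found in {path}")
    return records


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff3_line(contig: str, source: str, ftype: str, start0: int, end0: int,
               score, strand: str, attrs: dict[str, str]) -> str:
    score_s = f"{score:.3g}" if isinstance(score, (int, float)) else "."
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return "\t".join([contig, source, ftype, str(start0 + 1), str(end0), score_s,
                      strand, ".", attr_s])


def write_hits_gff3(hits: Sequence[HomologyHit], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for i, h in enumerate(hits):
        lines.append(_gff3_line(h.contig_id, "paleofv", "translated_hit",
                                h.start, h.end, h.score, h.strand, {
                                    "ID": f"hit{i + 1}",
                                    "probe_id": h.probe_id,
                                    "identity": f"{h.percent_identity:.4f}",
                                    "probe_coverage": f"{h.probe_coverage:.4f}",
                                    "e_value": f"{h.e_value:.3g}",
                                    "frame": str(h.frame),
                                }))
    Path(path).write_text("\n".join(lines) + "\n")


def write_loci_gff3(loci: Sequence[ProviralLocus], path: str | Path,
                    annotations: dict[str, dict] | None = None) -> None:
    """Loci plus optional per-locus LTR/gene/artifact features.

    ``annotations`` maps locus_id to a dict with optional keys ``ltr_pair``
    (LTRPair in genome coordinates), ``genes`` (list of GeneAnnotation in
    genome coordinates) and ``artifacts`` (list of ArtifactFlag).
    """
    annotations = annotations or {}
    lines = ["##gff-version 3"]
    for loc in loci:
        attrs = {"ID": loc.locus_id, "n_hits": str(len(loc.supporting_hits))}
        if loc.lineage:
            attrs["lineage"] = loc.lineage
        lines.append(_gff3_line(loc.contig_id, "paleofv", "proviral_locus",
                                loc.start, loc.end, None, loc.strand, attrs))
        ann = annotations.get(loc.locus_id, {})
        pair: LTRPair | None = ann.get("ltr_pair")
        if pair is not None:
            for tag, (s, e) in (("ltr5", pair.ltr5_span), ("ltr3", pair.ltr3_span)):
                lines.append(_gff3_line(loc.contig_id, "paleofv", "long_terminal_repeat",
                                        s, e, None, loc.strand,
                                        {"ID": f"{loc.locus_id}.{tag}",
                                         "Parent": loc.locus_id,
                                         "divergence": f"{pair.divergence_D:.4f}"}))
        for g in ann.get("genes", ()):  # type: GeneAnnotation
            lines.append(_gff3_line(loc.contig_id, "paleofv", "CDS", g.start, g.end,
                                    g.score, g.strand,
                                    {"ID": f"{loc.locus_id}.{g.gene}",
                                     "Parent": loc.locus_id, "gene": g.gene,
                                     "identity": f"{g.identity:.4f}"}))
        for i, a in enumerate(ann.get("artifacts", ())):  # type: ArtifactFlag
            lines.append(_gff3_line(loc.contig_id, "paleofv", "assembly_artifact",
                                    a.source_span[0], a.duplicate_span[1], None,
                                    loc.strand,
                                    {"ID": f"{loc.locus_id}.artifact{i + 1}",
                                     "Parent": loc.locus_id,
                                     "identity": f"{a.identity:.4f}",
                                     "adjacency_gap": str(a.adjacency_gap)}))
    Path(path).write_text("\n".join(lines) + "\n")


def hits_to_frame(hits: Iterable[HomologyHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "genome_id": h.genome_id, "contig_id": h.contig_id,
        "start": h.start, "end": h.end, "strand": h.strand, "frame": h.frame,
        "probe_id": h.probe_id, "percent_identity": h.percent_identity,
        "probe_coverage": h.probe_coverage, "score": h.score, "e_value": h.e_value,
    } for h in hits])


def loci_to_frame(loci: Iterable[ProviralLocus]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_id": l.locus_id, "genome_id": l.genome_id, "contig_id": l.contig_id,
        "start": l.start, "end": l.end, "strand": l.strand,
        "n_hits": len(l.supporting_hits), "lineage": l.lineage,
    } for l in loci])
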
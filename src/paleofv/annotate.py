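"""Per-locus annotation: LTR pairs, ORF disruption, gene boundaries, artifacts.

A candidate endogenous-retrovirus locus is characterised by four largely
independent analyses:

* **LTR pair detection** — the 5' and 3' ends of the locus (extended into its
  flanks) are compared by local alignment; a provirus that retained both long
  terminal repeats shows a high-identity repeat pair whose divergence feeds
  molecular dating. Absence of a pair is a result, not an error: heavily
  decayed lineages often keep no recognisable LTRs.
* **ORF disruption profiling** — positions of start (ATG) and stop
  (TAA/TAG/TGA) codons in the three forward frames, plus per-gene premature
  stop counts and frameshift evidence, quantifying post-insertion decay.
* **Coding-region boundaries** — translated alignment of labelled reference
  proteins (gag/pol/env plus accessory genes) locates each gene even when no
  intact open reading frame survives.
* **Assembly-artifact flags** — near-identical internal repeats sitting next
  to each other, the signature of tandem mis-assembly rather than biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import align
from .screen import ProbeSet, SearchParams, translated_search

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class LTRPair:
    """A detected 5'/3' long-terminal-repeat pair and its divergence.

    Coordinates are 0-based half-open on the sequence handed to
    :func:`detect_ltr_pair`. ``divergence_D`` is the p-distance over ungapped
    alignment columns (model correction is applied downstream at dating
    time); ``indel_columns`` counts gap columns, excluded from D's
    denominator.
    """

    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    aligned_length: int  # ungapped columns
    mismatches: int
    indel_columns: int
    identity: float

    @property
    def p_distance(self) -> float:
        return self.mismatches / self.aligned_length if self.aligned_length else 0.0

    @property
    def divergence_D(self) -> float:
        return self.p_distance

    @property
    def ltr5_span(self) -> tuple[int, int]:
        return (self.ltr5_start, self.ltr5_end)

    @property
    def ltr3_span(self) -> tuple[int, int]:
        return (self.ltr3_start, self.ltr3_end)


@dataclass
class GeneAnnotation:
    gene: str
    start: int
    end: int
    strand: str
    best_probe_id: str
    identity: float
    score: float
    blocks: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, frame)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class OrfDisruptionProfile:
    """Start/stop codon landscape of a locus in the three forward frames."""

    stop_positions: dict[int, list[int]]  # frame (1..3) -> 0-based offsets
    start_positions: dict[int, list[int]]
    premature_stop_count: dict[str, int] = field(default_factory=dict)
    frameshift_evidence: dict[str, bool] = field(default_factory=dict)


@dataclass
class ArtifactFlag:
    source_span: tuple[int, int]
    duplicate_span: tuple[int, int]
    identity: float
    adjacency_gap: int


@dataclass
class MotifScan:
    """Presence/absence of short regulatory motifs (absence is a finding)."""

    motif: str
    positions: list[int]

    @property
    def present(self) -> bool:
        return bool(self.positions)


# ---------------------------------------------------------------------------


def detect_ltr_pair(seq: str, min_len: int = 100, max_len: int = 2000,
                    min_identity: float = 0.70,
                    search_window: int | None = None) -> LTRPair | None:
    """Find the best repeat pair between the two ends of a locus.

    ``seq`` should be the candidate locus extended into its flanks so intact
    LTR boundaries fall inside the two search windows. The 5' window is
    locally aligned against the 3' window; the best-scoring repeat is
    accepted if it spans at least ``min_len`` ungapped columns at
    ``min_identity`` or better. Returns None when no qualifying pair exists
    (e.g. lineages whose LTRs decayed beyond recognition).
    """
    if search_window is None:
        search_window = min(len(seq) // 2, max_len + 1500)
    if len(seq) <= 2 * min_len:
        return None
    w = min(search_window, len(seq) // 2)
    head = seq[:w]
    tail = seq[-w:]
    hit = align.local_dna_alignment(head, tail, trim_ends=True)
    if hit is None:
        return None
    ungapped = hit.identities + hit.mismatches
    if ungapped < min_len:
        return None
    if hit.identities / ungapped < min_identity:
        return None
    if max(hit.query_end - hit.query_start, hit.target_end - hit.target_start) > max_len:
        return None
    off = len(seq) - w
    pair = LTRPair(
        ltr5_start=hit.query_start, ltr5_end=hit.query_end,
        ltr3_start=off + hit.target_start, ltr3_end=off + hit.target_end,
        aligned_length=ungapped, mismatches=hit.mismatches,
        indel_columns=hit.gap_columns,
        identity=hit.identities / ungapped,
    )
    if pair.ltr3_start < pair.ltr5_end:  # windows overlapped and matched same span
        return None
    return pair


def orf_disruption_profile(seq: str, annotations: Sequence[GeneAnnotation] = ()) -> OrfDisruptionProfile:
    """Locate every ATG and stop codon in forward frames +1..+3.

    With gene annotations supplied, also counts premature stops inside each
    gene span (in the gene's own frame, excluding the terminal codon) and
    carries over frameshift evidence: a gene whose probe-alignment blocks sit
    in more than one frame was hit by an indel.
    """
    seq = seq.upper()
    stops: dict[int, list[int]] = {1: [], 2: [], 3: []}
    starts: dict[int, list[int]] = {1: [], 2: [], 3: []}
    codes = align.encode_dna(seq).astype(np.int32)
    if codes.size >= 3:
        # codon id = 16*b0 + 4*b1 + b2; invalid bases poison the codon
        c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
        ids = np.where((c0 < 4) & (c1 < 4) & (c2 < 4), 16 * c0 + 4 * c1 + c2, -1)
        stop_ids = [16 * 3 + 0 * 4 + 0, 16 * 3 + 0 * 4 + 2, 16 * 3 + 2 * 4 + 0]  # TAA TAG TGA
        atg_id = 16 * 0 + 4 * 3 + 2
        is_stop = np.isin(ids, stop_ids)
        is_start = ids == atg_id
        for frame in (1, 2, 3):
            idx = np.arange(frame - 1, ids.size, 3)
            stops[frame] = [int(i) for i in idx[is_stop[idx]]]
            starts[frame] = [int(i) for i in idx[is_start[idx]]]
    profile = OrfDisruptionProfile(stop_positions=stops, start_positions=starts)
    for ann in annotations:
        frame = ann.start % 3 + 1
        inframe = stops[frame]
        count = sum(1 for p in inframe if ann.start < p < ann.end - 3)
        profile.premature_stop_count[ann.gene] = count
        frames_seen = {f for _, _, f in ann.blocks}
        profile.frameshift_evidence[ann.gene] = len(frames_seen) > 1
    return profile


def _chain_gene_hits(hits, max_gap: int = 2000):
    """Chain filtered hits for one gene on one strand into the best span."""
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    chains = []
    cur = []
    for h in hits:
        if cur and h.start - max(x.end for x in cur) > max_gap:
            chains.append(cur)
            cur = []
        cur.append(h)
    if cur:
        chains.append(cur)
    return max(chains, key=lambda ch: sum(h.score for h in ch)) if chains else []


def annotate_coding_regions(seq: str, reference_proteins: dict[str, list[tuple[str, str]]],
                            max_e: float = 1e-3) -> list[GeneAnnotation]:
    """Locate each viral gene on a locus by chained translated alignment.

    ``reference_proteins`` maps a gene label to (probe_id, protein) probes.
    For each gene the best-scoring chain of local translated hits on one
    strand defines the span; genes with no hit at ``max_e`` are omitted —
    truncated or deleted genes simply do not appear. Overlapping claims
    between genes are resolved in favour of the higher-scoring one.
    """
    out: list[GeneAnnotation] = []
    for gene, probes in reference_proteins.items():
        ps = ProbeSet(probes, source_label=gene)
        hits = [h for h in translated_search(seq, ps, SearchParams(report_max_e=max_e))
                if h.e_value <= max_e]
        if not hits:
            continue
        by_strand = {}
        for h in hits:
            by_strand.setdefault(h.strand, []).append(h)
        strand = max(by_strand, key=lambda s: sum(h.score for h in by_strand[s]))
        chain = _chain_gene_hits(by_strand[strand])
        if not chain:
            continue
        total_cols = sum(h.end - h.start for h in chain)
        ident = sum(h.percent_identity * (h.end - h.start) for h in chain) / total_cols
        out.append(GeneAnnotation(
            gene=gene,
            start=min(h.start for h in chain), end=max(h.end for h in chain),
            strand=strand,
            best_probe_id=max(chain, key=lambda h: h.score).probe_id,
            identity=ident,
            score=sum(h.score for h in chain),
            blocks=[(h.start, h.end, h.frame) for h in chain],
        ))
    # resolve heavy overlaps by score
    out.sort(key=lambda a: -a.score)
    kept: list[GeneAnnotation] = []
    for ann in out:
        clash = False
        for k in kept:
            ov = min(ann.end, k.end) - max(ann.start, k.start)
            if ov > 0 and ov / (ann.end - ann.start) > 0.8:
                clash = True
                break
        if not clash:
            kept.append(ann)
    kept.sort(key=lambda a: a.start)
    return kept


def flag_repeat_artifacts(seq: str, min_len: int = 500, min_identity: float = 0.90,
                          max_adjacency_gap: int = 1000,
                          ltr_pair: LTRPair | None = None) -> list[ArtifactFlag]:
    """Flag adjacent near-identical internal repeats as likely assembly artifacts.

    Self-comparison by k-mer seeded blocks; a repeat pair is flagged when both
    copies are at least ``min_len`` long at ``min_identity``, and the copies
    sit within ``max_adjacency_gap`` of each other. The locus's own LTR pair
    — a biological repeat — is excluded.
    """
    blocks = align.kmer_homology_blocks(
        seq, seq, k=13, min_len=min_len, exclude_self_diagonal=True)
    flags: list[ArtifactFlag] = []
    for blk in blocks:
        if blk.identity < min_identity:
            continue
        gap = blk.b_start - blk.a_end
        if gap < 0 or gap > max_adjacency_gap:
            continue
        if ltr_pair is not None:
            if _overlaps(blk.a_span, ltr_pair.ltr5_span) and _overlaps(blk.b_span, ltr_pair.ltr3_span):
                continue
        flags.append(ArtifactFlag(
            source_span=blk.a_span, duplicate_span=blk.b_span,
            identity=blk.identity, adjacency_gap=gap,
        ))
    flags.sort(key=lambda f: f.source_span)
    return flags


def scan_motif(seq: str, motif: str = "TATAAAA") -> MotifScan:
    """Simple exact-motif scan (e.g. the foamy virus internal promoter).

    A negative result is reported as absence, mirroring heavily mutated
    elements in which such signals are no longer recognisable.
    """
    positions = []
    at = seq.upper().find(motif)
    while at != -1:
        positions.append(at)
        at = seq.find(motif, at + 1)
    return MotifScan(motif=motif, positions=positions)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return min(a[1], b[1]) > max(a[0], b[0])
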
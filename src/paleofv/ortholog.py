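"""Orthologous-insertion calling from flanking-sequence homology.

An endogenous retrovirus insertion shared by two species at the homologous
locus proves the integration predates their split (vertical transmission).
The test: extract the flanking sequence on each side of every candidate
locus (30,000 bp by default, clipped at contig ends with the truncation
recorded), find homologous blocks between the flanks of a cross-species
locus pair, discard blocks shorter than 500 bp (short-repeat noise), and
call the pair orthologous when the length-weighted block identity exceeds
90% AND the merged blocks cover more than 50% of the usable flank. Both
bounds are strict, and upstream/downstream flanks are pooled for both
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import align
from .align import DnaBlock
from .screen import ProviralLocus


class OrthologError(ValueError):
    pass


@dataclass
class Flanks:
    """Upstream/downstream flanking sequence of one locus (provirus excluded)."""

    locus_id: str
    genome_id: str
    upstream: str
    downstream: str
    upstream_truncated_by: int
    downstream_truncated_by: int

    @property
    def usable_length(self) -> int:
        return len(self.upstream) + len(self.downstream)


@dataclass
class HomologyBlock:
    """A filtered homologous block between two flanks (coordinates per side)."""

    side: str  # 'upstream' or 'downstream'
    a_span: tuple[int, int]
    b_span: tuple[int, int]
    identity: float
    length: int
    e_value: float


@dataclass
class OrthologCall:
    locus_a: str
    locus_b: str
    genome_a: str
    genome_b: str
    blocks: list[HomologyBlock] = field(default_factory=list)
    mean_identity: float = 0.0
    coverage: float = 0.0
    verdict: str = "not_orthologous"
    warning: str | None = None

    @property
    def is_orthologous(self) -> bool:
        return self.verdict == "orthologous"


def extract_flanks(genome: str, locus: ProviralLocus | tuple[int, int],
                   flank_len: int = 30_000, locus_id: str = "",
                   genome_id: str = "") -> Flanks:
    """Extract [start-flank_len, start) and [end, end+flank_len), clipped.

    Truncation at contig boundaries is recorded so coverage denominators can
    exclude sequence that does not exist.
    """
    if isinstance(locus, ProviralLocus):
        start, end = locus.start, locus.end
        locus_id = locus_id or locus.locus_id
        genome_id = genome_id or locus.genome_id
    else:
        start, end = locus
    if not (0 <= start < end <= len(genome)):
        raise OrthologError(f"locus ({start}, {end}) outside contig of length {len(genome)}")
    up_start = max(0, start - flank_len)
    down_end = min(len(genome), end + flank_len)
    return Flanks(
        locus_id=locus_id, genome_id=genome_id,
        upstream=genome[up_start:start],
        downstream=genome[end:down_end],
        upstream_truncated_by=flank_len - (start - up_start),
        downstream_truncated_by=flank_len - (down_end - end),
    )


def flank_homology_blocks(flank_a: str, flank_b: str, word_size: int = 11,
                          max_e: float = 1e-5, min_block: int = 500) -> list[DnaBlock]:
    """Homologous blocks between two flank sequences.

    Exact ``word_size``-mers are seeded, chained along diagonals and
    realigned; blocks shorter than ``min_block`` or weaker than ``max_e`` are
    excluded. Empty input yields an empty list.
    """
    if not flank_a or not flank_b:
        return []
    return align.kmer_homology_blocks(flank_a, flank_b, k=word_size,
                                      min_len=min_block, max_e=max_e)


def call_orthologous_insertion(flanks_a: Flanks, flanks_b: Flanks,
                               min_identity: float = 0.90, min_coverage: float = 0.50,
                               min_block: int = 500, max_e: float = 1e-5,
                               word_size: int = 11) -> OrthologCall:
    """Decide whether two loci are the same insertion event.

    Upstream flanks are compared with upstream, downstream with downstream;
    block identity is length-weighted, coverage is the merged block
    projection over the usable flank length (averaged over the two genomes so
    the call is symmetric under argument swap). Verdict is strict:
    identity > ``min_identity`` AND coverage > ``min_coverage``.
    """
    call = OrthologCall(locus_a=flanks_a.locus_id, locus_b=flanks_b.locus_id,
                        genome_a=flanks_a.genome_id, genome_b=flanks_b.genome_id)
    usable_a = flanks_a.usable_length
    usable_b = flanks_b.usable_length
    if usable_a == 0 or usable_b == 0:
        call.warning = "zero usable flank"
        return call
    blocks: list[HomologyBlock] = []
    cov_a: list[tuple[int, int]] = []
    cov_b: list[tuple[int, int]] = []
    for side in ("upstream", "downstream"):
        fa = getattr(flanks_a, side)
        fb = getattr(flanks_b, side)
        for blk in flank_homology_blocks(fa, fb, word_size=word_size,
                                         max_e=max_e, min_block=min_block):
            blocks.append(HomologyBlock(side=side, a_span=blk.a_span, b_span=blk.b_span,
                                        identity=blk.identity, length=blk.length,
                                        e_value=blk.e_value))
            off = 0 if side == "upstream" else len(flanks_a.upstream)
            offb = 0 if side == "upstream" else len(flanks_b.upstream)
            cov_a.append((off + blk.a_start, off + blk.a_end))
            cov_b.append((offb + blk.b_start, offb + blk.b_end))
    call.blocks = blocks
    if blocks:
        total = sum(b.length for b in blocks)
        call.mean_identity = sum(b.identity * b.length for b in blocks) / total
        c_a = min(1.0, align.covered_length(cov_a) / usable_a)
        c_b = min(1.0, align.covered_length(cov_b) / usable_b)
        call.coverage = 0.5 * (c_a + c_b)
    if call.mean_identity > min_identity and call.coverage > min_coverage:
        call.verdict = "orthologous"
    return call


@dataclass
class OrthologMatrix:
    calls: list[OrthologCall]
    mutual_pairs: list[tuple[str, str]]

    def call_for(self, locus_a: str, locus_b: str) -> OrthologCall | None:
        for c in self.calls:
            if {c.locus_a, c.locus_b} == {locus_a, locus_b}:
                return c
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "locus_a": c.locus_a, "locus_b": c.locus_b,
            "genome_a": c.genome_a, "genome_b": c.genome_b,
            "n_blocks": len(c.blocks), "mean_identity": c.mean_identity,
            "coverage": c.coverage, "verdict": c.verdict,
            "mutual": (c.locus_a, c.locus_b) in self.mutual_pairs,
        } for c in self.calls]
        return pd.DataFrame(rows)


def ortholog_matrix(loci_a: Sequence[ProviralLocus], loci_b: Sequence[ProviralLocus],
                    genome_a: str, genome_b: str, flank_len: int = 30_000,
                    min_identity: float = 0.90, min_coverage: float = 0.50,
                    min_block: int = 500) -> OrthologMatrix:
    """Evaluate every cross-genome locus pair and report mutual best orthologs.

    One-to-many conflicts are resolved by the highest coverage*identity
    product: a pair enters the ortholog set only when each locus is the
    other's best orthologous match.
    """
    fa = [extract_flanks(genome_a, l, flank_len) for l in loci_a]
    fb = [extract_flanks(genome_b, l, flank_len) for l in loci_b]
    calls = []
    score: dict[tuple[str, str], float] = {}
    for xa in fa:
        for xb in fb:
            call = call_orthologous_insertion(xa, xb, min_identity=min_identity,
                                              min_coverage=min_coverage,
                                              min_block=min_block)
            calls.append(call)
            score[(call.locus_a, call.locus_b)] = call.coverage * call.mean_identity

    def best_for_a(la: str) -> str | None:
        cands = [c for c in calls if c.locus_a == la and c.is_orthologous]
        return max(cands, key=lambda c: score[(c.locus_a, c.locus_b)]).locus_b if cands else None

    def best_for_b(lb: str) -> str | None:
        cands = [c for c in calls if c.locus_b == lb and c.is_orthologous]
        return max(cands, key=lambda c: score[(c.locus_a, c.locus_b)]).locus_a if cands else None

    mutual = []
    for la in sorted({c.locus_a for c in calls}):
        lb = best_for_a(la)
        if lb is not None and best_for_b(lb) == la:
            mutual.append((la, lb))
    return OrthologMatrix(calls=calls, mutual_pairs=mutual)


def export_synteny_map(calls: Sequence[OrthologCall]) -> pd.DataFrame:
    """One row per homology block: coordinates on both flanks plus identity.

    The table is sorted by (genome, locus, side, start) so downstream
    genome-comparison plotting tools receive a deterministic layout.
    """
    rows = []
    for c in calls:
        for b in c.blocks:
            rows.append({
                "genome_a": c.genome_a, "locus_a": c.locus_a,
                "side": b.side,
                "a_start": b.a_span[0], "a_end": b.a_span[1],
                "genome_b": c.genome_b, "locus_b": c.locus_b,
                "b_start": b.b_span[0], "b_end": b.b_span[1],
                "identity": b.identity,
            })
    df = pd.DataFrame(rows, columns=["genome_a", "locus_a", "side", "a_start", "a_end",
                                     "genome_b", "locus_b", "b_start", "b_end", "identity"])
    if len(df):
        df = df.sort_values(["genome_a", "locus_a", "side", "a_start"]).reset_index(drop=True)
    return df
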
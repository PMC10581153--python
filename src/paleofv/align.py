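"""Internal alignment engine shared by the screening, annotation and ortholog stages.

Three primitives live here:

* seeded Smith-Waterman protein-vs-peptide local alignment (BLOSUM62,
  affine gaps 11/1) with Karlin-Altschul e-values — the translated-search
  core;
* local DNA alignment for long-terminal-repeat (LTR) self-comparison;
* k-mer seeded, diagonal-chained DNA homology blocks for long flank
  comparison, with edlib-based identity refinement.

All coordinates are 0-based, half-open. Every function is deterministic for
fixed inputs. An adapter hook (`ExternalSearchAdapter`) lets a tabular
external search tool stand in for the internal aligner; the internal path is
the default and the one exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import math

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1), the
# standard tabulated values used by protein BLAST.
KA_PROT_LAMBDA = 0.267
KA_PROT_K = 0.041

# Ungapped nucleotide parameters for match +2 / mismatch -3 scoring.
KA_NT_LAMBDA = 0.625
KA_NT_K = 0.410

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i
    _NT_CODE[_b + 32] = _i  # lowercase


def encode_dna(seq: str) -> np.ndarray:
    """Map a DNA string onto uint8 codes (A,C,G,T -> 0..3; others -> 255)."""
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def protein_evalue(score: float, probe_len: int, space_len: int) -> float:
    """Karlin-Altschul e-value for a gapped BLOSUM62 local alignment score."""
    return KA_PROT_K * probe_len * space_len * math.exp(-KA_PROT_LAMBDA * score)


def min_score_for_evalue(max_e: float, probe_len: int, space_len: int) -> float:
    return math.log(KA_PROT_K * probe_len * space_len / max_e) / KA_PROT_LAMBDA


def nt_evalue(score: float, m: int, n: int) -> float:
    try:
        return KA_NT_K * m * n * math.exp(-KA_NT_LAMBDA * score)
    except OverflowError:
        return 0.0 if score > 0 else math.inf


@dataclass
class LocalHit:
    """A local alignment between a query (probe) and a target sequence.

    Coordinates are half-open on the respective sequences. ``identities`` and
    ``mismatches`` count ungapped columns only; ``columns`` is the total
    alignment length including gap columns.
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    score: float
    identities: int
    mismatches: int
    gap_columns: int
    columns: int

    @property
    def identity(self) -> float:
        return self.identities / self.columns if self.columns else 0.0


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _dna_aligner(match: float = 2.0, mismatch: float = -3.0,
                 gap_open: float = -5.0, gap_extend: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _hit_from_alignment(aln, query: str, target: str) -> LocalHit:
    qblocks, tblocks = aln.aligned  # align(query, target): first axis is query
    identities = 0
    mismatches = 0
    aligned = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        qa = query[qs:qe]
        ta = target[ts:te]
        same = sum(1 for x, y in zip(qa, ta) if x == y)
        identities += same
        mismatches += (qe - qs) - same
        aligned += qe - qs
    qs0, qe1 = int(qblocks[0][0]), int(qblocks[-1][1])
    ts0, te1 = int(tblocks[0][0]), int(tblocks[-1][1])
    gap_columns = (qe1 - qs0 - aligned) + (te1 - ts0 - aligned)
    return LocalHit(
        query_start=qs0,
        query_end=qe1,
        target_start=ts0,
        target_end=te1,
        score=float(aln.score),
        identities=identities,
        mismatches=mismatches,
        gap_columns=gap_columns,
        columns=aligned + gap_columns,
    )


def local_protein_hits(probe: str, peptide: str, min_score: float,
                       max_hits: int = 8) -> Iterator[LocalHit]:
    """Yield successive non-overlapping local alignments of probe vs peptide.

    After each reported hit the matched target span is masked with ``X`` and
    the search repeats, BLAST-style, until the score drops below
    ``min_score`` or ``max_hits`` is reached.
    """
    if not probe or not peptide:
        return
    aligner = _protein_aligner()
    work = peptide
    for _ in range(max_hits):
        alignments = aligner.align(probe, work)
        try:
            best = alignments[0]
        except IndexError:
            return
        if best.score < min_score or len(best.aligned[0]) == 0:
            return
        hit = _hit_from_alignment(best, probe, work)
        yield hit
        work = work[: hit.target_start] + "X" * (hit.target_end - hit.target_start) + work[hit.target_end :]


def _columns_from_alignment(aln) -> list[tuple[int | None, int | None]]:
    """Alignment as explicit columns of (query index | None, target index | None)."""
    qblocks, tblocks = aln.aligned
    cols: list[tuple[int | None, int | None]] = []
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        if prev_q is not None:
            for q in range(prev_q, qs):
                cols.append((q, None))
            for t in range(prev_t, ts):
                cols.append((None, t))
        for q, t in zip(range(qs, qe), range(ts, te)):
            cols.append((q, t))
        prev_q, prev_t = qe, te
    return cols


def _max_scoring_segment(scores: Sequence[float]) -> tuple[int, int]:
    """Kadane's algorithm: half-open index range of the maximal-sum segment."""
    best = cur = 0.0
    best_range = (0, 0)
    start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur, start = s, i
        else:
            cur += s
        if cur > best:
            best = cur
            best_range = (start, i + 1)
    return best_range


def local_dna_alignment(a: str, b: str, trim_ends: bool = False) -> LocalHit | None:
    """Best local DNA alignment (match +2 / mismatch -3 / gaps 5,2), or None.

    With ``trim_ends`` the alignment is re-trimmed to its maximal-scoring
    column segment under match +1 / mismatch or gap -2, which removes weak
    chance extensions beyond a repeat boundary that affine local alignment
    sometimes keeps.
    """
    if not a or not b:
        return None
    aligner = _dna_aligner()
    alignments = aligner.align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if len(best.aligned[0]) == 0:
        return None
    if not trim_ends:
        return _hit_from_alignment(best, a, b)
    cols = _columns_from_alignment(best)
    scores = [1.0 if (q is not None and t is not None and a[q] == b[t]) else -2.0
              for q, t in cols]
    lo, hi = _max_scoring_segment(scores)
    cols = cols[lo:hi]
    if not cols:
        return None
    identities = mismatches = gap_columns = 0
    for q, t in cols:
        if q is None or t is None:
            gap_columns += 1
        elif a[q] == b[t]:
            identities += 1
        else:
            mismatches += 1
    qidx = [q for q, _ in cols if q is not None]
    tidx = [t for _, t in cols if t is not None]
    return LocalHit(
        query_start=qidx[0], query_end=qidx[-1] + 1,
        target_start=tidx[0], target_end=tidx[-1] + 1,
        score=float(best.score), identities=identities, mismatches=mismatches,
        gap_columns=gap_columns, columns=len(cols),
    )


# ---------------------------------------------------------------------------
# k-mer seeded DNA homology blocks
# ---------------------------------------------------------------------------


@dataclass
class DnaBlock:
    """An homologous block between two DNA sequences.

    ``a_span``/``b_span`` are half-open intervals on the two inputs;
    ``length`` is the alignment length (gap columns included), identity is
    matches over alignment length.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identities: int
    length: int
    score: float
    e_value: float

    @property
    def identity(self) -> float:
        return self.identities / self.length if self.length else 0.0

    @property
    def a_span(self) -> tuple[int, int]:
        return (self.a_start, self.a_end)

    @property
    def b_span(self) -> tuple[int, int]:
        return (self.b_start, self.b_end)


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where the window holds a non-ACGT base."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    vals = codes.astype(np.int64).copy()
    vals[~valid] = 0
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    pows = (4 ** np.arange(k, dtype=np.int64))[::-1]
    out = win @ pows
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    out[~ok] = -1
    return out


def edlib_identity(a: str, b: str) -> tuple[int, int]:
    """(matches, alignment_length) of a global alignment of two DNA strings."""
    if not a or not b:
        return 0, max(len(a), len(b))
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    matched = nice["matched_aligned"]
    return matched.count("|"), len(matched)


def kmer_homology_blocks(
    a: str,
    b: str,
    k: int = 11,
    chain_gap: int = 200,
    diag_band: int = 16,
    min_len: int = 100,
    max_e: float = 1e-5,
    max_kmer_occ: int = 12,
    exclude_self_diagonal: bool = False,
) -> list[DnaBlock]:
    """Find homologous blocks between two DNA sequences by seed-and-chain.

    Exact k-mer matches are grouped by diagonal (within ``diag_band`` to
    tolerate short indels) and chained when consecutive seeds on the a-axis
    are at most ``chain_gap`` apart. Each chain's spanned substrings are
    realigned globally with edlib to obtain identity, and chains shorter than
    ``min_len`` or weaker than ``max_e`` are dropped. With
    ``exclude_self_diagonal`` the trivial a==b main diagonal is ignored
    (self-comparison mode); mirror-image duplicate chains are also collapsed
    so each repeat pair is reported once, with a_start <= b_start.
    """
    if not a or not b:
        return []
    ca, cb = encode_dna(a), encode_dna(b)
    ka = _kmer_codes(ca, k)
    kb = _kmer_codes(cb, k)
    if ka.size == 0 or kb.size == 0:
        return []

    index: dict[int, list[int]] = {}
    for pos, code in enumerate(ka):
        if code < 0:
            continue
        bucket = index.setdefault(int(code), [])
        if len(bucket) < max_kmer_occ:
            bucket.append(pos)

    matches: list[tuple[int, int]] = []
    for bpos, code in enumerate(kb):
        if code < 0:
            continue
        for apos in index.get(int(code), ()):
            if exclude_self_diagonal and abs(apos - bpos) < k:
                continue
            matches.append((apos, bpos))
    if not matches:
        return []
    matches.sort()

    # Greedy chaining over active chains.
    chains: list[dict] = []
    active: list[dict] = []
    for apos, bpos in matches:
        diag = bpos - apos
        placed = None
        for ch in active:
            if apos - ch["a_last"] > chain_gap:
                continue
            if abs(diag - ch["diag"]) <= diag_band and bpos > ch["b_last"] - k:
                placed = ch
                break
        if placed is None:
            placed = {
                "a_first": apos, "b_first": bpos,
                "a_last": apos, "b_last": bpos, "diag": diag,
            }
            chains.append(placed)
            active.append(placed)
        else:
            placed["a_last"] = apos
            placed["b_last"] = bpos
            placed["diag"] = diag
        active = [ch for ch in active if apos - ch["a_last"] <= chain_gap]

    blocks: list[DnaBlock] = []
    seen: set[tuple[int, int, int, int]] = set()
    for ch in chains:
        a_start, a_end = ch["a_first"], ch["a_last"] + k
        b_start, b_end = ch["b_first"], ch["b_last"] + k
        if min(a_end - a_start, b_end - b_start) < min_len:
            continue
        if exclude_self_diagonal:
            # report each repeat pair once, lower coordinate first
            if a_start > b_start:
                a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
            key = (a_start, a_end, b_start, b_end)
            if key in seen:
                continue
            seen.add(key)
            overlap = min(a_end, b_end) - max(a_start, b_start)
            if overlap >= k:  # substantially self-overlapping (tandem array core)
                continue
            if overlap > 0:  # junction k-mer leaked across the copy boundary; trim
                a_end -= overlap
                b_end -= overlap
                if min(a_end - a_start, b_end - b_start) < min_len:
                    continue
        ident, length = edlib_identity(a[a_start:a_end], b[b_start:b_end])
        mismatch_and_gap = length - ident
        score = 2.0 * ident - 3.0 * mismatch_and_gap
        e = nt_evalue(score, len(a), len(b))
        if e > max_e:
            continue
        blocks.append(DnaBlock(a_start, a_end, b_start, b_end, ident, length, score, e))
    blocks.sort(key=lambda blk: (blk.a_start, blk.b_start))
    return blocks


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and coalesced."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def covered_length(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


# Adapter surface: an external translated-search or megablast executable can
# be plugged in by supplying a callable returning pre-parsed rows; see
# screen.translated_search for how rows map onto HomologyHit.
ExternalSearchAdapter = Callable[[str, Sequence[tuple[str, str]]], "list"]
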
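"""Translated-homology screening of genome sequence for endogenous viral loci.

Mirrors a tBLASTn-style survey: every probe protein is aligned locally
(BLOSUM62, affine gaps) against all six reading frames of the genome,
significant hits are filtered on identity / probe coverage / e-value, nearby
hits are chained into candidate proviral loci, and loci are grouped into
viral lineages by pairwise nucleotide identity (a distance-based stand-in
for phylogenetic confirmation).

The significance filter defaults to 40% identity, 40% probe coverage and
e <= 1e-5, with inclusive bounds. "Coverage" is the fraction of the PROBE
spanned by the alignment; the alternative reading (fraction of the genomic
hit region) is not offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from . import align
from .align import LocalHit

VALID_NT = set("ACGTNacgtn")
_AA_OK = set("ACDEFGHIKLMNPQRSTVWYX*BZ")


class ScreenError(ValueError):
    pass


@dataclass
class ProbeSet:
    """Probe proteins used to interrogate the genome (e.g. foamy virus POL)."""

    entries: list[tuple[str, str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for pid, seq in self.entries:
            if not seq:
                raise ScreenError(f"probe {pid!r} is empty")
            bad = set(seq.upper()) - _AA_OK
            if bad:
                raise ScreenError(f"probe {pid!r} has non-amino-acid characters {bad}")
        self.entries = [(pid, seq.upper()) for pid, seq in self.entries]

    @classmethod
    def from_fasta(cls, path: str | Path, source_label: str = "") -> "ProbeSet":
        entries = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not entries:
            raise ScreenError(f"no probes found in {path}")
        return cls(entries, source_label or str(path))


@dataclass
class HomologyHit:
    """One translated local alignment mapped back onto genome coordinates."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int  # 1..3 on the reported strand
    probe_id: str
    percent_identity: float  # fraction in [0, 1]
    probe_coverage: float  # fraction of probe aligned, in [0, 1]
    score: float
    e_value: float
    probe_start: int = 0
    probe_end: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ScreenError("hit start must precede end")


@dataclass
class ProviralLocus:
    locus_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    supporting_hits: list[HomologyHit] = field(default_factory=list)
    lineage: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SearchParams:
    report_max_e: float = 1e-3  # hits weaker than this are never materialised
    max_hits_per_frame: int = 8


# ---------------------------------------------------------------------------


def six_frame_translate(dna: str) -> list[tuple[str, int, str]]:
    """All six conceptual translations of a DNA string.

    Returns ``(strand, frame, peptide)`` for strand in '+'/'-' and frame
    1..3. Codons containing N translate to X; trailing partial codons are
    dropped. Raises on characters outside {A,C,G,T,N}.
    """
    bad = set(dna) - VALID_NT
    if bad:
        raise ScreenError(f"non-nucleotide characters in sequence: {sorted(bad)[:5]}")
    seq = dna.upper()
    rc = str(Seq(seq).reverse_complement())
    out = []
    for strand, s in (("+", seq), ("-", rc)):
        for frame in (1, 2, 3):
            sub = s[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            out.append((strand, frame, pep))
    return out


def _map_hit_to_genome(hit: LocalHit, strand: str, frame: int, genome_len: int) -> tuple[int, int]:
    """Genome-coordinate span of a peptide-coordinate local hit."""
    offset = frame - 1
    nt_start = offset + 3 * hit.target_start
    nt_end = offset + 3 * hit.target_end
    if strand == "+":
        return nt_start, nt_end
    return genome_len - nt_end, genome_len - nt_start


def translated_search(genome: str, probes: ProbeSet, params: SearchParams | None = None,
                      genome_id: str = "genome", contig_id: str = "chr1") -> list[HomologyHit]:
    """Six-frame local protein search of ``probes`` against ``genome``.

    Hits with e-value above ``params.report_max_e`` are not reported; apply
    :func:`filter_hits` for the significance filter proper. Deterministic for
    fixed inputs. An empty genome yields an empty list.
    """
    params = params or SearchParams()
    if not genome:
        return []
    frames = six_frame_translate(genome)
    space = sum(len(pep) for _, _, pep in frames)
    hits: list[HomologyHit] = []
    for probe_id, probe in probes.entries:
        min_score = align.min_score_for_evalue(params.report_max_e, len(probe), space)
        for strand, frame, pep in frames:
            if not pep:
                continue
            for lh in align.local_protein_hits(probe, pep, min_score,
                                               max_hits=params.max_hits_per_frame):
                e = align.protein_evalue(lh.score, len(probe), space)
                if e > params.report_max_e:
                    continue
                gstart, gend = _map_hit_to_genome(lh, strand, frame, len(genome))
                hits.append(HomologyHit(
                    genome_id=genome_id, contig_id=contig_id,
                    start=gstart, end=gend, strand=strand, frame=frame,
                    probe_id=probe_id,
                    percent_identity=lh.identity,
                    probe_coverage=(lh.query_end - lh.query_start) / len(probe),
                    score=lh.score, e_value=e,
                    probe_start=lh.query_start, probe_end=lh.query_end,
                ))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end, h.probe_id, h.strand, h.frame))
    return hits


def filter_hits(hits: Iterable[HomologyHit], min_identity: float = 0.40,
                min_coverage: float = 0.40, max_e: float = 1e-5) -> list[HomologyHit]:
    """Apply the significance filter (inclusive bounds), preserving order."""
    if not 0 <= min_identity <= 1 or not 0 <= min_coverage <= 1 or max_e < 0:
        raise ScreenError("filter thresholds out of range")
    return [h for h in hits
            if h.percent_identity >= min_identity
            and h.probe_coverage >= min_coverage
            and h.e_value <= max_e]


def merge_hits_to_loci(hits: Sequence[HomologyHit], max_gap_bp: int = 5000) -> list[ProviralLocus]:
    """Chain same-contig, same-strand hits within ``max_gap_bp`` into loci.

    The chaining gap bridges degraded internal provirus regions without
    fusing independent neighbouring insertions. Locus ids are assigned by
    (contig, start) so the operation is deterministic and idempotent.
    """
    groups: dict[tuple[str, str, str], list[HomologyHit]] = {}
    for h in hits:
        groups.setdefault((h.genome_id, h.contig_id, h.strand), []).append(h)
    loci: list[ProviralLocus] = []
    for (gid, contig, strand), hs in groups.items():
        hs = sorted(hs, key=lambda h: (h.start, h.end))
        cur: list[HomologyHit] = []
        cur_end = None
        for h in hs:
            if cur and h.start - cur_end > max_gap_bp:
                loci.append(ProviralLocus("", gid, contig, cur[0].start,
                                          max(x.end for x in cur), strand, cur))
                cur = []
            cur.append(h)
            cur_end = max(x.end for x in cur)
        if cur:
            loci.append(ProviralLocus("", gid, contig, cur[0].start,
                                      max(x.end for x in cur), strand, cur))
    loci.sort(key=lambda l: (l.contig_id, l.start, l.end, l.strand))
    for i, loc in enumerate(loci):
        loc.locus_id = f"locus_{i + 1:04d}"
    return loci


def locus_sequence(genome: str, locus: ProviralLocus) -> str:
    return genome[locus.start : locus.end]


def cluster_lineages(loci: Sequence[ProviralLocus], genome_seqs: dict[str, str],
                     identity_threshold: float = 0.80) -> dict[str, str]:
    """Group loci into viral lineages by pairwise nucleotide identity.

    Single-linkage clustering at ``identity_threshold``: identity is computed
    as matches over global-alignment length between locus sequences. Labels
    'a', 'b', ... are assigned by descending cluster size, ties broken by the
    (contig, start) of each cluster's first locus. A distance-based stand-in
    for the maximum-likelihood phylogeny used to confirm candidate loci.
    """
    if not loci:
        raise ScreenError("cluster_lineages needs at least one locus")
    n = len(loci)
    seqs = [locus_sequence(genome_seqs[l.genome_id], l) for l in loci]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            matches, length = align.edlib_identity(seqs[i], seqs[j])
            if length and matches / length >= identity_threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    orderkey = lambda members: (-len(members), min(
        (loci[i].contig_id, loci[i].start) for i in members))
    labels = {}
    for rank, members in enumerate(sorted(clusters.values(), key=orderkey)):
        label = chr(ord("a") + rank) if rank < 26 else f"z{rank}"
        for i in members:
            labels[loci[i].locus_id] = label
            loci[i].lineage = label
    return labels
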
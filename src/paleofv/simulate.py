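"""Synthetic host genomes carrying proviruses with known ground truth.

The simulator emulates the history that endogenous-retrovirus mining assumes:
a neutral host genome; proviruses with the canonical LTR-gag-pol-env-LTR
layout integrated at known times with a target-site duplication (TSD);
Jukes-Cantor (JC69) substitution at a fixed per-site per-year rate, so a
provirus integrated T years ago accumulates an LTR-LTR divergence of about
2*R*T; a host speciation event splitting one ancestor into two descendant
genomes, making pre-split insertions orthologous (shared flanking sequence)
and post-split insertions lineage-specific; post-insertion decay (premature
stop codons, +/-1 frameshifts); and optional tandem-duplication artifacts of
the kind genome assemblers produce.

Coordinates are 0-based, half-open everywhere. All randomness flows through
``numpy.random.Generator`` objects seeded from a single config seed, and any
call is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Data import CodonTable

from .align import encode_dna

_BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

_table = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _table.forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aas in _AA_TO_CODONS.values():
    _aas.sort()
AMINO_ACIDS = "".join(sorted(_AA_TO_CODONS))  # 20 standard residues


class SimulationError(ValueError):
    """Invalid simulator configuration or operation."""


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class InsertionEvent:
    """One germ-line integration: when, which provirus template, which lineage.

    ``lineage`` is None for pre-split (ancestral) events; post-split events
    must name one of the two descendant genomes.
    """

    time_years: float
    template_id: str
    lineage: str | None = None


@dataclass
class SimConfig:
    genome_length: int = 200_000
    gc_content: float = 0.42
    sub_rate: float = 1.5e-9  # substitutions / site / year (R)
    split_time_years: float = 2.8e6
    insertion_events: list[InsertionEvent] = field(default_factory=list)
    ltr_length: int = 400
    tsd_length: int = 4
    decay_stop_rate: float = 1.0  # expected premature stops per kb of CDS
    decay_frameshift_rate: float = 0.0  # expected +/-1 frameshifts per kb of CDS
    indel_rate: float = 0.0  # neutral indel events / site / year (off by default)
    artifact_dup_prob: float = 0.0
    seed: int = 0
    genome_ids: tuple[str, str] = ("genomeA", "genomeB")
    min_locus_spacing: int = 20_000

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise SimulationError("genome_length must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise SimulationError("gc_content must lie strictly between 0 and 1")
        for name in ("sub_rate", "decay_stop_rate", "decay_frameshift_rate",
                     "indel_rate", "split_time_years"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if not 0.0 <= self.artifact_dup_prob <= 1.0:
            raise SimulationError("artifact_dup_prob must be a probability")
        if self.ltr_length < 50:
            raise SimulationError("ltr_length must be >= 50")
        if self.tsd_length < 0:
            raise SimulationError("tsd_length must be non-negative")
        for ev in self.insertion_events:
            if ev.time_years < 0:
                raise SimulationError("insertion times must be non-negative")
            if ev.time_years > self.split_time_years and ev.lineage is not None:
                raise SimulationError(
                    f"pre-split event at {ev.time_years} cannot name lineage {ev.lineage}")
            if ev.time_years <= self.split_time_years and ev.lineage is not None \
                    and ev.lineage not in self.genome_ids:
                raise SimulationError(f"unknown lineage {ev.lineage!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["genome_ids"] = list(self.genome_ids)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class LocusTruth:
    """Ground truth for one planted provirus (0-based, half-open coordinates)."""

    genome_id: str
    locus_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    time_years: float
    template_id: str
    partner_id: str | None
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    tsd_length: int
    gene_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_stop_positions: list[int] = field(default_factory=list)
    planted_frameshift_positions: list[int] = field(default_factory=list)
    artifact_duplication_span: tuple[int, int, int, int] | None = None  # src s,e + dup s,e

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SimResult:
    config: SimConfig
    genomes: dict[str, str]
    truth: dict[str, list[LocusTruth]]
    templates: dict[str, "ProvirusTemplate"]

    def loci(self, genome_id: str) -> list[LocusTruth]:
        return self.truth[genome_id]


# ---------------------------------------------------------------------------
# provirus templates
# ---------------------------------------------------------------------------


@dataclass
class ProvirusTemplate:
    """Protein templates for one viral lineage, in genomic gene order."""

    template_id: str
    proteins: dict[str, str]  # gene -> amino-acid sequence (starts with M)


def random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return "M" + body


# Gene lengths loosely follow exogenous foamy virus proportions (gag ~ 650,
# pol ~ 1150, env ~ 990 aa) at reduced scale so test genomes stay small.
_DEFAULT_GENE_LENGTHS = {"gag": 440, "pol": 760, "env": 620, "acc1": 210, "acc2": 110}


def default_templates(seed: int = 7, gene_lengths: dict[str, int] | None = None,
                      ids: tuple[str, ...] = ("fv_a", "fv_b")) -> dict[str, ProvirusTemplate]:
    """Two unrelated provirus templates, one per simulated viral lineage."""
    lengths = gene_lengths or _DEFAULT_GENE_LENGTHS
    rng = np.random.default_rng(seed)
    out = {}
    for tid in ids:
        proteins = {gene: random_protein(n, rng) for gene, n in lengths.items()}
        out[tid] = ProvirusTemplate(tid, proteins)
    return out


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """DNA coding sequence for a protein: ATG..., uniform synonymous codons, one stop."""
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS.get(aa)
        if options is None:
            raise SimulationError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


def mutate_protein(protein: str, identity: float, rng: np.random.Generator) -> str:
    """Degrade a protein to approximately the requested amino-acid identity.

    Mutated positions are spread evenly along the sequence and replacements
    are drawn from residues with negative BLOSUM62 score against the
    original, so local alignment identity tracks the planted fraction instead
    of being rescued by conservative substitutions.
    """
    from Bio.Align import substitution_matrices

    if not 0.0 <= identity <= 1.0:
        raise SimulationError("identity must be in [0, 1]")
    mat = substitution_matrices.load("BLOSUM62")
    n_mut = int(round((1.0 - identity) * len(protein)))
    if n_mut == 0:
        return protein
    positions = np.unique(np.round(np.linspace(0, len(protein) - 1, n_mut)).astype(int))
    out = list(protein)
    for pos in positions:
        orig = out[pos]
        bad = [aa for aa in AMINO_ACIDS if aa != orig and mat[orig][aa] < 0]
        out[pos] = bad[rng.integers(len(bad))]
    return "".join(out)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def random_genome(length: int, gc_content: float, rng: np.random.Generator) -> str:
    if length <= 0:
        raise SimulationError("genome_length must be positive")
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    draws = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(_BASES[i] for i in draws)


def simulate_ancestor(cfg: SimConfig) -> tuple[str, dict[str, list[LocusTruth]]]:
    """An i.i.d. ancestral genome at the configured GC content, no insertions yet."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    return random_genome(cfg.genome_length, cfg.gc_content, rng), {}


@dataclass
class ProvirusLayout:
    """Internal structure of a built provirus (coordinates relative to its start)."""

    length: int
    ltr_length: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    genes: dict[str, tuple[int, int]]


def build_provirus(template: ProvirusTemplate, ltr_length: int,
                   rng: np.random.Generator) -> tuple[str, ProvirusLayout]:
    """LTR + reverse-translated gene cassette + identical LTR."""
    if not template.proteins:
        raise SimulationError("provirus template has no proteins")
    if ltr_length < 50:
        raise SimulationError("ltr_length must be >= 50")
    ltr = random_genome(ltr_length, 0.5, rng)
    parts = [ltr, random_genome(50, 0.5, rng)]
    genes: dict[str, tuple[int, int]] = {}
    offset = ltr_length + 50
    for gene, protein in template.proteins.items():
        cds = reverse_translate(protein, rng)
        genes[gene] = (offset, offset + len(cds))
        parts.append(cds)
        offset += len(cds)
        spacer = random_genome(20, 0.5, rng)
        parts.append(spacer)
        offset += len(spacer)
    parts.append(random_genome(30, 0.5, rng))
    offset += 30
    parts.append(ltr)
    total = offset + ltr_length
    layout = ProvirusLayout(
        length=total, ltr_length=ltr_length,
        ltr5=(0, ltr_length), ltr3=(offset, total), genes=genes,
    )
    return "".join(parts), layout


def insert_provirus(genome: str, provirus: str, position: int,
                    tsd_length: int = 4) -> tuple[str, tuple[int, int]]:
    """Integrate a provirus with a target-site duplication.

    Returns the new genome and the provirus span (TSD copies excluded). The
    ``tsd_length`` bases starting at ``position`` are duplicated so they flank
    both LTRs, as retroviral integration does.
    """
    if not 0 <= position <= len(genome) - tsd_length:
        raise SimulationError(f"insertion position {position} out of range")
    new = genome[: position + tsd_length] + provirus + genome[position:]
    span = (position + tsd_length, position + tsd_length + len(provirus))
    return new, span


def excise_provirus(genome: str, span: tuple[int, int], tsd_length: int) -> str:
    """Inverse of insert_provirus: remove the provirus and one TSD copy."""
    start, end = span
    return genome[: start - tsd_length] + genome[end:]


def evolve(sequence: str, rate: float, years: float,
           rng: np.random.Generator | int, model: str = "JC69") -> str:
    """Neutral substitution over ``years`` at per-site per-year ``rate`` (JC69).

    Each site changes to a specific other base with probability
    (1/4)(1 - exp(-4*mu*t/3)), the exact JC69 transition probability, so the
    expected p-distance to the input is (3/4)(1 - exp(-4*mu*t/3)).
    """
    if model != "JC69":
        raise SimulationError(f"unsupported substitution model {model!r}")
    if years < 0 or rate < 0:
        raise SimulationError("rate and years must be non-negative")
    d = rate * years
    if d > 0.75:
        raise SimulationError(f"rate*years = {d:.3g} exceeds the sub-saturation bound 0.75")
    if d == 0 or not sequence:
        return sequence
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    codes = encode_dna(sequence).copy()
    hit = rng.random(codes.size) < p_change
    hit &= codes < 4  # leave non-ACGT untouched
    n = int(hit.sum())
    if n:
        codes[hit] = (codes[hit] + 1 + rng.integers(0, 3, size=n).astype(np.uint8)) % 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    valid = codes < 4
    out[valid] = lut[codes[valid]]
    return out.tobytes().decode("ascii")


# --- coordinate bookkeeping -------------------------------------------------


def _shift_point(x: int, pos: int, delta: int, is_end: bool) -> int:
    if delta > 0:  # insertion of delta bases at index pos
        if (x > pos) or (x >= pos and not is_end):
            return x + delta
        return x
    # deletion of -delta bases at index pos
    return x + delta if x > pos else x


def _shift_locus(loc: LocusTruth, pos: int, delta: int) -> None:
    loc.start = _shift_point(loc.start, pos, delta, False)
    loc.end = _shift_point(loc.end, pos, delta, True)
    loc.ltr5_start = _shift_point(loc.ltr5_start, pos, delta, False)
    loc.ltr5_end = _shift_point(loc.ltr5_end, pos, delta, True)
    loc.ltr3_start = _shift_point(loc.ltr3_start, pos, delta, False)
    loc.ltr3_end = _shift_point(loc.ltr3_end, pos, delta, True)
    loc.gene_spans = {
        g: (_shift_point(s, pos, delta, False), _shift_point(e, pos, delta, True))
        for g, (s, e) in loc.gene_spans.items()
    }
    loc.planted_stop_positions = [
        _shift_point(p, pos, delta, False) for p in loc.planted_stop_positions]
    loc.planted_frameshift_positions = [
        _shift_point(p, pos, delta, False) for p in loc.planted_frameshift_positions]
    if loc.artifact_duplication_span is not None:
        s1, e1, s2, e2 = loc.artifact_duplication_span
        loc.artifact_duplication_span = (
            _shift_point(s1, pos, delta, False), _shift_point(e1, pos, delta, True),
            _shift_point(s2, pos, delta, False), _shift_point(e2, pos, delta, True))


def _shift_all(loci: list[LocusTruth], pos: int, delta: int) -> None:
    for loc in loci:
        _shift_locus(loc, pos, delta)


# --- decay and artifacts ----------------------------------------------------


def degrade_provirus(genome: str, loci: list[LocusTruth], decay_stop_rate: float,
                     artifact_dup_prob: float, rng: np.random.Generator | int,
                     decay_frameshift_rate: float = 0.0) -> str:
    """Plant premature stops, frameshifts and tandem-duplication artifacts.

    ``decay_stop_rate`` and ``decay_frameshift_rate`` are expected events per
    kb of coding sequence; ``artifact_dup_prob`` is the per-locus probability
    of one adjacent tandem duplication of an internal fragment (> 500 bp),
    emulating an assembly error. Truth coordinates in ``loci`` are updated in
    place; the (possibly longer) genome is returned.
    """
    if decay_stop_rate < 0 or decay_frameshift_rate < 0:
        raise SimulationError("decay rates must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    for loc in sorted(loci, key=lambda l: l.start):
        # premature stop codons, codon-aligned within each gene
        for gene, (gs, ge) in loc.gene_spans.items():
            n_codons = (ge - gs) // 3
            if n_codons < 4:
                continue
            lam = decay_stop_rate * (ge - gs) / 1000.0
            for _ in range(rng.poisson(lam)):
                ci = int(rng.integers(1, n_codons - 1))
                pos = gs + 3 * ci
                stop = STOP_CODONS[rng.integers(3)]
                genome = genome[:pos] + stop + genome[pos + 3 :]
                loc.planted_stop_positions.append(pos)
            lam_fs = decay_frameshift_rate * (ge - gs) / 1000.0
            for _ in range(rng.poisson(lam_fs)):
                pos = int(rng.integers(gs + 3, ge - 3))
                if rng.random() < 0.5:
                    genome = genome[:pos] + genome[pos + 1 :]
                    _shift_all(loci, pos, -1)
                else:
                    base = _BASES[rng.integers(4)]
                    genome = genome[:pos] + base + genome[pos:]
                    _shift_all(loci, pos, +1)
                loc.planted_frameshift_positions.append(pos)
        if artifact_dup_prob > 0 and rng.random() < artifact_dup_prob:
            inner_start, inner_end = loc.ltr5_end, loc.ltr3_start
            max_len = min(1500, inner_end - inner_start - 10)
            if max_len > 500:
                frag_len = int(rng.integers(501, max_len + 1))
                src_start = int(rng.integers(inner_start, inner_end - frag_len + 1))
                src_end = src_start + frag_len
                frag = genome[src_start:src_end]
                genome = genome[:src_end] + frag + genome[src_end:]
                _shift_all(loci, src_end, frag_len)
                loc.artifact_duplication_span = (src_start, src_end, src_end, src_end + frag_len)
    return genome


# ---------------------------------------------------------------------------
# cohort simulation: ancestor -> insertions -> speciation -> decay
# ---------------------------------------------------------------------------


def _sample_position(rng: np.random.Generator, genome_len: int,
                     occupied: list[tuple[int, int]], spacing: int) -> int:
    margin = min(spacing, genome_len // 4)
    lo, hi = margin, max(margin + 1, genome_len - margin)
    for _ in range(2000):
        pos = int(rng.integers(lo, hi))
        if all(pos < s - spacing or pos > e + spacing for s, e in occupied):
            return pos
    raise SimulationError("could not place insertion: genome too crowded for min_locus_spacing")


def simulate_cohort(cfg: SimConfig,
                    templates: dict[str, ProvirusTemplate] | None = None) -> SimResult:
    """Run the full two-genome scenario encoded in ``cfg``.

    Events older than ``split_time_years`` are applied to the common ancestor
    (their descendant copies are orthologous, truth partners filled in both
    directions); younger events go to one named lineage. The genome evolves
    between events under JC69 at ``sub_rate``, each descendant evolves
    independently after the split, and decay/artifact plumbing runs last so
    duplicated fragments stay near-identical, as assembly artifacts are.
    """
    cfg.validate()
    if templates is None:
        templates = default_templates(seed=cfg.seed + 101)
    for ev in cfg.insertion_events:
        if ev.template_id not in templates:
            raise SimulationError(f"unknown provirus template {ev.template_id!r}")

    rng = np.random.default_rng(cfg.seed)
    genome = random_genome(cfg.genome_length, cfg.gc_content, rng)

    pre = sorted((ev for ev in cfg.insertion_events if ev.time_years > cfg.split_time_years),
                 key=lambda ev: -ev.time_years)
    post = [ev for ev in cfg.insertion_events if ev.time_years <= cfg.split_time_years]

    # One nucleotide sequence per viral lineage: every insertion of a template
    # is a copy of the same provirus genome (as retroviral copies are), so
    # same-lineage loci stay clusterable at the nucleotide level.
    prov_cache: dict[str, tuple[str, ProvirusLayout]] = {}

    def built(template_id: str, source_rng: np.random.Generator):
        if template_id not in prov_cache:
            prov_cache[template_id] = build_provirus(
                templates[template_id], cfg.ltr_length, source_rng)
        return prov_cache[template_id]

    anc_loci: list[LocusTruth] = []
    t_now = pre[0].time_years if pre else cfg.split_time_years
    for idx, ev in enumerate(pre):
        genome = evolve(genome, cfg.sub_rate, t_now - ev.time_years, rng)
        t_now = ev.time_years
        prov, layout = built(ev.template_id, rng)
        pos = _sample_position(rng, len(genome), [l.span for l in anc_loci],
                               cfg.min_locus_spacing)
        genome, span = insert_provirus(genome, prov, pos, cfg.tsd_length)
        _shift_all(anc_loci, pos, len(prov) + cfg.tsd_length)
        s = span[0]
        anc_loci.append(LocusTruth(
            genome_id="ancestor", locus_id=f"anc{idx:02d}", contig_id="chr1",
            start=s, end=span[1], strand="+", time_years=ev.time_years,
            template_id=ev.template_id, partner_id=None,
            ltr5_start=s + layout.ltr5[0], ltr5_end=s + layout.ltr5[1],
            ltr3_start=s + layout.ltr3[0], ltr3_end=s + layout.ltr3[1],
            tsd_length=cfg.tsd_length,
            gene_spans={g: (s + gs, s + ge) for g, (gs, ge) in layout.genes.items()},
        ))
    genome = evolve(genome, cfg.sub_rate, t_now - cfg.split_time_years, rng)

    # Post-split insertion sites are drawn jointly in ancestral (split-time)
    # coordinates so independent insertions in the two lineages never share
    # flanking sequence by landing at nearby homologous positions.
    post_sorted = sorted(post, key=lambda ev: -ev.time_years)
    anc_positions: list[int] = []
    occupied = [l.span for l in anc_loci]
    for _ in post_sorted:
        pos = _sample_position(rng, len(genome), occupied, cfg.min_locus_spacing)
        anc_positions.append(pos)
        occupied.append((pos, pos))
    post_pos = dict(zip(map(id, post_sorted), anc_positions))

    genomes: dict[str, str] = {}
    truth: dict[str, list[LocusTruth]] = {}
    lineage_rngs = {gid: np.random.default_rng(rng.integers(2**31)) for gid in cfg.genome_ids}
    for gid in cfg.genome_ids:
        lrng = lineage_rngs[gid]
        g = genome
        loci = []
        for loc in anc_loci:
            other = cfg.genome_ids[1] if gid == cfg.genome_ids[0] else cfg.genome_ids[0]
            copy = dataclasses.replace(
                loc, genome_id=gid, locus_id=f"{loc.locus_id}.{gid}",
                partner_id=f"{loc.locus_id}.{other}",
                gene_spans=dict(loc.gene_spans),
                planted_stop_positions=list(loc.planted_stop_positions),
                planted_frameshift_positions=list(loc.planted_frameshift_positions),
            )
            loci.append(copy)
        own = sorted((ev for ev in post if (ev.lineage or cfg.genome_ids[0]) == gid),
                     key=lambda ev: -ev.time_years)
        t_now = cfg.split_time_years
        inserted_here: list[tuple[int, int]] = []  # (ancestral pos, inserted length)
        for jdx, ev in enumerate(own):
            g = evolve(g, cfg.sub_rate, t_now - ev.time_years, lrng)
            t_now = ev.time_years
            prov, layout = built(ev.template_id, lrng)
            anc_pos = post_pos[id(ev)]
            pos = anc_pos + sum(L for p, L in inserted_here if p <= anc_pos)
            inserted_here.append((anc_pos, len(prov) + cfg.tsd_length))
            g, span = insert_provirus(g, prov, pos, cfg.tsd_length)
            _shift_all(loci, pos, len(prov) + cfg.tsd_length)
            s = span[0]
            loci.append(LocusTruth(
                genome_id=gid, locus_id=f"{gid}.p{jdx:02d}", contig_id="chr1",
                start=s, end=span[1], strand="+", time_years=ev.time_years,
                template_id=ev.template_id, partner_id=None,
                ltr5_start=s + layout.ltr5[0], ltr5_end=s + layout.ltr5[1],
                ltr3_start=s + layout.ltr3[0], ltr3_end=s + layout.ltr3[1],
                tsd_length=cfg.tsd_length,
                gene_spans={gene: (s + gs, s + ge) for gene, (gs, ge) in layout.genes.items()},
            ))
        g = evolve(g, cfg.sub_rate, t_now, lrng)
        g = degrade_provirus(g, loci, cfg.decay_stop_rate, cfg.artifact_dup_prob,
                             lrng, cfg.decay_frameshift_rate)
        genomes[gid] = g
        truth[gid] = sorted(loci, key=lambda l: l.start)
    return SimResult(config=cfg, genomes=genomes, truth=truth, templates=templates)


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "genome_id", "locus_id", "contig_id", "start", "end", "strand", "time_years",
    "template_id", "partner_id", "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end",
    "tsd_length",
]


def write_truth_tsv(result: SimResult, path: str | Path) -> None:
    lines = ["# coordinates: 0-based, half-open", "\t".join(_TRUTH_COLUMNS)]
    for gid in result.config.genome_ids:
        for loc in result.truth[gid]:
            row = [str(getattr(loc, c)) if getattr(loc, c) is not None else ""
                   for c in _TRUTH_COLUMNS]
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_json(result: SimResult, path: str | Path) -> None:
    payload = {
        "coordinate_convention": "0-based, half-open",
        "loci": [dataclasses.asdict(loc) for gid in result.config.genome_ids
                 for loc in result.truth[gid]],
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=list))


def write_genome_fasta(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for gid, seq in result.genomes.items():
        p = outdir / f"{gid}.fasta"
        with open(p, "w") as fh:
            fh.write(f">chr1 {gid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        paths[gid] = p
    return paths


def write_probe_fasta(templates: dict[str, ProvirusTemplate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, tpl in templates.items():
            for gene, protein in tpl.proteins.items():
                fh.write(f">{tid}.{gene} gene={gene}\n{protein}\n")


def check_truth_consistency(result: SimResult) -> None:
    """Raise if any truth record is internally inconsistent with its genome."""
    for gid in result.config.genome_ids:
        n = len(result.genomes[gid])
        ids = {loc.locus_id for loc in result.truth[gid]}
        for loc in result.truth[gid]:
            assert 0 <= loc.start < loc.end <= n, f"{loc.locus_id}: span out of genome"
            assert loc.start <= loc.ltr5_start < loc.ltr5_end <= loc.ltr3_start \
                < loc.ltr3_end <= loc.end, f"{loc.locus_id}: LTR spans disordered"
            if loc.partner_id is not None:
                assert loc.partner_id not in ids, "partner must live in the sibling genome"
                other = [g for g in result.config.genome_ids if g != gid][0]
                partners = {l.locus_id: l for l in result.truth[other]}
                assert loc.partner_id in partners, f"missing partner {loc.partner_id}"
                assert partners[loc.partner_id].partner_id == loc.locus_id, \
                    "orthology must be symmetric"
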
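"""Reference simulation scenarios exercising the full discovery chain.

Each function builds a self-contained synthetic study with known ground
truth and runs the relevant pipeline stages on it. They are shared between
the test suite and the reproduction script so both measure the same
quantities the same way. Problem sizes are chosen to finish in seconds to a
couple of minutes on one CPU; docs/methods.md records the choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import annotate, dating, ortholog, screen, simulate


@dataclass
class ClockRecovery:
    t_true_mya: float
    t_hat_mya: list[float]
    n_detected: int
    n_loci: int

    @property
    def median_t_mya(self) -> float:
        return float(np.median(self.t_hat_mya))

    @property
    def mean_bias(self) -> float:
        return float(np.mean(self.t_hat_mya)) / self.t_true_mya - 1.0


def clock_recovery(seed: int, n_loci: int = 24, ltr_length: int = 400,
                   t_star_years: float = 20e6, rate: float = 1.5e-9) -> ClockRecovery:
    """Insert proviruses at a known time, recover it from LTR divergence.

    For each replicate locus a provirus with identical LTRs is integrated
    into a small host sequence, the genome evolves ``t_star_years`` under
    JC69, the LTR pair is re-detected by self-alignment and the integration
    time estimated as T = D/2R with JC69-corrected D (matching the
    simulator's substitution model).
    """
    rng = np.random.default_rng(seed)
    templates = simulate.default_templates(seed + 17)
    params = dating.DatingParams(R=rate, model="JC69")
    t_hats = []
    for _ in range(n_loci):
        prov, layout = simulate.build_provirus(templates["fv_a"], ltr_length, rng)
        host = simulate.random_genome(3000, 0.42, rng)
        genome, span = simulate.insert_provirus(host, prov, 1500, 4)
        genome = simulate.evolve(genome, rate, t_star_years, rng)
        ext = 400
        sub = genome[span[0] - ext : span[1] + ext]
        pair = annotate.detect_ltr_pair(sub, search_window=ext + ltr_length + 150)
        if pair is None:
            continue
        res = dating.date_ltr_pair(pair, params)
        t_hats.append(res.T_mya)
    return ClockRecovery(t_true_mya=t_star_years / 1e6, t_hat_mya=t_hats,
                         n_detected=len(t_hats), n_loci=n_loci)


@dataclass
class OrthologyRecovery:
    n_true_pairs: int
    n_recovered_true: int
    n_mutual_pairs: int
    n_false_positive_calls: int
    n_nonpartner_pairs: int
    matrix: ortholog.OrthologMatrix
    sim: simulate.SimResult


def orthology_scenario(seed: int, n_presplit: int = 7, n_postsplit_each: int = 3,
                       split_mya: float = 2.8, rate: float = 1.5e-9,
                       genome_length: int = 1_200_000,
                       flank_len: int = 30_000) -> OrthologyRecovery:
    """Sister-species cohort with known orthology, scored against truth.

    The ancestor receives ``n_presplit`` insertions older than the split;
    each descendant then gains ``n_postsplit_each`` lineage-specific ones.
    Truth loci (not the screen) feed the ortholog matrix, isolating the
    flank-homology decision itself.
    """
    split = split_mya * 1e6
    events = [simulate.InsertionEvent(float(t), "fv_a")
              for t in np.linspace(20e6, split * 1.2, n_presplit)]
    gids = ("genomeA", "genomeB")
    for i in range(n_postsplit_each):
        for gid in gids:
            events.append(simulate.InsertionEvent(split * (0.2 + 0.2 * i), "fv_b", gid))
    cfg = simulate.SimConfig(
        genome_length=genome_length, split_time_years=split, sub_rate=rate,
        insertion_events=events, seed=seed, min_locus_spacing=flank_len + 6000,
        genome_ids=gids)
    sim = simulate.simulate_cohort(cfg)

    def as_locus(loc: simulate.LocusTruth) -> screen.ProviralLocus:
        return screen.ProviralLocus(loc.locus_id, loc.genome_id, loc.contig_id,
                                    loc.start, loc.end, loc.strand)

    loci_a = [as_locus(l) for l in sim.truth["genomeA"]]
    loci_b = [as_locus(l) for l in sim.truth["genomeB"]]
    matrix = ortholog.ortholog_matrix(loci_a, loci_b, sim.genomes["genomeA"],
                                      sim.genomes["genomeB"], flank_len=flank_len)
    true_pairs = {(l.locus_id, l.partner_id) for l in sim.truth["genomeA"]
                  if l.partner_id is not None}
    recovered = set(matrix.mutual_pairs)
    n_fp_calls = sum(1 for c in matrix.calls
                     if c.is_orthologous and (c.locus_a, c.locus_b) not in true_pairs)
    n_nonpartner = sum(1 for c in matrix.calls
                       if (c.locus_a, c.locus_b) not in true_pairs)
    return OrthologyRecovery(
        n_true_pairs=len(true_pairs),
        n_recovered_true=len(recovered & true_pairs),
        n_mutual_pairs=len(recovered),
        n_false_positive_calls=n_fp_calls,
        n_nonpartner_pairs=n_nonpartner,
        matrix=matrix, sim=sim)


@dataclass
class FilterSweep:
    n_replicates: int
    accepted_low: int  # planted below-threshold identity that survived the filter
    accepted_high: int  # planted above-threshold identity that survived
    detected_low: int  # reported by the search at all (pre-filter)
    detected_high: int


def planted_probe_screen(genome_length: int, probe: str, identity: float,
                         rng: np.random.Generator,
                         filter_kwargs: dict | None = None) -> tuple[int, int]:
    """Plant one degraded copy of ``probe`` and screen for it.

    The probe is degraded to the requested amino-acid identity, reverse
    translated and embedded in an i.i.d. host genome; the ORIGINAL probe then
    screens that genome. Returns (n_reported, n_passing_filter).
    """
    degraded = simulate.mutate_protein(probe, identity, rng)
    cds = simulate.reverse_translate(degraded, rng)[:-3]
    host = simulate.random_genome(genome_length, 0.42, rng)
    pos = genome_length // 3
    genome = host[:pos] + cds + host[pos:]
    hits = screen.translated_search(genome, screen.ProbeSet([("probe", probe)]))
    kept = screen.filter_hits(hits, **(filter_kwargs or {}))
    return len(hits), len(kept)


def filter_sweep(seed: int, n_replicates: int = 50, low: float = 0.39,
                 high: float = 0.45, probe_len: int = 300,
                 genome_length: int = 15_000) -> FilterSweep:
    """The screen's 40/40/1e-5 decision boundary on planted degraded probes."""
    rng = np.random.default_rng(seed)
    probe = simulate.random_protein(probe_len, rng)
    res = FilterSweep(n_replicates, 0, 0, 0, 0)
    for _ in range(n_replicates):
        n_rep, n_kept = planted_probe_screen(genome_length, probe, low, rng)
        res.detected_low += n_rep > 0
        res.accepted_low += n_kept > 0
        n_rep, n_kept = planted_probe_screen(genome_length, probe, high, rng)
        res.detected_high += n_rep > 0
        res.accepted_high += n_kept > 0
    return res


def artifact_scenario(seed: int, n_loci: int = 10) -> tuple[int, int, list[float]]:
    """Planted adjacent duplications vs the artifact flagger.

    Returns (n_planted, n_clean_false_flags, per-locus span Jaccard of the
    best flag against the planted duplication).
    """
    rng = np.random.default_rng(seed)
    templates = simulate.default_templates(seed + 3)
    jaccards: list[float] = []
    n_planted = 0
    false_flags = 0
    for i in range(n_loci):
        prov, layout = simulate.build_provirus(templates["fv_a"], 400, rng)
        host = simulate.random_genome(2000, 0.42, rng)
        genome, span = simulate.insert_provirus(host, prov, 1000, 4)
        loc = simulate.LocusTruth(
            genome_id="g", locus_id=f"L{i}", contig_id="chr1",
            start=span[0], end=span[1], strand="+", time_years=0.0,
            template_id="fv_a", partner_id=None,
            ltr5_start=span[0], ltr5_end=span[0] + 400,
            ltr3_start=span[0] + layout.ltr3[0], ltr3_end=span[0] + layout.ltr3[1],
            tsd_length=4,
            gene_spans={g: (span[0] + s, span[0] + e)
                        for g, (s, e) in layout.genes.items()})
        plant = i % 2 == 0
        genome = simulate.degrade_provirus(genome, [loc], decay_stop_rate=0.0,
                                           artifact_dup_prob=1.0 if plant else 0.0,
                                           rng=rng)
        sub = genome[loc.start : loc.end]
        pair = annotate.detect_ltr_pair(sub)
        flags = annotate.flag_repeat_artifacts(sub, ltr_pair=pair)
        if plant:
            n_planted += 1
            s1, e1, s2, e2 = loc.artifact_duplication_span
            truth_span = (s1 - loc.start, e2 - loc.start)
            best = 0.0
            for f in flags:
                found = (f.source_span[0], f.duplicate_span[1])
                inter = max(0, min(found[1], truth_span[1]) - max(found[0], truth_span[0]))
                union = max(found[1], truth_span[1]) - min(found[0], truth_span[0])
                best = max(best, inter / union if union else 0.0)
            jaccards.append(best)
        else:
            false_flags += len(flags)
    return n_planted, false_flags, jaccards
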
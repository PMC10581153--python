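"""Annotation tests: LTR pair detection, ORF profiling, gene boundaries, artifacts."""

import numpy as np
import pytest
from Bio.Seq import Seq

from paleofv import annotate, simulate
from paleofv.annotate import (GeneAnnotation, detect_ltr_pair, orf_disruption_profile,
                              annotate_coding_regions, flag_repeat_artifacts, scan_motif)


def brute_force_codon_scan(seq):
    """Independent oracle: naive per-frame sliding scan for starts and stops."""
    seq = seq.upper()
    stops, starts = {1: [], 2: [], 3: []}, {1: [], 2: [], 3: []}
    for frame in (1, 2, 3):
        i = frame - 1
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon in ("TAA", "TAG", "TGA"):
                stops[frame].append(i)
            if codon == "ATG":
                starts[frame].append(i)
            i += 3
    return stops, starts


class TestDetectLtrPair:
    def test_planted_identical_repeats_found_exactly(self, rng):
        ltr = simulate.random_genome(400, 0.5, rng)
        mid = simulate.random_genome(4000, 0.5, rng)
        flank5 = simulate.random_genome(300, 0.5, rng)
        flank3 = simulate.random_genome(300, 0.5, rng)
        seq = flank5 + ltr + mid + ltr + flank3
        pair = detect_ltr_pair(seq)
        assert pair is not None
        assert pair.ltr5_span == (300, 700)
        assert pair.ltr3_span == (300 + 400 + 4000, 300 + 400 + 4000 + 400)
        assert pair.mismatches == 0
        assert pair.divergence_D == 0.0

    def test_mutated_repeats_p_distance_matches_mismatch_count(self, rng):
        # plant exactly 6 substitutions into one of two 100-column repeats
        ltr = simulate.random_genome(100, 0.5, rng)
        mutated = list(ltr)
        for pos in (10, 25, 40, 55, 70, 85):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        seq = (simulate.random_genome(200, 0.5, rng) + ltr
               + simulate.random_genome(2000, 0.5, rng) + "".join(mutated)
               + simulate.random_genome(200, 0.5, rng))
        pair = detect_ltr_pair(seq, min_len=80)
        assert pair is not None
        assert pair.aligned_length == 100
        assert pair.mismatches == 6
        assert pair.p_distance == pytest.approx(0.06)

    def test_random_sequence_has_no_pair(self, rng):
        seq = simulate.random_genome(6000, 0.5, rng)
        assert detect_ltr_pair(seq) is None

    def test_boundary_accuracy_on_simulated_loci(self, templates):
        # each of the four boundaries within 5 bp of truth in >=90% of loci
        rng = np.random.default_rng(77)
        ok = 0
        n = 30
        for _ in range(n):
            prov, layout = simulate.build_provirus(templates["fv_a"], 400, rng)
            host = simulate.random_genome(3000, 0.42, rng)
            g, span = simulate.insert_provirus(host, prov, 1500, 4)
            g = simulate.evolve(g, 1.5e-9, 20e6, rng)
            ext = 400
            sub = g[span[0] - ext : span[1] + ext]
            pair = detect_ltr_pair(sub, search_window=ext + 550)
            if pair is None:
                continue
            truth = (ext, ext + 400, ext + layout.ltr3[0], ext + layout.ltr3[1])
            found = (pair.ltr5_start, pair.ltr5_end, pair.ltr3_start, pair.ltr3_end)
            if all(abs(a - b) <= 5 for a, b in zip(found, truth)):
                ok += 1
        assert ok >= 0.9 * n


class TestOrfProfile:
    def test_minimal_orf(self):
        prof = orf_disruption_profile("ATGTAA")
        assert prof.start_positions[1] == [0]
        assert prof.stop_positions[1] == [3]
        assert prof.start_positions[2] == prof.stop_positions[2] == []
        assert prof.start_positions[3] == prof.stop_positions[3] == []

    def test_matches_brute_force_scan_on_random_sequences(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            seq = simulate.random_genome(int(rng.integers(3, 400)), 0.5, rng)
            prof = orf_disruption_profile(seq)
            stops, starts = brute_force_codon_scan(seq)
            assert prof.stop_positions == stops
            assert prof.start_positions == starts

    def test_undecayed_genes_have_zero_premature_stops(self, templates, rng):
        prov, layout = simulate.build_provirus(templates["fv_a"], 400, rng)
        anns = [GeneAnnotation(g, s, e, "+", "p", 1.0, 0.0, blocks=[(s, e, s % 3 + 1)])
                for g, (s, e) in layout.genes.items()]
        prof = orf_disruption_profile(prov, anns)
        assert all(v == 0 for v in prof.premature_stop_count.values())
        assert all(v is False for v in prof.frameshift_evidence.values())

    def test_planted_stops_counted_per_gene(self, templates, rng):
        prov, layout = simulate.build_provirus(templates["fv_a"], 400, rng)
        host = simulate.random_genome(1000, 0.5, rng)
        g, span = simulate.insert_provirus(host, prov, 500, 4)
        s = span[0]
        loc = simulate.LocusTruth(
            genome_id="g", locus_id="L", contig_id="c", start=s, end=span[1],
            strand="+", time_years=0, template_id="fv_a", partner_id=None,
            ltr5_start=s, ltr5_end=s + 400, ltr3_start=s + layout.ltr3[0],
            ltr3_end=s + layout.ltr3[1], tsd_length=4,
            gene_spans={gn: (s + gs, s + ge) for gn, (gs, ge) in layout.genes.items()})
        g = simulate.degrade_provirus(g, [loc], decay_stop_rate=2.0,
                                      artifact_dup_prob=0.0, rng=rng)
        sub = g[loc.start : loc.end]
        anns = [GeneAnnotation(gn, gs - loc.start, ge - loc.start, "+", "p", 1.0, 0.0,
                               blocks=[(gs - loc.start, ge - loc.start,
                                        (gs - loc.start) % 3 + 1)])
                for gn, (gs, ge) in loc.gene_spans.items()]
        prof = orf_disruption_profile(sub, anns)
        planted_by_gene = {
            gn: sum(1 for p in loc.planted_stop_positions if gs <= p < ge)
            for gn, (gs, ge) in loc.gene_spans.items()}
        assert prof.premature_stop_count == planted_by_gene


class TestCodingRegions:
    @pytest.fixture()
    def gene_probes(self, templates):
        return {g: [(f"fv_a.{g}", p)] for g, p in templates["fv_a"].proteins.items()}

    def test_recovered_spans_overlap_truth(self, templates, rng, gene_probes):
        prov, layout = simulate.build_provirus(templates["fv_a"], 400, rng)
        anns = annotate_coding_regions(prov, gene_probes)
        found = {a.gene: a.span for a in anns}
        for gene, (ts, te) in layout.genes.items():
            assert gene in found, f"{gene} not annotated"
            s, e = found[gene]
            inter = max(0, min(e, te) - max(s, ts))
            union = max(e, te) - min(s, ts)
            assert inter / union >= 0.9

    def test_truncated_gene_is_omitted(self, templates, rng, gene_probes):
        prov, layout = simulate.build_provirus(templates["fv_a"], 400, rng)
        cut = layout.genes["env"][0]  # drop env and everything after
        anns = annotate_coding_regions(prov[:cut], gene_probes)
        genes = {a.gene for a in anns}
        assert "env" not in genes
        assert {"gag", "pol"} <= genes

    def test_reverse_complement_flips_spans(self, templates, rng, gene_probes):
        prov, layout = simulate.build_provirus(templates["fv_a"], 400, rng)
        rc = str(Seq(prov).reverse_complement())
        fwd = {a.gene: a for a in annotate_coding_regions(prov, gene_probes)}
        rev = {a.gene: a for a in annotate_coding_regions(rc, gene_probes)}
        for gene, a in fwd.items():
            b = rev[gene]
            assert b.strand == "-"
            assert (b.start, b.end) == (len(prov) - a.end, len(prov) - a.start)


class TestArtifacts:
    def test_planted_adjacent_duplication_flagged(self, rng):
        core = simulate.random_genome(6000, 0.5, rng)
        frag = core[2000:3000]
        seq = core[:3000] + frag + core[3000:]  # tandem duplication of 1 kb
        flags = flag_repeat_artifacts(seq)
        assert len(flags) == 1
        f = flags[0]
        assert f.identity >= 0.99
        assert f.adjacency_gap == 0
        assert f.source_span == (2000, 3000)
        assert f.duplicate_span == (3000, 4000)

    def test_clean_sequence_has_no_flags(self, rng):
        seq = simulate.random_genome(8000, 0.5, rng)
        assert flag_repeat_artifacts(seq) == []

    def test_ltr_pair_is_never_flagged(self, rng):
        ltr = simulate.random_genome(600, 0.5, rng)
        seq = ltr + simulate.random_genome(800, 0.5, rng) + ltr
        pair = detect_ltr_pair(seq, search_window=700)
        assert pair is not None
        flags = flag_repeat_artifacts(seq, max_adjacency_gap=2000, ltr_pair=pair)
        assert flags == []

    def test_distant_repeats_not_flagged_as_adjacent(self, rng):
        frag = simulate.random_genome(800, 0.5, rng)
        seq = frag + simulate.random_genome(5000, 0.5, rng) + frag
        assert flag_repeat_artifacts(seq) == []


class TestMotifScan:
    def test_absent_motif_reported_absent(self, rng):
        scan = scan_motif("ACGC" * 500, "TATAAAA")
        assert not scan.present

    def test_planted_promoter_found(self, rng):
        seq = simulate.random_genome(1000, 0.5, rng) + "TATAAAA" + \
            simulate.random_genome(500, 0.5, rng)
        scan = scan_motif(seq)
        assert 1000 in scan.positions
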
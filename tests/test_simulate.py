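"""Simulator unit and property tests: construction invariants and the clock."""

import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

from paleofv import simulate
from paleofv.simulate import (InsertionEvent, SimConfig, SimulationError,
                              build_provirus, evolve, insert_provirus,
                              excise_provirus, random_genome, simulate_ancestor,
                              simulate_cohort, degrade_provirus)


class TestAncestor:
    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SimConfig(genome_length=1000, seed=42)
        g1, _ = simulate_ancestor(cfg)
        g2, _ = simulate_ancestor(cfg)
        assert g1 == g2
        assert len(g1) == 1000

    def test_gc_content_matches_binomial_expectation(self):
        n = 1_000_000
        g, _ = simulate_ancestor(SimConfig(genome_length=n, gc_content=0.5, seed=1))
        gc = (g.count("G") + g.count("C")) / n
        sd = np.sqrt(0.25 / n)
        assert abs(gc - 0.5) < 3 * sd

    @pytest.mark.parametrize("bad", [0, -5])
    def test_nonpositive_length_rejected(self, bad):
        with pytest.raises(SimulationError):
            simulate_ancestor(SimConfig(genome_length=bad))


class TestProvirus:
    def test_ltrs_identical_at_integration(self, templates, rng):
        prov, layout = build_provirus(templates["fv_a"], 400, rng)
        assert prov[:400] == prov[-400:]
        assert layout.ltr5 == (0, 400)
        assert layout.ltr3[1] - layout.ltr3[0] == 400

    def test_genes_reverse_translate_back_to_templates(self, templates, rng):
        prov, layout = build_provirus(templates["fv_a"], 400, rng)
        for gene, (s, e) in layout.genes.items():
            aa = str(Seq(prov[s:e]).translate())
            assert aa[-1] == "*" and "*" not in aa[:-1]
            assert aa[:-1] == templates["fv_a"].proteins[gene]
            assert prov[s : s + 3] == "ATG"

    def test_codon_choice_varies_with_seed_but_protein_fixed(self, templates):
        protein = templates["fv_a"].proteins["gag"]
        cds1 = simulate.reverse_translate(protein, np.random.default_rng(1))
        cds2 = simulate.reverse_translate(protein, np.random.default_rng(2))
        assert cds1 != cds2
        assert str(Seq(cds1).translate())[:-1] == protein
        assert str(Seq(cds2).translate())[:-1] == protein

    def test_empty_template_rejected(self, rng):
        with pytest.raises(SimulationError):
            build_provirus(simulate.ProvirusTemplate("x", {}), 400, rng)


class TestInsertion:
    def test_target_site_duplication_flanks_both_ltrs(self, templates, rng):
        prov, _ = build_provirus(templates["fv_a"], 400, rng)
        host = random_genome(5000, 0.5, rng)
        g, span = insert_provirus(host, prov, 2000, tsd_length=4)
        assert g[span[0] - 4 : span[0]] == g[span[1] : span[1] + 4]
        assert len(g) == len(host) + len(prov) + 4

    def test_excision_roundtrip_recovers_host(self, templates, rng):
        prov, _ = build_provirus(templates["fv_a"], 400, rng)
        host = random_genome(5000, 0.5, rng)
        g, span = insert_provirus(host, prov, 1234, tsd_length=4)
        assert excise_provirus(g, span, 4) == host

    def test_out_of_range_position_rejected(self, templates, rng):
        prov, _ = build_provirus(templates["fv_a"], 400, rng)
        with pytest.raises(SimulationError):
            insert_provirus("ACGT" * 10, prov, 100)


class TestEvolve:
    def test_zero_time_is_identity(self, rng):
        s = random_genome(1000, 0.5, rng)
        assert evolve(s, 1.5e-9, 0.0, rng) == s

    def test_p_distance_matches_jc69_closed_form(self, rng):
        n = 100_000
        s = random_genome(n, 0.5, rng)
        d = 0.03
        s2 = evolve(s, 1.5e-9, d / 1.5e-9, rng)
        p = sum(a != b for a, b in zip(s, s2)) / n
        expected = 0.75 * (1 - np.exp(-4 * d / 3))
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(p - expected) < 3 * sd

    def test_fixed_seed_reproducible(self, rng):
        s = random_genome(2000, 0.5, rng)
        assert evolve(s, 1e-9, 1e7, 99) == evolve(s, 1e-9, 1e7, 99)

    def test_saturation_rejected(self, rng):
        s = random_genome(100, 0.5, rng)
        with pytest.raises(SimulationError):
            evolve(s, 1e-7, 1e10, rng)


class TestCohort:
    def test_orthology_truth_symmetric_and_complete(self, small_cohort):
        simulate.check_truth_consistency(small_cohort)
        by_id = {l.locus_id: l for gid in small_cohort.truth
                 for l in small_cohort.truth[gid]}
        pre = [l for l in by_id.values() if l.partner_id is not None]
        post = [l for l in by_id.values() if l.partner_id is None]
        assert len(pre) == 4  # 2 ancestral insertions x 2 genomes
        assert len(post) == 2
        for loc in pre:
            partner = by_id[loc.partner_id]
            assert partner.partner_id == loc.locus_id
            assert partner.genome_id != loc.genome_id
            assert partner.time_years == loc.time_years

    def test_truth_spans_extract_consistent_sequence(self, small_cohort):
        # an orthologous pair's provirus copies are near-identical at 2*2.8 MY
        a = next(l for l in small_cohort.truth["genomeA"] if l.partner_id is not None)
        b = next(l for l in small_cohort.truth["genomeB"] if l.locus_id == a.partner_id)
        sa = small_cohort.genomes["genomeA"][a.start : a.end]
        sb = small_cohort.genomes["genomeB"][b.start : b.end]
        diffs = sum(x != y for x, y in zip(sa, sb)) / min(len(sa), len(sb))
        expected = 0.75 * (1 - np.exp(-4 * (2 * 2.8e6 * 1.5e-9) / 3))
        assert diffs == pytest.approx(expected, abs=0.01)

    def test_ltr_clock_over_replicate_loci(self):
        # mean LTR-LTR p-distance across >=20 proviruses within 3 SE of JC69(2RT)
        events = [InsertionEvent(20e6, "fv_a")]
        ps = []
        for seed in range(20):
            cfg = SimConfig(genome_length=30_000, split_time_years=2.8e6,
                            insertion_events=events, seed=seed,
                            min_locus_spacing=5000, genome_ids=("gA", "gB"))
            res = simulate_cohort(cfg)
            loc = res.truth["gA"][0]
            g = res.genomes["gA"]
            l5 = g[loc.ltr5_start : loc.ltr5_end]
            l3 = g[loc.ltr3_start : loc.ltr3_end]
            ps.append(sum(a != b for a, b in zip(l5, l3)) / len(l5))
        expected = 0.75 * (1 - np.exp(-4 * (2 * 20e6 * 1.5e-9) / 3))
        se = np.std(ps, ddof=1) / np.sqrt(len(ps))
        assert abs(np.mean(ps) - expected) < 3 * se

    def test_post_split_lineage_assignment(self, small_cohort):
        for gid in ("genomeA", "genomeB"):
            own_private = [l for l in small_cohort.truth[gid] if l.partner_id is None]
            assert len(own_private) == 1
            assert own_private[0].genome_id == gid


class TestDegrade:
    def _one_locus(self, templates, rng, host_len=3000):
        prov, layout = build_provirus(templates["fv_a"], 400, rng)
        host = random_genome(host_len, 0.5, rng)
        g, span = insert_provirus(host, prov, host_len // 2, 4)
        s = span[0]
        loc = simulate.LocusTruth(
            genome_id="g", locus_id="L0", contig_id="chr1", start=s, end=span[1],
            strand="+", time_years=0.0, template_id="fv_a", partner_id=None,
            ltr5_start=s, ltr5_end=s + 400,
            ltr3_start=s + layout.ltr3[0], ltr3_end=s + layout.ltr3[1], tsd_length=4,
            gene_spans={gn: (s + gs, s + ge) for gn, (gs, ge) in layout.genes.items()})
        return g, loc

    def test_zero_rates_leave_genome_unchanged(self, templates, rng):
        g, loc = self._one_locus(templates, rng)
        g2 = degrade_provirus(g, [loc], 0.0, 0.0, rng)
        assert g2 == g

    def test_planted_stops_are_in_frame_stop_codons(self, templates, rng):
        g, loc = self._one_locus(templates, rng)
        g2 = degrade_provirus(g, [loc], decay_stop_rate=2.0, artifact_dup_prob=0.0, rng=rng)
        assert loc.planted_stop_positions
        for pos in loc.planted_stop_positions:
            assert g2[pos : pos + 3] in simulate.STOP_CODONS
            gene = next((gn, gs) for gn, (gs, ge) in loc.gene_spans.items()
                        if gs <= pos < ge)
            assert (pos - gene[1]) % 3 == 0

    def test_stop_count_matches_poisson_mean(self, templates):
        rng = np.random.default_rng(5)
        rate = 1.5
        total = 0
        coding_kb = 0.0
        for _ in range(30):
            g, loc = self._one_locus(templates, rng)
            degrade_provirus(g, [loc], rate, 0.0, rng)
            total += len(loc.planted_stop_positions)
            coding_kb += sum(e - s for s, e in loc.gene_spans.values()) / 1000
        mean = rate * coding_kb
        assert abs(total - mean) < 3 * np.sqrt(mean)

    def test_artifact_duplication_adjacent_and_identical(self, templates, rng):
        g, loc = self._one_locus(templates, rng)
        g2 = degrade_provirus(g, [loc], 0.0, artifact_dup_prob=1.0, rng=rng)
        assert loc.artifact_duplication_span is not None
        s1, e1, s2, e2 = loc.artifact_duplication_span
        assert e1 == s2  # inserted immediately next to the source
        assert e2 - s2 == e1 - s1 > 500
        assert g2[s1:e1] == g2[s2:e2]
        assert loc.ltr3_end - loc.ltr3_start == 400  # truth shifted, not mangled
        assert g2[loc.ltr3_start:loc.ltr3_end] == g[loc.ltr3_start - (e2 - s2):
                                                    loc.ltr3_end - (e2 - s2)]

    def test_frameshift_shifts_truth_coordinates(self, templates, rng):
        g, loc = self._one_locus(templates, rng)
        end_before = loc.end
        g2 = degrade_provirus(g, [loc], 0.0, 0.0, rng, decay_frameshift_rate=1.0)
        shift = len(g2) - len(g)
        assert loc.planted_frameshift_positions
        assert loc.end == end_before + shift
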
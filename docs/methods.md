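# Methods

This note documents the models behind each stage, the defaults that matter,
what the simulator does and does not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The provirus simulator

**Host genome.** An i.i.d. nucleotide sequence at a configurable GC content
(default 0.42, a typical mammalian value). There is no repeat structure, no
gene content, no isochores — see *Limitations*.

**Proviruses.** Each viral lineage is a template of protein sequences in
genomic order (gag, pol, env plus two accessory genes, lengths roughly
proportional to exogenous foamy virus genes but scaled down ~30% so test
genomes stay small). The provirus is LTR + reverse-translated coding
cassette + an identical copy of the LTR. Reverse translation picks
synonymous codons uniformly at random. Within one simulated cohort a
template is reverse-translated **once** and every insertion of that lineage
reuses the same nucleotide sequence: real ERV copies are copies of one
viral genome, and this is what makes same-lineage loci clusterable at the
nucleotide level (~74% identity is all that survives independent
reverse-translation of the same protein).

**Integration.** Insertion duplicates the `tsd_length` bases at the target
site (default 4 bp, a typical retroviral target-site duplication; the length
is configurable) so they flank both LTRs. All truth coordinates are 0-based,
half-open, and are shifted consistently by every later insertion or indel.

**Substitution.** JC69 only. A site evolved for time *t* at rate *μ* changes
to each specific other base with probability (1/4)(1 − e^(−4μt/3)), the
exact JC69 transition probability, so expected p-distances follow the closed
form without discretising time. Saturation (μt > 0.75) is rejected. Neutral
indels are off by default; decay frameshifts (below) are the only default
source of length change. Keeping the model this small is deliberate: it
makes the divergence↔time relation exactly invertible, which the dating
closed-loop tests exploit.

**Speciation.** The ancestor (with its pre-split insertions) is copied into
two descendants which then evolve independently for the split time; each
descendant's LTRs, flanks and coding regions therefore diverge at 2·R·t
between species. Pre-split loci carry symmetric `partner_id` truth links;
post-split insertions go to one named lineage. Post-split insertion *sites*
are drawn jointly in ancestral coordinates with a minimum spacing
(`min_locus_spacing`, default 20 kb; the orthology scenario uses
flank + 6 kb) so that two independent insertions never land close enough to
share flanking homology — without this, nearby independent insertions in
sister species are genuinely indistinguishable from orthologs by
flank-homology criteria, which is a limitation of the method itself, not of
an implementation.

**Decay and artifacts.** Premature stops and ±1 frameshifts are planted
inside coding spans as Poisson events per kb of CDS (defaults 1.0 stops/kb,
0 frameshifts/kb; these are plumbing for testability, not estimates of any
real element's decay). Assembly artifacts are modelled as a >500 bp internal
fragment copied immediately adjacent to its source. Decay and artifacts are
applied after evolution — an assembly error is a modern event, which is why
artifact copies are near-identical while LTR pairs are not.

## Screening

Probes are aligned against all six conceptual translations with a local
Smith–Waterman (BLOSUM62, affine gaps 11/1, via Biopython's C
`PairwiseAligner`); after each hit the matched peptide span is masked with X
and the search repeats, BLAST-style (up to 8 hits per probe × frame).
E-values come from Karlin–Altschul statistics with the standard gapped
BLOSUM62 parameters (λ = 0.267, K = 0.041) over the total translated search
space. Hits weaker than e = 1e−3 are never materialised; the significance
filter proper is identity ≥ 0.40, probe coverage ≥ 0.40, e ≤ 1e−5, with
**inclusive** bounds (the thresholds are conventionally quoted without
strictness; inclusivity is exposed in config). "Coverage" is the fraction
of the **probe** spanned by the alignment — the standard reading in
translated searches; the alternative (fraction of the genomic region) is
deliberately not offered, to keep results comparable.

Same-contig, same-strand hits within 5 kb are chained into loci (proviruses
are < 15 kb; 5 kb bridges degraded internal regions without fusing
neighbouring insertions). Lineage grouping is single-linkage clustering on
pairwise nucleotide identity (edlib global alignment, matches over alignment
columns) at 0.80 — a distance stand-in for the phylogenetic confirmation
step, which is out of scope. Labels a, b, … go to clusters by size, ties by
(contig, start).

An adapter seam exists for substituting an external translated-search
executable producing tabular output; the internal aligner is the default and
the only path the tests exercise.

## LTR detection and annotation

The locus, extended 2.5 kb into its flanks (`ltr_flank_extension`; the
hull of protein hits can end >1 kb short of an LTR because of untranslated
leader/trailer and unprobed accessory genes), is searched by locally
aligning its 5′ window against its 3′ window (match +2 / mismatch −3 /
gap −5,−2). The alignment is then re-trimmed to its maximal-scoring column
segment under match +1 / mismatch-or-gap −2 (Kadane), which removes the few
bases of chance extension affine local alignment keeps beyond a repeat
boundary. Acceptance: ≥ 100 ungapped columns (≤ 2000), identity ≥ 0.70.
Absence of a qualifying pair is a *result* (`None`), not an error — heavily
decayed lineages really do lack recognisable LTRs, and such loci are
reported as explicitly undatable. Divergence bookkeeping: mismatches over
ungapped columns; indel columns are counted but excluded from the
denominator (configurable in principle, documented here). Equal-scoring
candidate pairs are resolved by the aligner's leftmost-optimal convention.

ORF disruption profiles cover the three forward frames only (loci are
reported on their detected strand first); positions of every ATG and
TAA/TAG/TGA, computed by vectorised codon-id matching, are checked in the
tests against a naive sliding-window oracle. Gene boundaries come from the
best-scoring chain of translated hits per gene (chain gap ≤ 2 kb, frames
may differ across chained blocks — that difference *is* the frameshift
evidence); overlapping gene claims resolve by score. A simple exact-motif
scan reports presence/absence of the internal promoter signal (TATAAAA);
absence is a finding, not an error.

Artifact flags: intra-locus repeat pairs found by k-mer self-comparison
(k = 13, trivial self-diagonal excluded, mirror pairs collapsed), kept when
both copies are ≥ 500 bp at ≥ 0.90 identity and within 1 kb of each other —
"identical sequence inserted next to its source", the signature of tandem
mis-assembly. The locus's own LTR pair is explicitly excluded.

## Orthology calling

Flanks of 30,000 bp per side are extracted (clipped at contig ends, with the
truncation recorded and excluded from coverage denominators). Homologous
blocks between flanks use exact 11-mer seeding, greedy chaining along
diagonals (gap ≤ 200 bp, diagonal band ±16 to tolerate small indels) and
edlib global realignment of the chained span for identity; blocks < 500 bp
or weaker than e = 1e−5 (ungapped nucleotide Karlin–Altschul, λ = 0.625,
K = 0.41) are discarded. At ≥ 90% identity an 11-mer survives with
probability ≈ 0.31 per position, so true homology chains densely while
random 30 kb flank pairs yield ~200 scattered seed matches and no chain of
500 bp — the length filter alone removes the short-repeat noise it exists
for.

A pair is orthologous iff length-weighted mean block identity **> 0.90**
and merged-block coverage **> 0.50** (strict bounds, honouring the
">90%/>50%" phrasing). Upstream and downstream flanks are pooled for both
criteria (per-side block detail is retained in the synteny export);
coverage averages the a-side and b-side projections so the verdict is
exactly symmetric under argument swap. In the all-pairs matrix, one-to-many
conflicts resolve by the coverage·identity product and only mutual best
matches enter the ortholog set.

## Dating

T = (D/R)/2, held bit-exactly on the reporting path. D is the p-distance by
default — the most conservative reading of "nucleotide divergence" — with
JC69 correction available; the simulator-matched tests use JC69 so the loop
closes against the generating model (whether a published divergence of this
kind is corrected or raw is generally not stated; at D ≈ 0.06 the two differ
by ~4%). The ancestral-ruminant rate 1.5 × 10⁻⁹ substitutions/site/year
ships as the `ruminant_ancestral` preset and default. An optional binomial
confidence interval on the mismatch count can be propagated through the
clock; it is an extension beyond the usual point estimate and is off by
default.

## Problem sizes in tests and the reproduction script

Chosen as the package's own trade-off between statistical resolution and
desk-scale runtime: clock loop 24 loci (40 in the script) × 400 bp LTRs at
20 MYA; orthology scenario 7 shared + 3 private insertions per lineage in a
1.2 Mb ancestor with full 30 kb flanks; filter boundary 50 replicates of a
300-aa probe planted in 15 kb hosts; null-specificity check ~1 Mb of i.i.d.
genome. With 400 bp LTRs at 20 MYA each locus's estimate carries ~20%
binomial CV, so the mean over 40 loci has ~3% standard error — the scatter
seen in the script's `clock_mean_bias_percent` is expected sampling noise,
not systematic bias.

## Limitations

* The host model is i.i.d. sequence: no transposable-element background, no
  segmental duplications, no rate heterogeneity among sites or lineages.
  Passing the null-specificity tests therefore bounds false positives from
  alignment statistics only, not from real repeat families — on real
  assemblies a repeat-masking step upstream of screening is advisable.
* JC69 throughout; no recombination, selection, or CpG hypermutability. On
  real data LTR dating inherits every caveat of the single-rate clock.
* Orthology calling assumes collinear, same-orientation flanks; inversions
  or translocations near a locus would defeat it (as they would the
  underlying criteria).
* The lineage clustering is a nucleotide-distance stand-in for phylogenetic
  confirmation; maximum-likelihood trees, domain annotation and consensus
  building are out of scope.
* Two independent insertions closer than a flank length are intrinsically
  indistinguishable from orthologs by flank homology; the simulator's
  spacing constraint encodes the method's assumption rather than removing
  the limitation.
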
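# paleofv

Mining, annotation, orthology calling and molecular dating of **endogenous
foamy virus (EFV)** insertions in host genome assemblies — with a built-in
provirus simulator so every stage is testable against known ground truth.

Endogenous retroviruses are germ-line "fossil viruses": a retrovirus that
integrated into an ancestor's genome and has been inherited vertically ever
since. Four questions drive their analysis, and each maps onto one module of
this package:

| Question | Module | Method |
| --- | --- | --- |
| Where are viral remnants in the genome? | `paleofv.screen` | six-frame translated homology search (tBLASTn-style) with a 40% identity / 40% probe coverage / e ≤ 1e−5 significance filter |
| What is left of each provirus? | `paleofv.annotate` | LTR pair detection by end-to-end self-alignment; start/stop codon profiles in frames +1..+3; gene boundaries by translated alignment; adjacent-repeat assembly-artifact flags |
| Was an insertion inherited from a common ancestor? | `paleofv.ortholog` | 30 kb flanking sequences compared across species; orthologous iff length-weighted block identity > 90% **and** flank coverage > 50%, blocks ≥ 500 bp |
| When did it integrate? | `paleofv.dating` | molecular clock on the LTR pair: **T = (D / R) / 2**, with D the LTR–LTR divergence (p-distance or JC69) and R the host neutral substitution rate |

The simulator (`paleofv.simulate`) generates a neutral host genome, inserts
proviruses (LTR–gag–pol–env–LTR, with target-site duplications) at known
times, evolves sequences under JC69 so LTR pairs diverge at 2·R·T, splits
the host into two descendant species at a configurable time (pre-split
insertions become orthologous, post-split ones lineage-specific), and
finally applies post-insertion decay (premature stops, frameshifts) and
optional tandem-duplication assembly artifacts.

## Worked example: dating an integration

The clock relation with a divergence of D = 0.06 between a provirus's two
LTRs and the ancestral-ruminant substitution rate R = 1.5 × 10⁻⁹
substitutions/site/year:

```python
from paleofv import dating, scenarios

params = dating.DatingParams(R=1.5e-9)
res = dating.estimate_integration_time(D=0.06, params=params)
print(f"T = {res.T_mya:.1f} MYA  ({res.T_years:.3e} years)")

rec = scenarios.clock_recovery(seed=1, n_loci=24)
print(f"detected LTR pairs: {rec.n_detected}/{rec.n_loci}")
print(f"median T-hat: {rec.median_t_mya:.2f} MYA   mean bias: {100*rec.mean_bias:+.1f}%")
```

prints

```
T = 20.0 MYA  (2.000e+07 years)
detected LTR pairs: 24/24
median T-hat: 20.90 MYA   mean bias: -0.8%
```

The first two lines are the point estimate: at that rate, 6% LTR–LTR
divergence corresponds to an integration 20 million years ago. The
`clock_recovery` block closes the loop on simulated data: 24 proviruses are
planted 20 MYA with 400 bp LTRs, their LTR pairs re-detected from sequence
alone, and the integration time re-estimated — the median lands within a few
percent of the planted age, the residual scatter being binomial noise on
~24 expected mismatches per LTR pair.

## Command line

```bash
paleofv simulate --outdir sim --genome-length 400000 --n-presplit 3 --seed 1
paleofv run --genome A=sim/genomeA.fasta --genome B=sim/genomeB.fasta \
            --probes sim/probes.fasta --outdir run1
paleofv report run1
```

`run` chains screen → annotate → ortholog → date, writes per-stage TSV/GFF3
tables plus a `manifest.json` with input hashes and per-stage status, and is
bit-reproducible for fixed inputs and seed. Exit codes: 0 success, 2 config
error, 3 input parse error, 4 stage failure.

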
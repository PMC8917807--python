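# paraflux

Analysis pipeline for the expression behaviour of **paralog gene pairs** —
duplicated genes that can substitute for each other in protein complexes —
across developmental time courses, tissues and species.

Paralogs are a major source of proteome modularity: two subunits with the
same fold can be swapped in and out of a complex as conditions change. This
package quantifies that behaviour at every level where it leaves a
statistical trace:

- **Pair co-expression and divergence** — Pearson correlation R of the two
  members' profiles; pairs with R ≤ 0 are *divergent*, R > 0 *co-regulated*;
  random-gene-pair nulls, identity-binned comparisons, coefficients of
  variation, and the per-pair Δ = R_protein − R_rna score that isolates
  post-transcriptional divergence.
- **Complex variability** — per complex, variability = 1 − median pairwise
  member correlation; stable/variable quartile classes; the relation between
  variability and *paralog content* (fraction of members with a paralog);
  per-subunit median correlations; random-complex nulls.
- **Stoichiometric stability** — per subunit and comparison, the median
  Euclidean log2-fold-change distance to co-members against 2,500 distances
  from size-matched random complexes: p = (#{null < obs} + 1)/(n_null + 1).
- **Differential analysis** — Welch-t/BH differential abundance with the
  |log2 FC| > 0.58 and adj. p < 0.05 rule; concordant vs opposite pair
  regulation; NED/ED degradation-class enrichment and Δ contrasts; TMT PSM
  filtering and protein-group summarization; ranked fold-change KS tests.
- **Conserved paralog substitution across species** — per-replicate log2
  paralog ratios, moderated-t ratio-change tests, orthogroup aggregation,
  Fisher-combined p-values, and the conservation rule: present in all
  species, sign-consistent in ≥ 5 of 7 comparisons, BH-adjusted combined
  p ≤ 0.05.
- **Promoter motif profiles** — JASPAR PWM scanning of 2,000-bp promoter
  windows at the 80% relative-score threshold; shared vs member-exclusive
  TF-site fractions; per-TF score-difference distributions between pair
  members.
- **Enrichment** — Fisher over-representation and KS ranked enrichment over
  GMT gene sets with BH/Hommel adjustment.

Every input the pipeline consumes can be produced by the seeded
synthetic-data generator (`paraflux.simulate`), which plants known structure
(divergent fractions, content-coupled complex dispersion, conserved ratio
shifts, promoter motifs, PSM violations) so each statistic is testable as a
parameter-recovery problem. See `docs/methods.md` for the models,
assumptions and numerical choices.

## Worked example

Run the analysis chain end to end on the packaged synthetic study (each
script reads/writes `results/`):

```bash
python analysis/01_simulate_study.py --seed 0
python analysis/02_coexpression_divergence.py --seed 0
python analysis/03_complex_variability.py --seed 0
python analysis/06_conserved_signature.py --seed 0
```

which prints, with seed 0:

```
wrote 400 pairs (140 planted divergent, 35%), 40 complexes, 2 layers x (1400, 30) to results/
divergent fraction (rna): 0.350 vs planted 0.350
paralog R vs random-pair null: rank-sum p = 1.81e-20 (null mean -0.000)
delta scores for 400 pairs, median -0.033
40 complexes scored; content-variability R = 0.92 (p = 5.5e-17); classes: intermediate=20, stable=10, variable=10
real vs random complex median R: rank-sum p = 1.4e-26
50 conserved orthogroup pairs called of 50 planted: sensitivity 1.00, FDP 0.000
ratio PCA: PC1 20%, PC2 17% of variance
```

Reading the numbers: the divergence classifier recovers the planted 35%
divergent fraction exactly at noise 0.3× the latent sd; paralog-pair
correlations differ sharply from random gene pairs whose null is centered at
0; the slightly negative median Δ reflects the extra protein-layer noise;
complex variability correlates with paralog content (R = 0.92 here, by
construction of the coupling); and the cross-species rule recovers all 50
planted conserved substitutions among 1,000 orthogroup pairs with no false
calls. The remaining drivers (`04`, `05`, `07`) cover stoichiometric
stability, differential/concordance/PSM processing and promoter motifs.

The same chain is available as a library call:

```python
from paraflux.pipeline import run_synthetic_study
results = run_synthetic_study(seed=0)
results["conserved_signature"].head()
```

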
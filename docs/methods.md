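# Methods

## The analysis

`orthoscreen` implements a reference-gene-anchored temporal co-expression
screen between two species sampled along their own developmental stage
axes, followed by gene-set over-representation of the passing genes.
The motivating setting is comparative craniofacial development: a mouse
time course (E8.5–E13.5) against a zebrafish time course (20 somites to
72 hpf), with *Sox9* (mouse) and *sox9b* (zebrafish) as the anchors
because they share a rising-then-plateauing trajectory across these
windows while the duplicated paralog *sox9a* does not.

For each species *s* with reference gene *g\*ₛ* and stage axis
*t = 1..Tₛ*:

1. counts are normalized to `x_gst = log2(count / libsize × 10⁶ + c)`
   (CPM with pseudocount *c*, default 1);
2. replicate samples are averaged within each stage, giving the stage
   profile `x̄_g = (x̄_g1, …, x̄_gTₛ)`;
3. every gene is scored by the Pearson product-moment correlation
   `r_gs = corr(x̄_g, x̄_{g*ₛ})`.

An ortholog pair (gA, gB) **passes** when `r_{gA,A} > τ` **and**
`r_{gB,B} > τ` with τ = 0.7 by default (strict inequality; the
correlation is computed within species only — the two stage axes have
different lengths and are never concatenated). One-to-many pairs are
screened independently, so a divergent duplicate fails while its
sibling passes; a gene joins the passing list if any of its pairs
passes. Undefined correlations (zero-variance profiles) fail and are
counted in the log rather than being set to 0.

The passing species-A gene list is tested for over-representation in a
GMT gene-set collection: with universe size N, set size K (after
intersection with the universe), query size n and overlap k, the
p-value is the hypergeometric upper tail P(X ≥ k), computed exactly in
log space from log-binomial coefficients (`scipy.special.gammaln` +
`logsumexp`) so genome-scale arguments do not overflow. Adjusted
values come from the Benjamini–Hochberg step-up
(`q(i) = min_{j≥i} p(j)·m/j`, clipped at 1); a set is significant when
q < 0.05 by default. The default universe is the set of screened
species-A genes (the background actually tested), configurable to all
profiled genes.

## Normalization choices

The normalization dialect is deliberately minimal — per-sample
library-size scaling, log2, pseudocount 1 — because the screen
statistic is a correlation of log-scale profiles: any per-sample scale
factor enters log2-CPM as an additive per-sample constant and, after
stage averaging, as an additive per-stage constant shared by the gene
and the reference, so more elaborate between-sample normalizations
(TMM, quantile) would change r only at second order. No batch
correction is attempted.

Correlations default to **stage-mean** profiles rather than all
replicate samples: the two species have very unequal replicate counts
per stage (29 mouse embryos at E9.5 vs 11 elsewhere; 8 zebrafish pools
at 32 hpf vs 16 elsewhere), and replicate-level correlation would
weight stages by their replicate numbers. The replicate-level
alternative (`replicate_mode: all-samples`) is implemented and logged
for sensitivity analysis.

Per-gene z-scaling across stages (mean 0, sd 1, ddof = 1 as in R's
`scale()`) is applied by default for display parity; it is an affine
per-gene transform, so it provably changes no correlation and no
verdict, and the test suite asserts this end-to-end. Constant genes
are flagged and excluded rather than scaled.

## The synthetic experiment

The generator emulates the sampling design the screen is meant for:

| parameter | default | meaning |
|---|---|---|
| `stages_a` / `replicates_a` | E8.5–E13.5 / (11, 29, 11, 11, 11, 11) | mouse stages and embryos per stage |
| `stages_b` / `replicates_b` | 20ss–72hpf / (16, 16, 8, 16, 16) | zebrafish stages and pooled replicates |
| `n_planted_genes` | 50 | genes truly tracking the reference in both species |
| `n_null_genes` | 950 | genes with reference-independent profiles |
| `n_divergent_paralogs` | 1 | failing species-B duplicates on passing hosts |
| `amplitude` | 3 log2 | rise of the reference ramp (8-fold) |
| `profile_noise_sd` | 0.25 log2 | per-stage perturbation of planted profiles |
| `null_profile_sd` | 1.0 log2 | per-stage spread of null profiles |
| `null_r_cap` | 0.5 | upper bound on a null profile's true correlation with the reference shape |
| `dispersion` | 10 | negative-binomial size (inverse-dispersion) |
| `library_size_mean` | 10⁶ | mean sequencing depth (log-normal, sd 0.25 in log) |

The reference trajectory is a linear ramp in log2 units from `low` to
`high`, reaching the plateau at E11.5 / 48 hpf — the simplest monotone
shape consistent with a gradual rise followed by saturation. Planted
genes share this shape per species up to a per-gene baseline offset
(irrelevant to correlation) and i.i.d. per-stage Gaussian noise; at the
default `profile_noise_sd` their true profile correlation with the
reference is ≈ 0.98. Divergent paralogs sit on the reversed ramp, which
gives a strongly negative correlation — a deliberate caricature of the
sox9a behaviour sufficient for the qualitative pass/fail split. Counts
are negative binomial in the mean/size parameterization
(var = μ + μ²/size): per-stage linear means are the per-species
softmax of the log2 profiles scaled by a log-normal library size, so
library-size normalization downstream is non-trivial.

**Truth-label contract.** With only 6 and 5 stages, an unconstrained
"null" profile has a ≈ 6–9% per-species chance of truly correlating
above 0.7 with the reference shape — such a gene would be a genuine
co-mover mislabelled null, and the noiseless limit could never recover
*exactly* the planted set. Null profiles are therefore redrawn (per
species, independently) while their true correlation with the
reference shape exceeds `null_r_cap` = 0.5. Because rejection never
looks across species, species-A and species-B pass events for null
genes remain independent, which is what the product-of-marginals
calibration check exploits. Set `null_r_cap: null` to disable.

What the generator does **not** emulate: 3′-tag library artefacts
(UMIs, positional bias), stage-to-stage correlation of biological
noise, compositional shifts from a few very highly expressed genes,
annotation errors in the ortholog map, and real GO structure
(annotations arrive as a flat GMT; no DAG propagation). Passing tests
therefore demonstrate correctness of the screening machinery under its
own statistical assumptions, not robustness to real-data pathologies.

## Numerical and procedural details

- Pearson r is computed from centred sums and clipped to [−1, 1];
  vectors shorter than 3 stages are rejected, zero variance returns the
  undefined flag (NaN), which always fails the screen.
- Screen records are ordered by min(r_a, r_b) descending with
  lexicographic (gene_a, gene_b) tie-breaks; undefined correlations
  sort last.
- Stage means are taken through an explicit contiguous numpy copy so
  that results are bit-identical whether profiles come from a fresh
  simulation or from TSVs read back from disk (pandas' own reductions
  can differ in the last ulp depending on internal block layout).
- Gene-set size filters default to [10, 500] after universe
  intersection, conventional for over-representation analysis.
- The BH step-up assigns tied p-values a shared q; empty inputs yield
  empty outputs.
- Pipeline runs are fully seeded: the run seed drives the simulator,
  and identical config + seed gives byte-identical output tables (the
  run summary additionally carries timestamps, a config hash and
  library versions for provenance, and is therefore not byte-stable).

## Problem sizes used in the checks

The acceptance checks run the full design at 1 001 species-A genes
(1 reference + 50 planted + 950 null) over 20 seeds for recovery and
null calibration, 10 seeds for the enrichment construction, full
enumeration of every hypergeometric tail up to N = 12, and 1 000
random vectors for the correlation and BH oracles. These sizes give
19 000 pooled null pairs for the calibration contrast while keeping a
complete run in the order of seconds.

## Known limitations

- Orthology is taken from the supplied table or from name matching
  (case-insensitive equality plus the single-letter a/b zebrafish
  duplicate suffix); no sequence-based inference.
- Pearson only (a Spearman option was considered and deliberately left
  out of scope); correlations on 5–6 points are noisy, which is why
  the screen is a screen and not an inference procedure — no p-values
  are attached to individual correlations.
- The enrichment stage assumes pre-propagated annotations and tests
  over-representation only.
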
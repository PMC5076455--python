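# Methods

## Model and procedure

The pipeline turns a case-vs-reference expression comparison into a
pathway-level activation profile and then into a drug ranking.

1. **Differential expression.** Per gene, the case-to-normal ratio (CNR)
   is the ratio of arithmetic means of linear-scale intensities, each
   floored at `epsilon = 1e-6` to avoid division by zero on all-zero
   intensities.  Significance uses the classic equal-variance two-sample
   Student's t-test (not Welch), two-sided, followed by
   Benjamini–Hochberg adjustment; `BTIF = 1` iff `q < alpha`
   (default `alpha = 0.05`).  Genes with fewer than two non-missing
   values on a side are untestable: they keep their CNR, get
   `p = q = NaN`, `BTIF = 0`, and are excluded from the BH family so they
   cannot dilute it.  Degenerate zero-variance pairs resolve to `p = 1`
   when the constants are equal (no evidence) and `p = 0` otherwise.

2. **Pathway activation strength.**
   `PAS_p = Σ_n ARR_n · BTIF_n · log10(CNR_n)` over measured member
   genes.  The log base (default 10) only rescales PAS and every
   downstream score.  Pathways with *no* measured member score 0 but
   carry a `no_coverage` flag so "no data" stays distinguishable from
   "no change"; the zero-PAS sample exclusion below ignores the flag and
   acts on values, keeping the exclusion rule well defined.
   Per-sample profiles reuse the *group-level* BTIF with sample-specific
   CNRs: a single sample cannot support a t-test, so group significance
   is the only consistent gate for per-sample scoring.

3. **Sample exclusion.** Case samples whose PAS is exactly 0 for every
   pathway are insignificantly perturbed and dropped before scoring.
   Dropping every sample is an error, surfaced with its stage name.

4. **GeroScore.**
   `GS_d^g = Σ_t DTI_dt · Σ_p NII_tp · ARR_tp · PAS_p^g · PAR_p`.
   ARR here is the target's own member weight in pathway *p*: it is the
   only pathway- and target-specific signed role available, which is what
   the formula's indices require.  NII, ARR, PAR are structural database
   constants; only PAS varies across case entities.  The per-drug
   aggregate is the arithmetic mean over case samples (median exposed as
   an option); ranking is by descending aggregate with ties broken
   lexicographically by drug id, which keeps reruns deterministic.
   When several datasets are screened separately, per-dataset tables can
   be combined by averaging z-scored aggregates; no canonical combination
   rule exists, so this stays configurable rather than baked in.

5. **Donor-age grouping.** Young reference: `15 <= age <= 30`
   (inclusive); old case: `age > 60` (strictly), a literal reading of the
   stated age windows; everything else is excluded.

6. **Plate-matched perturbation designs.** For each compound the case
   set is all wells matching (compound, dose, duration) — dose compared
   with 1% relative tolerance because annotation files round
   inconsistently — and the reference set is vehicle (DMSO) wells on the
   same plate(s), which cancels plate effects.  Replicate plates are
   pooled into one design per compound.  Cell-line restriction is a
   pre-step flag, not hard-coded.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | FDR threshold gating BTIF |
| `epsilon` | 1e-6 | floor on means before ratios (intensity units) |
| `log_base` | 10 | base of the PAS logarithm |
| `young_min/max`, `old_min` | 15/30, 60 | donor-age windows (years) |
| `shortlist_n` | 10 | number of top-ranked drugs reported |
| `aggregation` | mean | per-drug aggregate over case samples |

## Synthetic world

The generator emulates a two-group aging contrast: reference intensities
are log-normal, `10^(2.0 + N(0, 0.1))` per gene and sample (intensities
around 100, matching positive microarray scale); 10 disjoint pathways of
15 genes each are drawn with PAR ±1 and member ARR from
{±1, ±0.5}; the first 3 pathways are planted with fold-change 4 on case
samples, applied per member as `fc^(sign(ARR)·PAR)` so a planted
pathway's expected PAS sign equals its aging role (pro-aging pathways up
in the old state, anti-aging pathways down).  Group sizes default to 8
case vs 8 reference.  The planted ideal geroprotector targets every
member of every planted pathway with `DTI = sign(ARR)` — inhibit
activators, activate repressors — which opposes the planted shift
regardless of PAR; each of the 30 decoys gets 5 random pathway-member
targets with random DTI.  Disjoint pathway membership keeps expected PAS
per pathway independent and the recovery oracle tractable.

What a green recovery test establishes: the full chain (simulation → DE →
PAS → filter → scoring → ranking) preserves and amplifies a planted
signal of realistic effect size above random-target decoys.  What it does
not: robustness to probe effects, batch structure, correlated genes,
overlapping pathway membership, or L1000 inference-gene imputation — none
of which the generator emulates.

Under the null (fold-change 1) almost no gene passes the FDR gate, so
nearly every case sample has all-zero PAS and is excluded; replicates
with no rankable samples count as failures to recover, so measured
null recovery sits at or below the 1/(n_decoys+1) chance level rather
than at it.  This is a direct consequence of the sample-exclusion rule,
not a defect of the benchmark.

## Numerical choices

- Means and ratios are computed on the linear intensity scale; only PAS
  takes logs, after the BTIF gate, so zero ratios can only arise from the
  epsilon floor and stay finite.
- BH adjustment delegates to `statsmodels` (`fdr_bh`); the test suite
  cross-checks it against a from-definition step-up implementation.
- The vectorized GeroScore (drug × pathway weight matrix times PAS × PAR)
  is cross-checked against a naive double loop to 1e-12.
- All generators are pure functions of (config, seed) with one
  independent substream per stage, so adding a stage never perturbs the
  others and reruns are byte-identical.

## Known limitations

- Pathway scoring is topology-free: ARR weights, not graph propagation.
- Equal-variance t-test by design; heteroscedastic data would call for
  Welch, which is deliberately not offered to keep the method faithful.
- Per-sample BTIF reuses group significance; a sample that disagrees
  with its group can still inherit the group's significant genes.
- The drug model is binary activate/inhibit per target: no affinities,
  dose–response, or chemical similarity.
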
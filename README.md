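# geroscope

Pathway-level screening of candidate **geroprotectors** — substances
predicted to push an "old" gene-expression signalome back toward the
"young" state.  The package is aimed at computational biologists working
with bulk transcriptomes of young vs old donors (or compound-perturbation
screens such as LINCS L1000 level-3 matrices) who want to rank a library
of compounds with known protein targets by predicted rejuvenating effect.

## Method

For one case-vs-reference comparison (old vs young donors, or
compound vs same-plate DMSO vehicle) each gene gets a case-to-normal
ratio of mean intensities, `CNR = mean(case) / mean(reference)`, a
two-sided equal-variance Student's t-test, and a Benjamini–Hochberg
FDR-adjusted q-value; genes with `q < 0.05` are significant (`BTIF = 1`).

**Pathway activation strength** for pathway *p* sums the
activator/repressor-weighted log ratios of its significant members:

    PAS_p = Σ_n  ARR_n · BTIF_n · log10(CNR_n)

with ARR ∈ [−1, 1]\{0} the member's signed role (positive = activator).
Positive PAS means the pathway is up-regulated in the case state.
Case samples whose PAS is zero for *every* pathway are insignificantly
perturbed and excluded.

**GeroScore** ranks drug *d* against the PAS profile of case entity *g*:

    GS_d^g = Σ_t DTI_dt · Σ_p NII_tp · ARR_tp · PAS_p^g · PAR_p

where DTI ∈ {−1, +1} (drug activates / inhibits target *t*), NII is
target-in-pathway membership, and PAR ∈ {+1, −1} is the pathway's aging
role (pro- / anti-aging).  A drug scores high when it inhibits activators
of activated pro-aging pathways and reactivates suppressed anti-aging
ones.  Scores are averaged over case samples, drugs are ranked by
descending aggregate, and the top 10 form the shortlist.

A synthetic-data module generates expression matrices with planted
pathway fold-changes, pathway/drug databases, and one planted "ideal
geroprotector" among decoys, so the whole pipeline is testable end to end
without any external downloads.

## Worked example

```sh
geroscope simulate --n-genes 300 --n-pathways 5 --genes-per-pathway 10 \
    --n-planted 2 --n-decoys 8 --seed 11 --outdir simdemo
geroscope screen --expression simdemo/expression.tsv \
    --annotations simdemo/annotations.tsv \
    --pathway-db simdemo/pathways.tsv --drug-db simdemo/drugs.tsv \
    --outdir screendemo
```

prints the ranked score table:

```
               aggregate_score  rank
GEROPROTECTOR        64.705096     1
DECOY_4               4.586767     2
DECOY_6               2.293383     3
DECOY_1               2.164596     4
DECOY_7               2.164596     5
...
```

The planted geroprotector — the drug constructed to oppose the two
planted pathway shifts (inhibit their activators, activate their
repressors) — tops the ranking; decoys with random targets score near
zero.  `screendemo/` also holds the per-sample PAS profile, the filtered
profile, the shortlist, and a manifest with all parameters and input
checksums that makes the run byte-for-byte reproducible.

The same library drives perturbation screens: `geroscope lincs-design`
builds case/reference designs whose reference is restricted to DMSO
wells on the same RNA plate as the treated wells, and
`geroscope perturb` computes per-compound pathway activation profiles.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it simulates the default synthetic world (2000 genes, 10
pathways of 15 genes, 3 planted at fold-change 4, 8 old vs 8 young
samples, 30 decoy drugs), executes the full pipeline, and measures
rank-1 recovery of the planted geroprotector over 100 seeded replicates.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/geroscope/io.py` — domain types, TSV readers/writers, donor-age grouping
- `src/geroscope/diffexpr.py` — CNR, Student's t, BH FDR, significance flags
- `src/geroscope/pas.py` — pathway activation strength, zero-PAS filter
- `src/geroscope/scoring.py` — GeroScore, aggregation, ranking, shortlist
- `src/geroscope/perturbation.py` — plate-matched vehicle-control designs
- `src/geroscope/simulate.py` — synthetic data with planted structure
- `src/geroscope/pipeline.py`, `src/geroscope/cli.py` — workflows and CLI

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
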
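# surfhet

Expression, co-expression and heterogeneity analysis of cell-surface
therapeutic targets (TROP2, PSMA, DLL3, CEACAM5) in multi-site tumor
tissue-microarray cohorts, built for rapid-autopsy-style data: many
metastatic sites per patient, one tumor block per site, several TMA cores
per block.

It is aimed at translational pathology and biostatistics groups who score
IHC semiquantitatively and need the downstream statistics to respect the
nested sampling design (cores within blocks within sites within patients).

## What it computes

* **H-scores** from staining-level fractions, `H = 0·p0 + 1·p1 + 2·p2`
  (range 0–200), binarized at an inclusive positivity cut-off (default
  H ≥ 20).
* **AR/NE molecular subtypes** per tumor block from two marker axes —
  AR signaling (AR, NKX3.1) and neuroendocrine (SYP, INSM1) — giving the
  four-quadrant classes AR+/NE−, AR−/NE+, AR+/NE+, AR−/NE−.
* **Co-expression tables**: 2×2 joint-positivity contingency tables per
  marker pair within a subtype stratum, and per-patient three-way classes
  (non-expressor / heterogeneous / uniform-high) across metastatic sites.
* **Heterogeneity indices**: the probability that a random pair of samples
  from the same tumor block (intra-tumoral) or the same patient across
  blocks (inter-tumoral) is discordant in binarized status. For a block of
  *n* samples with *k* positives the concordance probability is the
  finite-population identity `[C(k,2)+C(n−k,2)]/C(n,2)`; the index is
  computed exactly by pair enumeration and by a pair-resampling bootstrap
  with bias-corrected and accelerated (BCa) 95% limits.
* **Association models**: per-site mean H-score contrasts from a linear
  mixed model with patient random intercepts (REML, Wald inference), and
  marker-positivity odds ratios for genomic alterations from a
  random-intercept logistic regression fit by Gauss–Hermite quadrature.
* **Synthetic cohorts** with known ground truth — subtype mixtures,
  anchored marker distributions, within-patient correlation, site shifts
  and genomic effect sizes — for estimator validation and power studies.

## Worked example

Generate a synthetic 52-patient cohort and analyze it:

```sh
$ surfhet simulate --seed 1 --out-dir demo
wrote 768 samples / 375 sites / 52 patients to demo

$ surfhet heterogeneity demo/cohort.tsv --marker TROP2 --scope both --seed 17
TROP2   intra_tumoral   0.0334  [0.0240, 0.0462]  pairs=602   seed=17
TROP2   inter_tumoral   0.2251  [0.2020, 0.2560]  pairs=5393  seed=17
```

TROP2 discordance is ~3% for two cores of the same tumor block but ~23%
for two blocks of the same patient: expression is locally uniform while
patients carry both positive and negative metastases — the pattern that
makes single-site biopsies unreliable for target selection. The brackets
are BCa 95% limits over 1000 bootstrap replicates of 1000 pairs.

```sh
$ surfhet coexpress demo/cohort.tsv --marker-a TROP2 --marker-b PSMA --stratum "AR+/NE-"
both_positive   195/303   64.0%
a_only          51/303    17.0%
b_only          25/303    8.0%
neither         32/303    11.0%
```

Among 303 adenocarcinoma (AR+/NE−) cores with both markers measured, 64%
co-express TROP2 and PSMA and 17% express TROP2 where PSMA is lost — the
fraction of disease a TROP2 agent could reach after PSMA-directed therapy
fails.

```sh
$ surfhet associate demo/cohort.tsv --marker PSMA --gene AR
PSMA~AR: OR 2.32 (95% CI 0.55 to 9.78; p=0.252; altered=19, wildtype=33)
```

Patient-level PSMA positivity versus AR-amplification status, with
patients counted once (positive if any site is positive).

The same stages are available as library calls (`surfhet.generate_cohort`,
`surfhet.enumerate_pairs`, `surfhet.heterogeneity_bootstrap`,
`surfhet.site_mixed_model`, ...), and `surfhet run` executes the full
pipeline into tidy TSVs plus a JSON manifest of hashes and seeds.

See `docs/methods.md` for the statistical models, defaults, and what the
synthetic generator does and does not emulate.

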
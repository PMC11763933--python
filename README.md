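# eeglgs

Diagnostic classification of multichannel EEG from the *texture* of its
directed connectivity. The pipeline turns a resting-state recording into
a small feature vector in four steps:

1. **Preprocess** — split each recording into equal segments (default
   five 60 s segments at 500 Hz), band-pass every segment into the six
   clinical bands — δ (0.5–4 Hz), θ (4–8 Hz), α (8–13 Hz), β (13–30 Hz),
   γ (30–100 Hz) and SMR (12–15 Hz) — with a second-order Butterworth
   filter, and z-score each channel (z = (x − μ)/σ, population σ).
2. **Connectivity** — for every ordered channel pair (x, y), fit two
   nested autoregressions by OLS on a shared sample range,

       y(t) = c + Σᵢ a(i) y(t−i) + e(t)
       y(t) = c + Σᵢ a(i) y(t−i) + Σⱼ b(j) x(t−j) + ẽ(t)

   and declare x → y Granger-causal when var(ẽ) < var(e) (or, in the
   calibrated mode, when the nested-model F-test rejects at level α).
   This gives a 19 × 19 directed connectivity matrix per (segment, band).
3. **Texture encoding** — slide eight local graph structure (LGS)
   operators over the matrix. Each operator is a small block (3×3 up to
   3×5) with a fixed ordered walk of eight directed cell-pair
   comparisons; each comparison emits a bit (1 if from-cell − to-cell
   ≥ 0), and the eight bits form one 8-bit code per window. The eight
   operators (SLGS, LELGS, VLGS, VSLGS, ZHLGS, ZHMLGS, ZVLGS, ZVMLGS)
   differ in block shape and traversal.
4. **Quantify & classify** — reduce each code matrix to three scalars:
   Shannon entropy of the code histogram H = −Σ p log₂ p (bits), its
   natural-log counterpart −Σ p ln p (nats), and the largest singular
   value of the code matrix. The resulting 8 × 3 = 24 features per
   (subject, segment, band) feed one-versus-all classifiers (KNN k=5,
   Gaussian Naïve Bayes, RBF SVM, AdaBoost) under stratified 10-fold
   cross-validation, reported as mean ± sd of accuracy, sensitivity,
   precision and F1 per class.

A VAR-based cohort simulator with per-class directed coupling graphs and
band-limited oscillations provides ground truth for every stage, so the
whole pipeline is testable without clinical data.

## Worked example

Simulate a small five-class cohort (4 subjects per class, 60 s each),
extract γ-band features with calibrated edge detection, and
cross-validate KNN one-versus-all:

```python
from eeglgs import (PipelineConfig, SimulationConfig, GrangerConfig,
                    ClassifierConfig)
from eeglgs.pipeline import run_all
from eeglgs.io_preprocess import DEFAULT_BANDS

gamma = tuple(b for b in DEFAULT_BANDS if b.name == "gamma")
cfg = PipelineConfig(
    segment_len=6_000, n_segments=5, bands=gamma,
    granger=GrangerConfig(lag_order=8, max_lag=8,
                          binarize_mode="ftest", alpha=1e-4),
    classifier=ClassifierConfig("knn", seed=0),
)
sim = SimulationConfig(n_samples=30_000, n_subjects_per_class=4, seed=0)
table, report, manifest = run_all(cfg, sim, "demo_out")
```

`table` has one row per (subject, segment, band) — here 100 rows × 24
feature columns — and `demo_out/cv_summary_percent.csv` holds the
per-class metrics:

```
        class algorithm      accuracy   sensitivity            f1     precision
    alzheimer       knn 100.00 ± 0.00 100.00 ± 0.00 100.00 ± 0.00 100.00 ± 0.00
      control       knn  94.00 ± 6.99 85.00 ± 24.15 84.67 ± 16.64 91.67 ± 18.00
   depression       knn 100.00 ± 0.00 100.00 ± 0.00 100.00 ± 0.00 100.00 ± 0.00
          mci       knn  94.00 ± 6.99 85.00 ± 33.75 80.67 ± 30.86 80.00 ± 32.20
schizophrenia       knn 100.00 ± 0.00 100.00 ± 0.00 100.00 ± 0.00 100.00 ± 0.00
```

Accuracy is the fraction of held-out samples classified correctly for
that one-versus-all task (the majority baseline here is 80%); the ± is
the spread over the ten folds. Three of five classes are recovered
perfectly from their coupling structure alone; the two sparsest graphs
(control, MCI) are occasionally confused at this small cohort size.

The same pipeline runs from a shell:

```sh
eeglgs simulate --seed 7 --subjects-per-class 4 --n-samples 30000 -o raw/
eeglgs extract  -i raw/ -o feats/ --fs 500 --segment-len 6000 --bands gamma --lag-order 8
eeglgs classify -i feats/features_combined.csv -o cv/
```

Real recordings enter through `read_edf` (EDF, header-labelled) or
`read_delimited` (CSV/TSV, rows = channels).

## Caveats

The default binarization is the raw variance comparison, which for
nested OLS fits on a shared sample range is satisfied almost surely —
matrices saturate to all ones. The pipeline counts saturated matrices in
its run manifest and provides a calibrated nested-model F-test mode
(`binarize_mode="ftest"`) and a `min_improvement` guard; see
`docs/methods.md` for the full discussion and the study configurations
used in the tests.
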
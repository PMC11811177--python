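# boclahe

Per-image automatic selection of CLAHE hyperparameters (clip limit, tile
grid size) by Gaussian-process Bayesian optimization of a combined
SSIM/BRISQUE objective, applied inside a lung-region mask. Ships with a
deterministic synthetic chest-phantom generator so everything is
testable offline.

## What's inside

| module | role |
|---|---|
| `boclahe.phantoms` | synthetic chest radiographs + ground-truth lung masks and lesion maps |
| `boclahe.clahe_core` | from-scratch CLAHE: tiling, histogram clipping/redistribution, per-tile LUTs, bilinear blending, masked application |
| `boclahe.quality_metrics` | windowed SSIM (l·c·s form), BRISQUE feature pipeline (MSCN → AGGD, 36 features), Mahalanobis quality distance, combined objective |
| `boclahe.bayes_opt` | exact GP regression (Matérn 2.5), UCB/EI acquisition, sequential optimization loop |
| `boclahe.pipeline` | end-to-end orchestration, PNG/JSON I/O, enhancement reports, cohort mode |
| `boclahe.eval_stats` | Dice/Jaccard, confusion-table metrics, rank AUC, one-way ANOVA |

Defaults follow the published optimization settings: clip limit searched
in [1, 255], tile grid in [8, 32], 25 random initial points + 25 BO
iterations, UCB κ = 2.576 (EI ξ = 0.01 by flag), GP noise α = 1e−6,
5 kernel-optimizer restarts, normalized targets.

## CLI

All functionality is under one entry point:

```sh
# generate 5 phantoms with masks
boclahe phantom --out scratch/ph --n 5 --seed 1

# fixed-parameter CLAHE inside a mask
boclahe enhance --input img.png --mask mask.png \
    --clip-limit 2.0 --tile-grid 8 --out out.png

# SSIM / BRISQUE / combined objective as JSON
boclahe metrics --ref img.png --test out.png --mask mask.png

# full BO-CLAHE optimization of one image
boclahe optimize --input img.png --mask mask.png \
    --out enhanced.png --report report.json --seed 0

# overlap metrics and one-way ANOVA
boclahe evalstats overlap maskA.png maskB.png
boclahe evalstats anova groups.json
```

`boclahe optimize` accepts `--config cfg.json` with flat keys
(`clip_limit_min/max`, `tile_grid_min/max`, `init_points`, `n_iter`,
`kappa`, `xi`, `noise_alpha`, `n_restarts`, `normalize_y`,
`acquisition`, `w_ssim`, `w_brisque`, `brisque_norm`, `seed`).

## Notes

* The BRISQUE score is a Mahalanobis distance to packaged reference
  statistics computed from a pristine phantom corpus
  (`src/boclahe/data/quality_model.json`, regenerable with
  `python scripts/build_quality_model.py`); an external model with the
  same JSON layout (36-vector `mean`, 36×36 `covariance`) can be
  passed instead. No trained SVR weights are required.
* All randomness flows from a single seed; identical inputs + seed give
  bit-identical enhanced images and reports.
* Masked application guarantees pixels outside the mask are never
  modified.
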
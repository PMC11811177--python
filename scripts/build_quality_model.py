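"""Regenerate the packaged BRISQUE reference statistics.

Computes the 36-feature vectors of a corpus of pristine (unenhanced)
phantom lung-region crops with varied geometry, rib texture, lesions and
mild noise, and stores their mean and (ridge-regularized) covariance as
src/boclahe/data/quality_model.json.

Usage: python scripts/build_quality_model.py [--n 240] [--seed 20240901]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from boclahe.phantoms import PhantomSpec, generate_phantom
from boclahe.quality_metrics import brisque_features


def corpus_features(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    feats = []
    for i in range(n):
        lungs = (
            (0.45 + rng.uniform(-0.04, 0.04), 0.30 + rng.uniform(-0.03, 0.03),
             0.30 + rng.uniform(-0.04, 0.04), 0.17 + rng.uniform(-0.02, 0.02)),
            (0.45 + rng.uniform(-0.04, 0.04), 0.70 + rng.uniform(-0.03, 0.03),
             0.30 + rng.uniform(-0.04, 0.04), 0.17 + rng.uniform(-0.02, 0.02)),
        )
        lesions = []
        for _ in range(rng.integers(0, 3)):
            lesions.append((int(rng.integers(40, 120)), int(rng.integers(30, 130)),
                            float(rng.uniform(4, 10)), float(rng.uniform(-30, 40))))
        spec = PhantomSpec(
            width=160, height=160,
            background_level=float(rng.uniform(20, 45)),
            lung_fill=float(rng.uniform(100, 150)),
            lung_ellipses=lungs,
            rib_count=int(rng.integers(3, 7)),
            rib_amplitude=float(rng.uniform(6, 18)),
            lesions=tuple(lesions),
            noise_sigma=float(rng.uniform(1.0, 4.0)),
        )
        img, mask, _ = generate_phantom(spec, int(rng.integers(0, 2**31)))
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        crop = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        feats.append(brisque_features(crop).values)
    return np.asarray(feats)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=240)
    ap.add_argument("--seed", type=int, default=20240901)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    F = corpus_features(args.n, args.seed)
    mean = F.mean(axis=0)
    cov = np.cov(F, rowvar=False)
    # ridge keeps the covariance positive definite despite near-constant features
    ridge = 1e-3 * float(np.trace(cov)) / 36 + 1e-8
    cov += ridge * np.eye(36)
    np.linalg.cholesky(cov)  # must be PD

    out = args.out or Path(__file__).resolve().parents[1] / "src/boclahe/data/quality_model.json"
    with open(out, "w") as fh:
        json.dump({"mean": mean.tolist(), "covariance": cov.tolist(),
                   "corpus_size": args.n, "corpus_seed": args.seed}, fh)
    print(f"wrote {out} (n={args.n}, ridge={ridge:.3g})")


if __name__ == "__main__":
    main()
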
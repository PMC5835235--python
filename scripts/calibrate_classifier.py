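"""Calibrate the component-artifact logistic classifier.

Generates a labelled synthetic component corpus, extracts the six
features, fits a logistic regression, and writes the standardization
statistics + weights to ``src/happe/data/classifier_weights.json``.
Fully seeded; rerunning reproduces the shipped weights bit-for-bit.

Usage:  python scripts/calibrate_classifier.py [--seeds N] [--out PATH]
"""
from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from happe.components import HeadModel, extract_features
from happe.montage import builtin_montage
from happe.synth import SynthSpec, generate_labeled_components

BASE_SEED = 7001


def corpus_features(seeds, n_per_class=8, duration_s=60.0, fs=250.0):
    head = HeadModel.build(builtin_montage("standard19"))
    X, y = [], []
    for seed in seeds:
        spec = SynthSpec(fs=fs, duration_s=duration_s, seed=seed)
        for comp in generate_labeled_components(spec, n_per_class):
            X.append(extract_features(comp.source, comp.scalp_map, fs, head))
            y.append(int(comp.is_artifact))
    return np.array(X), np.array(y)


def fit_logistic(z, y, l2=1.0, n_iter=200):
    """Newton-IRLS logistic regression with a small ridge penalty."""
    n, d = z.shape
    A = np.hstack([z, np.ones((n, 1))])
    beta = np.zeros(d + 1)
    for _ in range(n_iter):
        p = 1.0 / (1.0 + np.exp(-A @ beta))
        W = p * (1 - p)
        reg = l2 * np.eye(d + 1)
        reg[-1, -1] = 0.0
        H = A.T @ (A * W[:, None]) + reg
        g = A.T @ (y - p) - reg @ beta
        step = np.linalg.solve(H, g)
        beta += step
        if np.abs(step).max() < 1e-10:
            break
    return beta[:-1], beta[-1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=10)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1]
                    / "src/happe/data/classifier_weights.json")
    args = ap.parse_args()

    train_seeds = [BASE_SEED + k for k in range(args.seeds)]
    X, y = corpus_features(train_seeds)
    means, stds = X.mean(axis=0), X.std(axis=0)
    stds[stds < 1e-12] = 1.0
    z = (X - means) / stds
    w, b = fit_logistic(z, y)

    p = 1.0 / (1.0 + np.exp(-(z @ w + b)))
    pred = p > 0.5
    sens = (pred & (y == 1)).sum() / (y == 1).sum()
    spec = (~pred & (y == 0)).sum() / (y == 0).sum()
    print(f"training: n={len(y)} sensitivity={sens:.3f} specificity={spec:.3f}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps({
        "weights": list(w),
        "bias": float(b),
        "feature_means": list(means),
        "feature_stds": list(stds),
        "training_seeds": train_seeds,
        "n_per_class": 8,
    }, indent=1))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
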
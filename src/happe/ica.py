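"""Extended Infomax independent component analysis.

The decomposition stage shared by wavelet-enhanced cleaning and
component rejection.  Extended Infomax adapts the contrast function to
each source's kurtosis sign, so it separates subgaussian sources
(residual mains noise) as well as the supergaussian sources (blinks,
muscle bursts, most neural rhythms) that plain Infomax handles.

ICA is seed-dependent: the weight matrix is randomly initialized and the
training order of sample blocks is shuffled, so the seed is a mandatory
argument and is stored on the returned :class:`Decomposition`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Decomposition", "run_extended_infomax", "project_without_components"]

_ANNEAL_DEG = 60.0
_ANNEAL_FACTOR = 0.98
_W_STOP = 1e-7
_MAX_ITER = 512
_EXT_POINTS = 6000          # subsample size for kurtosis-sign re-estimation
_MAX_WEIGHT = 1e8


@dataclass
class Decomposition:
    """Result of an ICA decomposition of a channels x samples matrix.

    ``sources = unmixing @ (data - means)`` and
    ``data ~= mixing @ sources + means``.  When the data are rank
    deficient the decomposition lives in the effective-rank subspace and
    ``n_components < n_channels``.
    """

    unmixing: np.ndarray         # (r, C)
    mixing: np.ndarray           # (C, r)
    sources: np.ndarray          # (r, N)
    sphering: np.ndarray         # (r, C)
    channel_ids: list[str]
    means: np.ndarray            # (C,)
    seed: int
    converged: bool
    n_iter: int

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.mixing @ self.sources + self.means[:, None]


def _sphere(data: np.ndarray, rank_tol: float = 1e-9):
    """PCA whitening at full effective rank."""
    cov = data @ data.T / data.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * evals[0]
    r = int(keep.sum())
    if r < data.shape[0]:
        warnings.warn(
            f"rank-deficient data: reducing {data.shape[0]} channels to "
            f"effective rank {r}", RuntimeWarning, stacklevel=3)
    sph = (evecs[:, :r] / np.sqrt(evals[:r])).T      # (r, C)
    return sph


def run_extended_infomax(data: np.ndarray, seed: int,
                         channel_ids: list[str] | None = None,
                         max_iter: int = _MAX_ITER,
                         w_stop: float = _W_STOP) -> Decomposition:
    """Decompose ``data`` (channels x samples) with extended Infomax.

    Natural-gradient learning on blocks of sphered samples with online
    kurtosis-sign switching; the learning rate anneals when successive
    update directions differ by more than 60 degrees.  Deterministic for
    a fixed seed.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(n_ch)]
    budget = 30 * n_ch * n_ch
    if n_samp < budget:
        warnings.warn(
            f"{n_samp} samples for {n_ch} channels is below the 30*C^2 "
            f"budget ({budget}); decomposition may be unstable",
            RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)

    means = data.mean(axis=1)
    centered = data - means[:, None]
    sph = _sphere(centered)
    x = sph @ centered                              # (r, N), white
    r = x.shape[0]

    # random orthogonal initial weights
    q, _ = np.linalg.qr(rng.standard_normal((r, r)))
    w = q
    block = int(np.ceil(min(5 * np.log(n_samp), 0.3 * n_samp)))
    lrate = 0.00065 / np.log(max(r, 2))
    signs = np.ones(r)                               # +1 supergaussian
    eye = np.eye(r)
    old_dw = None
    converged = False
    n_iter = 0
    w_prev = w.copy()

    for n_iter in range(1, max_iter + 1):
        perm = rng.permutation(n_samp)
        for s0 in range(0, n_samp - block + 1, block):
            xb = x[:, perm[s0:s0 + block]]
            u = w @ xb
            y = np.tanh(u)
            d = (block * eye
                 - (signs[:, None] * y) @ u.T
                 - u @ u.T)
            w = w + lrate * d @ w
            if not np.isfinite(w).all() or np.abs(w).max() > _MAX_WEIGHT:
                # blow-up: restart with a smaller rate
                lrate *= 0.5
                q, _ = np.linalg.qr(rng.standard_normal((r, r)))
                w = q
                old_dw = None
                break
        else:
            # kurtosis-sign re-estimation on a subsample
            take = min(_EXT_POINTS, n_samp)
            idx = rng.choice(n_samp, take, replace=False)
            u = w @ x[:, idx]
            m2 = (u ** 2).mean(axis=1)
            m4 = (u ** 4).mean(axis=1)
            kurt = m4 / np.maximum(m2 ** 2, 1e-300) - 3.0
            signs = np.sign(kurt)
            signs[signs == 0] = 1.0

            dw = w - w_prev
            wchange = float(np.sqrt((dw ** 2).sum()))
            if old_dw is not None:
                denom = (np.linalg.norm(dw) * np.linalg.norm(old_dw))
                if denom > 0:
                    cosang = float((dw * old_dw).sum() / denom)
                    angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if angle > _ANNEAL_DEG:
                        lrate *= _ANNEAL_FACTOR
            old_dw = dw
            w_prev = w.copy()
            if wchange < w_stop:
                converged = True
                break

    unmixing = w @ sph                               # (r, C)
    mixing = np.linalg.pinv(unmixing)                # (C, r)
    sources = unmixing @ centered
    return Decomposition(
        unmixing=unmixing, mixing=mixing, sources=sources, sphering=sph,
        channel_ids=list(channel_ids), means=means, seed=int(seed),
        converged=converged, n_iter=n_iter,
    )


def project_without_components(dec: Decomposition,
                               drop: list[int] | set[int]) -> np.ndarray:
    """Channel-space reconstruction with the listed components removed."""
    drop = set(int(i) for i in drop)
    bad = [i for i in drop if not 0 <= i < dec.n_components]
    if bad:
        raise ValueError(f"component ids out of range: {sorted(bad)}")
    keep = [i for i in range(dec.n_components) if i not in drop]
    if not keep:
        warnings.warn("all components dropped: returning channel means",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(dec.mixing @ dec.sources) + dec.means[:, None]
    return dec.mixing[:, keep] @ dec.sources[keep, :] + dec.means[:, None]
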
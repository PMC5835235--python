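"""Automated independent-component artifact classification and rejection.

Each ICA component is scored on six features spanning temporal, spectral
and spatial information -- mean local skewness, log alpha-band power,
the 1/f fit exponent (lambda) and its fit error, the scalp-map range
within pattern, and the current density norm of a minimum-norm inverse
solution on a spherical head model.  A logistic head maps the
standardized feature vector to an artifact probability p in [0, 1];
components with p > 0.5 are rejected and the remainder re-projected to
channel space.

The classifier weights shipped in ``data/classifier_weights.json`` are
calibrated on the labelled synthetic component corpus by
``scripts/calibrate_classifier.py`` (seeded, reproducible); externally
trained weights can be loaded through the same JSON schema.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import Montage, Recording, TEN_TWENTY_LABELS
from .ica import Decomposition, project_without_components

__all__ = [
    "ComponentEvaluation",
    "HeadModel",
    "ClassifierWeights",
    "FEATURE_NAMES",
    "mean_local_skewness",
    "log_alpha_power",
    "fit_one_over_f",
    "range_within_pattern",
    "current_density_norm",
    "extract_features",
    "classify_components",
    "reject_and_project",
    "percent_variance_kept",
    "load_default_weights",
]

FEATURE_NAMES = (
    "mean_local_skewness",
    "log_alpha_power",
    "lambda",
    "fit_error",
    "range_within_pattern",
    "current_density_norm",
)

#: Frequencies (Hz) sampled for the 1/f spectral fit.
ONE_OVER_F_FREQS = (2.0, 5.0, 8.0, 13.0, 30.0, 75.0)

_RANGE_FLOOR = 1e-12


@dataclass
class ComponentEvaluation:
    component: int
    features: dict[str, float]
    artifact_probability: float
    rejected: bool


# ------------------------------------------------------------ features

def mean_local_skewness(source: np.ndarray, fs: float,
                        window_s: float = 15.0) -> float:
    """Mean over consecutive 15-s windows of the absolute sample skewness.

    Blink trains, electrode pops and other transient artifacts make a
    component's amplitude distribution locally asymmetric.  A trailing
    partial window of at least 5 s is included; shorter remainders are
    dropped.  Windows with zero variance contribute 0.
    """
    x = np.asarray(source, dtype=float)
    win = int(round(window_s * fs))
    if x.size < win:
        win = x.size
    vals = []
    for s0 in range(0, x.size, win):
        seg = x[s0:s0 + win]
        if seg.size < win and seg.size < 5.0 * fs:
            break
        if seg.std() < 1e-12:
            vals.append(0.0)
        else:
            vals.append(abs(float(stats.skew(seg))))
    return float(np.mean(vals)) if vals else 0.0


def _welch(source: np.ndarray, fs: float):
    nper = min(int(round(2.0 * fs)), source.size)
    return sps.welch(source, fs, window="hamming", nperseg=nper,
                     noverlap=nper // 2)


def log_alpha_power(source: np.ndarray, fs: float,
                    band: tuple[float, float] = (8.0, 13.0)) -> float:
    """Mean log10 Welch power in the alpha band (8-13 Hz)."""
    if fs <= 26.0:
        raise ValueError("sampling rate too low to resolve the alpha band")
    freqs, psd = _welch(np.asarray(source, float), fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.log10(np.maximum(psd[sel], 1e-300)).mean())


def fit_one_over_f(source: np.ndarray, fs: float,
                   sample_freqs: tuple[float, ...] = ONE_OVER_F_FREQS,
                   error_band: tuple[float, float] = (8.0, 15.0)
                   ) -> tuple[float, float]:
    """Exponent and fit error of a 1/f power-law fit to the spectrum.

    The log10 spectrum is sampled at six frequencies and fit with
    ``log P = a - lambda * log f``.  Cerebral components follow the
    power law (lambda near 1); muscle activity rises at high
    frequencies (small or negative lambda).  The fit error is the mean
    squared residual of the fitted line against the observed log
    spectrum restricted to 8-15 Hz, where the alpha peak and the
    alpha-to-beta transition make artifact spectra deviate most.
    """
    x = np.asarray(source, dtype=float)
    freqs, psd = _welch(x, fs)
    nyq = fs / 2.0
    pts = [min(f, nyq - 5.0) for f in sample_freqs]
    logp = np.array([
        math.log10(max(float(np.interp(f, freqs, psd)), 1e-300))
        for f in pts
    ])
    logf = np.log10(pts)
    design = np.column_stack([np.ones_like(logf), -logf])
    (a, lam), *_ = np.linalg.lstsq(design, logp, rcond=None)
    sel = (freqs >= error_band[0]) & (freqs <= error_band[1])
    fitted = a - lam * np.log10(np.maximum(freqs[sel], 1e-12))
    obs = np.log10(np.maximum(psd[sel], 1e-300))
    fit_error = float(np.mean((obs - fitted) ** 2))
    return float(lam), fit_error


def range_within_pattern(scalp_map: np.ndarray) -> float:
    """Log range of the unit-norm scalp map.

    Focal maps (single-electrode spikes, periocular blink fields) have a
    large spread between the largest and smallest activation; smooth
    dipolar cerebral maps have a small one.
    """
    v = np.asarray(scalp_map, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("scalp map contains non-finite values")
    norm = np.linalg.norm(v)
    if norm < _RANGE_FLOOR:
        return math.log(_RANGE_FLOOR)
    v = v / norm
    return math.log(max(float(v.max() - v.min()), _RANGE_FLOOR))


# ------------------------------------------------------------ head model

def _legendre_pair(nmax: int, x: np.ndarray):
    """P_n(x) and P_n^1(x) for n = 0..nmax by upward recurrence."""
    p = np.zeros((nmax + 1,) + x.shape)
    p1 = np.zeros_like(p)
    p[0] = 1.0
    if nmax >= 1:
        p[1] = x
        s = np.sqrt(np.maximum(1.0 - x * x, 0.0))
        p1[1] = -s  # Condon-Shortley convention
    for n in range(2, nmax + 1):
        p[n] = ((2 * n - 1) * x * p[n - 1] - (n - 1) * p[n - 2]) / n
        p1[n] = ((2 * n - 1) * x * p1[n - 1] - n * p1[n - 2]) / (n - 1)
    return p, p1


def _sphere_dipole_potential(electrodes: np.ndarray, dip_pos: np.ndarray,
                             dip_mom: np.ndarray, nmax: int = 60
                             ) -> np.ndarray:
    """Surface potential of a dipole inside a homogeneous unit sphere.

    Series solution for an insulated sphere: with f = |r0|, cos(gamma)
    the electrode-dipole angle, p_r / p_t the radial / tangential moment
    components,

        V = sum_n (2n+1)/n * f^(n-1) * (n p_r P_n + p_t P_n^1) / (4 pi)
    """
    e = np.asarray(electrodes, float)
    r0 = np.asarray(dip_pos, float)
    f = np.linalg.norm(r0)
    if f < 1e-9:
        rhat = np.array([0.0, 0.0, 1.0])
    else:
        rhat = r0 / f
    cosg = np.clip(e @ rhat, -1.0, 1.0)
    # tangential unit vector at the dipole, in the dipole-electrode plane,
    # pointing toward the electrode
    tvec = e - cosg[:, None] * rhat[None, :]
    tnorm = np.linalg.norm(tvec, axis=1)
    ok = tnorm > 1e-9
    tvec[ok] /= tnorm[ok, None]
    tvec[~ok] = 0.0
    p_r = float(dip_mom @ rhat)
    p_t = tvec @ dip_mom
    p, p1 = _legendre_pair(nmax, cosg)
    v = np.zeros(e.shape[0])
    for n in range(1, nmax + 1):
        v += ((2 * n + 1) / n) * f ** (n - 1) * (
            n * p_r * p[n] - p_t * p1[n])
    return v / (4.0 * math.pi)


@dataclass
class HeadModel:
    """Single-sphere analytic leadfield on a shell of grid dipoles."""

    positions: np.ndarray        # (n_elec, 3) unit sphere
    leadfield: np.ndarray        # (n_elec, 3 * n_dipoles)
    alpha: float                 # Tikhonov constant for the inverse
    channel_labels: list[str]

    @classmethod
    def build(cls, montage: Montage,
              labels: tuple[str, ...] | list[str] = TEN_TWENTY_LABELS,
              n_dipoles: int = 200, shell_radius: float = 0.8,
              alpha_scale: float = 1e-4, seed: int = 20) -> "HeadModel":
        chan = [montage.ten_twenty_map.get(l, l) for l in labels]
        missing = [c for c in chan if c not in montage.positions]
        if missing:
            raise ValueError(f"head model channels missing: {missing}")
        pos = montage.position_array(chan)
        rng = np.random.default_rng(seed)
        grid = rng.standard_normal((n_dipoles, 3))
        grid /= np.linalg.norm(grid, axis=1, keepdims=True)
        grid *= shell_radius
        cols = []
        eye3 = np.eye(3)
        for g in grid:
            for k in range(3):
                cols.append(_sphere_dipole_potential(pos, g, eye3[k]))
        lf = np.column_stack(cols)
        alpha = alpha_scale * np.trace(lf @ lf.T) / pos.shape[0]
        return cls(pos, lf, float(alpha), chan)

    def forward(self, dip_pos: np.ndarray, dip_mom: np.ndarray) -> np.ndarray:
        return _sphere_dipole_potential(self.positions, dip_pos, dip_mom)


def current_density_norm(scalp_map: np.ndarray, head: HeadModel) -> float:
    """Log norm of the minimum-norm distributed source estimate.

    ``j = L^T (L L^T + alpha I)^-1 v`` for the unit-norm map ``v``.
    Cerebral (dipolar) maps are explained by compact source estimates;
    non-physiological maps need large, complex ones.
    """
    v = np.asarray(scalp_map, dtype=float)
    if v.shape[0] != head.positions.shape[0]:
        raise ValueError(
            f"map has {v.shape[0]} channels, head model "
            f"{head.positions.shape[0]}")
    norm = np.linalg.norm(v)
    if norm < _RANGE_FLOOR:
        raise ValueError("degenerate all-zero scalp map")
    v = v / norm
    lf = head.leadfield
    gram = lf @ lf.T + head.alpha * np.eye(lf.shape[0])
    j = lf.T @ np.linalg.solve(gram, v)
    return float(np.log(np.linalg.norm(j)))


# ------------------------------------------------------------ classifier

@dataclass
class ClassifierWeights:
    """Logistic head over standardized features: p = sigmoid(w.z + b)."""

    weights: np.ndarray          # (6,)
    bias: float
    feature_means: np.ndarray    # (6,)
    feature_stds: np.ndarray     # (6,)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierWeights":
        return cls(
            weights=np.asarray(d["weights"], float),
            bias=float(d["bias"]),
            feature_means=np.asarray(d["feature_means"], float),
            feature_stds=np.asarray(d["feature_stds"], float),
        )

    def probability(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.feature_means) / self.feature_stds
        logit = z @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-logit))


def load_default_weights() -> ClassifierWeights:
    ref = resources.files("happe.data").joinpath("classifier_weights.json")
    return ClassifierWeights.from_dict(json.loads(ref.read_text()))


def extract_features(source: np.ndarray, scalp_map: np.ndarray, fs: float,
                     head: HeadModel) -> np.ndarray:
    """Six-feature vector for one component (order: FEATURE_NAMES)."""
    lam, fit_err = fit_one_over_f(source, fs)
    return np.array([
        mean_local_skewness(source, fs),
        log_alpha_power(source, fs),
        lam,
        fit_err,
        range_within_pattern(scalp_map),
        current_density_norm(scalp_map, head),
    ])


def classify_components(dec: Decomposition, montage: Montage, fs: float,
                        classifier: ClassifierWeights | None = None,
                        head: HeadModel | None = None,
                        ten_twenty: tuple[str, ...] = TEN_TWENTY_LABELS,
                        ) -> list[ComponentEvaluation]:
    """Score every component of ``dec``; reject when p > 0.5 (strict).

    Scalp maps are the mixing-matrix columns restricted to the channels
    carrying the 10-20 positions.  If bad-channel removal took out more
    than 4 of the 19, spatial features are unreliable and this raises.
    """
    classifier = classifier or load_default_weights()
    mapped = [montage.ten_twenty_map.get(l, l) for l in ten_twenty]
    present = [c for c in mapped if c in dec.channel_ids]
    if len(mapped) - len(present) > 4:
        raise ValueError(
            f"only {len(present)} of the {len(mapped)} 10-20 channels "
            f"remain; component scalp maps are unreliable")
    if head is None or head.channel_labels != present:
        head = HeadModel.build(montage, labels=present)
    rows = [dec.channel_ids.index(c) for c in present]
    evals = []
    for i in range(dec.n_components):
        fvec = extract_features(dec.sources[i], dec.mixing[rows, i], fs, head)
        p = float(classifier.probability(fvec))
        evals.append(ComponentEvaluation(
            component=i,
            features=dict(zip(FEATURE_NAMES, fvec)),
            artifact_probability=p,
            rejected=bool(p > 0.5),
        ))
    return evals


def reject_and_project(rec: Recording, dec: Decomposition,
                       evals: list[ComponentEvaluation]) -> Recording:
    """Remove rejected components and return the cleaned recording."""
    drop = [e.component for e in evals if e.rejected]
    data = project_without_components(dec, drop)
    return rec.with_step(
        f"reject_components({len(drop)} of {dec.n_components})", data=data)


def percent_variance_kept(pre: Recording | np.ndarray,
                          post: Recording | np.ndarray) -> float:
    """Share of signal variance retained across all electrodes.

    ``100 * (1 - var(pre - post) / var(pre))`` with variances pooled
    over every channel and sample.
    """
    a = pre.data if isinstance(pre, Recording) else np.asarray(pre, float)
    b = post.data if isinstance(post, Recording) else np.asarray(post, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = np.var(a)
    if denom == 0:
        return 100.0
    return float(100.0 * (1.0 - np.var(a - b) / denom))
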
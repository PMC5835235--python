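"""Electrode layouts: builtin generic montages and sfp-style file loading.

The builtin layouts place the 19 International 10-20 labels at their
standard arc positions on the unit sphere (nasion-inion and ear-to-ear
arcs of 180 degrees, circumferential ring at 72 degrees from the vertex)
and fill the remaining electrode count with a deterministic spiral over
the upper head surface, labelled ``E1``, ``E2``, ...  They stand in for
vendor net layouts, which users supply as "label x y z" text files.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .core import ConfigurationError, Montage, TEN_TWENTY_LABELS

__all__ = ["load_montage", "builtin_montage", "standard_1020_positions"]

_DEG = math.pi / 180.0


def _sph(theta_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector at polar angle theta from vertex, azimuth from +y (nose),
    positive azimuth toward the left ear (-x)."""
    t, a = theta_deg * _DEG, az_deg * _DEG
    return np.array([-math.sin(t) * math.sin(a),
                     math.sin(t) * math.cos(a),
                     math.cos(t)])


def _slerp(p: np.ndarray, q: np.ndarray, f: float) -> np.ndarray:
    w = math.acos(float(np.clip(p @ q, -1.0, 1.0)))
    if w < 1e-12:
        return p.copy()
    return (math.sin((1 - f) * w) * p + math.sin(f * w) * q) / math.sin(w)


def standard_1020_positions() -> dict[str, np.ndarray]:
    """Unit-sphere positions for the 10-20 scalp labels (plus Cz, Oz).

    Midline electrodes sit every 20% of the 180-degree nasion-inion arc;
    the circumferential ring lies 72 degrees from the vertex with labels
    every 10% of the circumference; F3/F4 and P3/P4 are placed midway
    along the arcs joining the midline and ring electrodes of their row.
    """
    pos: dict[str, np.ndarray] = {}
    # midline: theta from vertex, front (+) / back (-)
    pos["Cz"] = _sph(0, 0)
    pos["Fz"] = _sph(36, 0)
    pos["Pz"] = _sph(36, 180)
    pos["Fpz"] = _sph(72, 0)
    pos["Oz"] = _sph(72, 180)
    # circumferential ring at theta = 72; azimuth from nose, + = left
    ring = {"Fp1": 18, "F7": 54, "T3": 90, "T5": 126, "O1": 162}
    for label, az in ring.items():
        pos[label] = _sph(72, az)
        right = {"Fp1": "Fp2", "F7": "F8", "T3": "T4",
                 "T5": "T6", "O1": "O2"}[label]
        pos[right] = _sph(72, -az)
    # central row: ear-to-ear arc, 20% steps
    pos["C3"] = _sph(36, 90)
    pos["C4"] = _sph(36, -90)
    # interior frontal/parietal: midway along Fz-F7 / Pz-T5 arcs
    pos["F3"] = _slerp(pos["Fz"], pos["F7"], 0.5)
    pos["F4"] = _slerp(pos["Fz"], pos["F8"], 0.5)
    pos["P3"] = _slerp(pos["Pz"], pos["T5"], 0.5)
    pos["P4"] = _slerp(pos["Pz"], pos["T6"], 0.5)
    return pos


def _spiral_positions(n: int, theta_max: float = 115.0) -> list[np.ndarray]:
    """Deterministic Fibonacci-style spiral over the head surface."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    cos_max = math.cos(theta_max * _DEG)
    out = []
    for k in range(n):
        z = 1.0 - (1.0 - cos_max) * (k + 0.5) / n
        r = math.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * k
        out.append(np.array([r * math.cos(phi), r * math.sin(phi), z]))
    return out


def builtin_montage(name: str,
                    ten_twenty: tuple[str, ...] = TEN_TWENTY_LABELS) -> Montage:
    """Builtin layout by name: ``generic128``, ``generic64``, ``standard19``.

    The 10-20 labels are carried verbatim; extra electrodes are ``E<k>``.
    """
    counts = {"generic128": 128, "generic64": 64, "standard19": 19}
    if name not in counts:
        raise ConfigurationError(
            f"unknown builtin montage {name!r}; options: {sorted(counts)}"
        )
    n = counts[name]
    std = standard_1020_positions()
    missing = [l for l in ten_twenty if l not in std]
    if missing:
        raise ConfigurationError(
            f"10-20 labels without a standard position: {missing}"
        )
    positions = {l: std[l] for l in ten_twenty}
    n_extra = n - len(positions)
    if n_extra > 0:
        anchors = np.array(list(positions.values()))
        k = 1
        # oversample the spiral, keep points not colliding with anchors
        for cand in _spiral_positions(3 * n_extra + 40):
            if len(positions) >= n:
                break
            d = np.linalg.norm(anchors - cand, axis=1).min()
            if d > 0.12:
                positions[f"E{k}"] = cand
                anchors = np.vstack([anchors, cand])
                k += 1
        if len(positions) < n:  # pragma: no cover - generous oversampling
            raise ConfigurationError(f"could not place {n} electrodes")
    return Montage(positions, {l: l for l in ten_twenty})


def load_montage(source: str | Path,
                 ten_twenty_map: dict[str, str] | None = None,
                 ten_twenty: tuple[str, ...] = TEN_TWENTY_LABELS) -> Montage:
    """Load a montage from a builtin name or an sfp-style text file.

    File format: one ``label x y z`` line per electrode (whitespace
    separated; ``#`` comments allowed).  Positions are projected to the
    unit sphere.  For files, ``ten_twenty_map`` defaults to the identity
    on the 19 10-20 labels, which must then all be present.
    """
    if isinstance(source, str) and not Path(source).exists():
        if source.startswith("generic") or source.startswith("standard"):
            return builtin_montage(source, ten_twenty)
        raise ConfigurationError(f"montage {source!r}: no such file or builtin")
    path = Path(source)
    positions: dict[str, np.ndarray] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ConfigurationError(
                f"{path}:{line_no}: expected 'label x y z', got {line!r}"
            )
        positions[parts[0]] = np.array([float(v) for v in parts[1:]])
    if ten_twenty_map is None:
        ten_twenty_map = {l: l for l in ten_twenty}
    absent = [l for l, ch in ten_twenty_map.items() if ch not in positions]
    if absent:
        raise ConfigurationError(
            f"montage {path} is missing mapped 10-20 channels: {absent}"
        )
    return Montage(positions, ten_twenty_map)
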
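"""Core domain types: recordings, montages, and the ICA sample budget.

A :class:`Recording` is a channels x samples matrix in microvolts together
with its sampling rate, channel labels, optional montage, event markers and
a provenance history of the processing steps applied so far.  All pipeline
stages consume and return Recordings.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Recording",
    "Montage",
    "SampleBudget",
    "TEN_TWENTY_LABELS",
    "ica_sample_budget",
    "required_seconds",
    "select_channel_subset",
]

#: The 19 International 10-20 scalp labels used for component scalp maps.
#: 18 canonical positions (Cz, the usual recording reference, excluded)
#: plus Fpz.  Overridable wherever a montage is constructed.
TEN_TWENTY_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "Fpz",
)


class ConfigurationError(ValueError):
    """Invalid montage, subset or pipeline configuration."""


@dataclass
class Montage:
    """Electrode positions on the unit sphere plus the 10-20 label mapping.

    Parameters
    ----------
    positions
        Map from channel label to a head-centered (x, y, z) position.
        Positions are normalized to the unit sphere on construction.
    ten_twenty_map
        Map from each of the 19 10-20 labels to the layout channel id that
        carries it.  For layouts that use the 10-20 names directly this is
        the identity map.
    """

    positions: dict[str, np.ndarray]
    ten_twenty_map: dict[str, str]

    def __post_init__(self) -> None:
        normed = {}
        for label, pos in self.positions.items():
            p = np.asarray(pos, dtype=float).reshape(3)
            n = np.linalg.norm(p)
            if n == 0:
                raise ConfigurationError(f"electrode {label!r} at the origin")
            normed[label] = p / n
        self.positions = normed
        if len(self.ten_twenty_map) != 19:
            raise ConfigurationError(
                f"ten_twenty_map must have exactly 19 entries, got "
                f"{len(self.ten_twenty_map)}"
            )
        missing = [v for v in self.ten_twenty_map.values()
                   if v not in self.positions]
        if missing:
            raise ConfigurationError(
                f"10-20 mapped channels absent from montage: {missing}"
            )

    def position_array(self, labels) -> np.ndarray:
        """(len(labels), 3) array of unit-sphere positions."""
        return np.array([self.positions[l] for l in labels])


@dataclass
class Recording:
    """Multichannel EEG segment in microvolts."""

    data: np.ndarray                       # (n_channels, n_samples), uV
    sample_rate: float
    channel_ids: list[str]
    montage: Montage | None = None
    events: list[tuple[str, int]] = field(default_factory=list)
    history: list[str] = field(default_factory=list)
    input_kind: str = "rest"               # "rest" | "event"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        for label, idx in self.events:
            if not 0 <= idx < self.n_samples:
                raise ValueError(f"event {label!r} at sample {idx} out of range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_ids=list(self.channel_ids),
            events=list(self.events),
            history=list(self.history),
        )

    def with_step(self, description: str, data: np.ndarray | None = None,
                  channel_ids: list[str] | None = None) -> "Recording":
        """New Recording with ``description`` appended to the history."""
        return replace(
            self,
            data=self.data.copy() if data is None else data,
            channel_ids=list(self.channel_ids if channel_ids is None
                             else channel_ids),
            events=list(self.events),
            history=list(self.history) + [description],
        )


@dataclass(frozen=True)
class SampleBudget:
    """Outcome of the 30*C^2 minimum-samples rule for ICA stability."""

    n_channels: int
    n_samples_available: int
    n_samples_required: int
    sufficient: bool


def ica_sample_budget(n_channels: int, n_samples: int) -> SampleBudget:
    """Minimum data samples for a stable ICA decomposition of C channels.

    A decomposition of C channels needs at least ``30 * C**2`` samples;
    shorter recordings call for selecting a channel subset first.

    >>> ica_sample_budget(128, 0).n_samples_required
    491520
    """
    n_channels = int(n_channels)
    n_samples = int(n_samples)
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    required = 30 * n_channels * n_channels
    return SampleBudget(n_channels, n_samples, required, n_samples >= required)


def required_seconds(n_channels: int, sample_rate: float) -> float:
    """Seconds of recording needed to satisfy the 30*C^2 sample budget."""
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    return 30 * int(n_channels) ** 2 / float(sample_rate)


def select_channel_subset(rec: Recording, subset: list[str],
                          ten_twenty: tuple[str, ...] | None = None) -> Recording:
    """Restrict a recording to ``subset`` channels, in the requested order.

    The subset must contain the mapped 10-20 channels (needed later for
    component scalp maps); channels left out are removed for good.
    """
    unknown = [l for l in subset if l not in rec.channel_ids]
    if unknown:
        raise ConfigurationError(f"unknown channel labels: {unknown}")
    if len(set(subset)) != len(subset):
        raise ConfigurationError("duplicate labels in channel subset")
    if rec.montage is not None:
        mapped = rec.montage.ten_twenty_map
        want = ten_twenty if ten_twenty is not None else tuple(mapped.keys())
        missing = [l for l in want
                   if mapped.get(l, l) not in subset]
        if missing:
            raise ConfigurationError(
                f"channel subset must include the 10-20 channels; missing: "
                f"{missing}"
            )
    idx = [rec.channel_ids.index(l) for l in subset]
    return rec.with_step(
        f"select_channel_subset({len(subset)} of {rec.n_channels} channels)",
        data=rec.data[idx].copy(),
        channel_ids=list(subset),
    )

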
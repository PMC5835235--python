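"""Optional segmentation with artifact handling per segment.

Continuous (resting) data are cut into fixed-length windows from the
start of the file; event data are windowed around matching markers.
Two mutually exclusive follow-ups are offered:

* :func:`reject_segments` -- drop whole segments that breach an
  amplitude threshold (default +/-40 uV, reflecting the small residual
  amplitudes after wavelet and component cleaning) or whose
  joint-probability statistics are outliers (catches residual
  high-frequency muscle artifact that stays under the amplitude bound);
* :func:`interpolate_within_segments` -- for short files where whole-
  segment rejection would be too costly, spherical-spline interpolate
  individual bad channels per segment, judged on four criteria
  (variance, median gradient, amplitude range, deviation from mean
  amplitude).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .channels import _jointprob_statistic, spherical_spline_matrix
from .core import Montage, Recording

__all__ = [
    "SegmentSet",
    "segment_rest",
    "segment_events",
    "reject_segments",
    "interpolate_within_segments",
]


@dataclass
class SegmentSet:
    """Half-open segments [start, start + n_per_seg) of a parent recording."""

    recording: Recording
    seg_len_s: float
    starts: list[int]
    rejected: list[bool] = field(default_factory=list)
    reasons: list[set[str]] = field(default_factory=list)
    interpolated: list[list[str]] = field(default_factory=list)
    roi_channels: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not self.rejected:
            self.rejected = [False] * n
        if not self.reasons:
            self.reasons = [set() for _ in range(n)]
        if not self.interpolated:
            self.interpolated = [[] for _ in range(n)]

    @property
    def n_per_seg(self) -> int:
        return int(round(self.seg_len_s * self.recording.sample_rate))

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    @property
    def n_retained(self) -> int:
        return int(np.sum(~np.asarray(self.rejected, bool))) \
            if self.starts else 0

    def segment_data(self, i: int) -> np.ndarray:
        s0 = self.starts[i]
        return self.recording.data[:, s0:s0 + self.n_per_seg]

    def retained_recording(self) -> Recording:
        """Concatenation of the retained segments as a new Recording."""
        keep = [i for i in range(self.n_segments) if not self.rejected[i]]
        if not keep:
            raise ValueError("no segments retained")
        data = np.concatenate([self.segment_data(i) for i in keep], axis=1)
        return self.recording.with_step(
            f"retain_segments({len(keep)} of {self.n_segments})", data=data)


def segment_rest(rec: Recording, seg_len_s: float) -> SegmentSet:
    """Consecutive fixed-length windows from sample 0; partial tail dropped."""
    if seg_len_s <= 0:
        raise ValueError("segment length must be positive")
    n_per = int(round(seg_len_s * rec.sample_rate))
    starts = list(range(0, rec.n_samples - n_per + 1, n_per))
    if not starts:
        warnings.warn(
            f"segment length {seg_len_s:g} s exceeds the recording "
            f"({rec.duration:.3f} s): no segments", RuntimeWarning,
            stacklevel=2)
    return SegmentSet(rec, seg_len_s, starts)


def segment_events(rec: Recording, tags: list[str],
                   window: tuple[float, float]) -> SegmentSet:
    """One window ``[event + t_pre, event + t_post)`` per matching event.

    Windows extending past the recording bounds are skipped with a
    warning; overlap between neighbouring event windows is permitted.
    """
    if rec.input_kind != "event":
        raise ValueError("recording is not event-kind data")
    if not tags:
        raise ValueError("no event tags given")
    t_pre, t_post = window
    if t_post <= t_pre:
        raise ValueError("window end must exceed window start")
    fs = rec.sample_rate
    n_per = int(round((t_post - t_pre) * fs))
    starts = []
    skipped = 0
    for label, idx in rec.events:
        if label not in tags:
            continue
        s0 = idx + int(round(t_pre * fs))
        if s0 < 0 or s0 + n_per > rec.n_samples:
            skipped += 1
            continue
        starts.append(s0)
    if skipped:
        warnings.warn(f"{skipped} event window(s) out of bounds, skipped",
                      RuntimeWarning, stacklevel=2)
    return SegmentSet(rec, t_post - t_pre, starts)


def _jp_flags(values: np.ndarray, z_cut: float) -> np.ndarray:
    """Two-sided z > z_cut flags on the joint-probability statistic."""
    if not np.isfinite(z_cut):
        return np.zeros(values.shape, bool)
    stats = _jointprob_statistic(values.ravel()).reshape(values.shape)
    sd = stats.std()
    if sd < 1e-12:
        return np.zeros(values.shape, bool)
    return np.abs((stats - stats.mean()) / sd) > z_cut


def reject_segments(segs: SegmentSet, amp_lo: float = -40.0,
                    amp_hi: float = 40.0, z_cut: float = 3.0,
                    roi: list[str] | None = None) -> SegmentSet:
    """Flag segments by amplitude threshold and joint probability.

    A segment is marked when (a) any evaluated channel sample falls
    outside ``[amp_lo, amp_hi]``, (b) a channel's activity RMS in the
    segment is a joint-probability outlier against that channel's other
    segments (single-electrode probability), or (c) against the other
    channels within the same segment (electrode-group probability).
    All marks are applied simultaneously in one step.  With ``roi``
    only those channels are evaluated.
    """
    rec = segs.recording
    if roi:
        missing = [c for c in roi if c not in rec.channel_ids]
        if missing:
            raise ValueError(f"ROI channels not in recording: {missing}")
        rows = [rec.channel_ids.index(c) for c in roi]
    else:
        rows = list(range(rec.n_channels))
    n_seg = segs.n_segments
    cube = np.stack([segs.segment_data(i)[rows] for i in range(n_seg)])
    # (n_seg, n_roi, n_per)

    amp_flag = ((cube < amp_lo) | (cube > amp_hi)).any(axis=(1, 2))

    single_flag = np.zeros(n_seg, bool)
    group_flag = np.zeros(n_seg, bool)
    if n_seg >= 8:
        activity = np.sqrt((cube ** 2).mean(axis=2))      # (n_seg, n_roi)
        for c in range(activity.shape[1]):
            single_flag |= _jp_flags(activity[:, c], z_cut)
        for i in range(n_seg):
            if _jp_flags(activity[i, :], z_cut).any():
                group_flag[i] = True
    else:
        warnings.warn(
            "fewer than 8 segments: joint-probability rejection skipped, "
            "amplitude criterion only", RuntimeWarning, stacklevel=2)

    out = SegmentSet(rec, segs.seg_len_s, list(segs.starts),
                     roi_channels=list(roi) if roi else None)
    for i in range(n_seg):
        reasons = set(segs.reasons[i])
        if amp_flag[i]:
            reasons.add("amplitude")
        if single_flag[i]:
            reasons.add("jointprob_single")
        if group_flag[i]:
            reasons.add("jointprob_group")
        out.reasons[i] = reasons
        out.rejected[i] = segs.rejected[i] or bool(reasons)
        out.interpolated[i] = list(segs.interpolated[i])
    return out


def _segment_channel_criteria(seg: np.ndarray,
                              grand_mean: np.ndarray) -> np.ndarray:
    """Per-channel artifact criteria for one segment.

    Rows: variance, median absolute gradient, amplitude range,
    deviation of the segment-channel mean from the channel grand mean.
    """
    var = seg.var(axis=1)
    grad = np.median(np.abs(np.diff(seg, axis=1)), axis=1)
    rng_ = seg.max(axis=1) - seg.min(axis=1)
    dev = np.abs(seg.mean(axis=1) - grand_mean)
    return np.vstack([var, grad, rng_, dev])


def interpolate_within_segments(segs: SegmentSet, z_cut: float = 3.0,
                                montage: Montage | None = None,
                                min_ratio: float = 2.0) -> SegmentSet:
    """Interpolate per-segment bad channels instead of rejecting segments.

    Channels whose z-score on any of the four criteria exceeds ``z_cut``
    within a segment are rebuilt there (and only there) by spherical-
    spline interpolation from the segment's good channels.  A flagged
    channel must also deviate from the segment median of that criterion
    by at least a factor ``min_ratio`` -- a channel statistically
    detached but materially indistinguishable from its neighbours is
    left alone.
    """
    rec = segs.recording
    montage = montage or rec.montage
    if montage is None:
        raise ValueError("montage required for within-segment interpolation")
    data = rec.data.copy()
    n_per = segs.n_per_seg
    grand_mean = rec.data.mean(axis=1)
    out = SegmentSet(rec.with_step("interpolate_within_segments"),
                     segs.seg_len_s, list(segs.starts))
    out.recording.data[:] = data
    for i, s0 in enumerate(segs.starts):
        seg = data[:, s0:s0 + n_per]
        crit = _segment_channel_criteria(seg, grand_mean)
        bad = np.zeros(rec.n_channels, bool)
        for row in crit:
            sd = row.std()
            if sd < 1e-12:
                continue
            z_flag = np.abs((row - row.mean()) / sd) > z_cut
            med = np.median(row)
            if med > 1e-12:
                z_flag &= (row > min_ratio * med) | (row < med / min_ratio)
            bad |= z_flag
        bad_ids = [rec.channel_ids[k] for k in np.where(bad)[0]]
        if not bad_ids:
            continue
        good_ids = [c for c in rec.channel_ids if c not in bad_ids]
        if len(good_ids) < 4:
            warnings.warn(
                f"segment {i}: too few good channels to interpolate",
                RuntimeWarning, stacklevel=2)
            continue
        M = spherical_spline_matrix(
            montage.position_array(good_ids),
            montage.position_array(bad_ids))
        good_rows = [rec.channel_ids.index(c) for c in good_ids]
        interp = M @ seg[good_rows]
        for k, cid in enumerate(bad_ids):
            out.recording.data[rec.channel_ids.index(cid),
                               s0:s0 + n_per] = interp[k]
        out.interpolated[i] = bad_ids
    return out
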
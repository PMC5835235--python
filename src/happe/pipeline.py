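"""Pipeline orchestration, quality report, PSD export, cohort summary.

Stage order per file: read -> filter (band-pass iff fs >= 500 Hz) ->
channel-subset selection -> line-noise removal -> double-pass
bad-channel detection -> wavelet-enhanced ICA -> ICA with automated
component rejection -> optional segmentation branch -> bad-channel
interpolation -> re-referencing -> outputs.  One report row per file;
failures are isolated per file so a batch continues.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import channels as chn
from . import components as cmp
from . import segmentation as seg
from .core import Montage, Recording, TEN_TWENTY_LABELS, ica_sample_budget, \
    select_channel_subset
from .ica import run_extended_infomax
from .io import read_recording, write_recording
from .montage import load_montage
from .spectral import LineNoiseConfig, bandpass_if_high_rate, remove_line_noise
from .wavelet import wica_clean

__all__ = [
    "PipelineConfig",
    "REPORT_COLUMNS",
    "run_pipeline",
    "export_psd",
    "summarize_cohort",
]

log = logging.getLogger("happe")

#: Quality-report schema: one row per file.  Spellings are the sanitized
#: canonical metric names (metric definitions in docs/methods.md).
REPORT_COLUMNS = [
    "Filename",
    "File_length_in_sec",
    "Number_channels_userSelected",
    "Number_epochs_post_epoch_rejection",
    "Number_good_channels_selected",
    "Percent_good_channels_selected",
    "Interpolated_channel_IDs",
    "Number_ICs_rejected",
    "Percent_ICs_rejected",
    "Percent_variance_kept_of_post_waveleted_data",
    "Median_artifact_probability_of_kept_ICs",
    "Mean_artifact_probability_of_kept_ICs",
    "Range_artifact_probability_of_kept_ICs",
    "Min_artifact_probability_of_kept_ICs",
    "Max_artifact_probability_of_kept_ICs",
    "flags",
]


@dataclass
class PipelineConfig:
    """Validated run configuration; serialized next to the outputs."""

    input_kind: str = "rest"               # "rest" | "event"
    file_format: str = "native"            # "native" | "edf"
    montage: str = "generic128"
    channel_subset: list[str] | None = None
    ten_twenty: tuple[str, ...] = TEN_TWENTY_LABELS
    line_freq: float = 60.0
    line_clean: bool = True
    segment_mode: str = "none"             # "none" | "reject" | "interpolate"
    seg_len_s: float = 2.0
    event_tags: list[str] = field(default_factory=list)
    event_window: tuple[float, float] = (-0.5, 1.5)
    amp_threshold_uv: float = 40.0
    roi_channels: list[str] | None = None
    reference: str = "average"             # "average" or "channels"
    reference_channels: list[str] = field(default_factory=list)
    output_dir: str | Path = "happe_out"
    seed: int = 1
    emit_intermediates: bool = True
    semi_automated: bool = False           # export per-stage PSD tables
    ica_max_iter: int = 512

    def __post_init__(self) -> None:
        if self.input_kind not in ("rest", "event"):
            raise ValueError(f"input_kind must be rest|event, got "
                             f"{self.input_kind!r}")
        if self.segment_mode not in ("none", "reject", "interpolate"):
            raise ValueError(f"bad segment_mode {self.segment_mode!r}")
        if self.reference not in ("average", "channels"):
            raise ValueError(f"bad reference {self.reference!r}")
        if self.reference == "channels" and not self.reference_channels:
            raise ValueError("channel re-reference needs reference_channels")
        if self.input_kind == "event" and self.segment_mode != "none" \
                and not self.event_tags:
            raise ValueError("event segmentation needs event_tags")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ten_twenty" in d:
            d["ten_twenty"] = tuple(d["ten_twenty"])
        if "event_window" in d:
            d["event_window"] = tuple(d["event_window"])
        return cls(**d)

    def to_json(self) -> str:
        d = asdict(self)
        d["output_dir"] = str(d["output_dir"])
        return json.dumps(d, indent=1)


def export_psd(rec: Recording, path: str | Path,
               window_s: float = 2.0) -> None:
    """Write the per-channel Welch power spectrum as a CSV table.

    Columns: ``freq_hz`` then one column per channel (uV^2/Hz).  Serves
    the stage-wise inspection role of the interactive power-spectrum
    views in the semi-automated setting.
    """
    nper = min(int(round(window_s * rec.sample_rate)), rec.n_samples)
    freqs, psd = sps.welch(rec.data, rec.sample_rate, window="hamming",
                           nperseg=nper, noverlap=nper // 2, axis=1)
    df = pd.DataFrame(psd.T, columns=rec.channel_ids)
    df.insert(0, "freq_hz", freqs)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _kept_prob_stats(kept_probs: list[float]) -> dict[str, float]:
    if not kept_probs:
        return {k: float("nan") for k in
                ("Median", "Mean", "Range", "Min", "Max")}
    arr = np.asarray(kept_probs)
    return {
        "Median": float(np.median(arr)),
        "Mean": float(arr.mean()),
        "Range": float(arr.max() - arr.min()),
        "Min": float(arr.min()),
        "Max": float(arr.max()),
    }


def _process_one(rec: Recording, name: str, cfg: PipelineConfig,
                 montage: Montage, file_seed: int, out_dir: Path,
                 classifier) -> dict:
    flags: list[str] = []
    inter = out_dir / "intermediate"

    def save(stage: str, r: Recording) -> None:
        if cfg.emit_intermediates:
            write_recording(r, inter / f"{name}_{stage}.dat")
        if cfg.semi_automated:
            export_psd(r, out_dir / "psd" / f"{name}_{stage}_psd.csv")

    rec = Recording(rec.data, rec.sample_rate, list(rec.channel_ids),
                    montage=montage, events=list(rec.events),
                    history=list(rec.history), input_kind=cfg.input_kind)

    # 1. filtering (band-pass only for fast-sampled files)
    rec = bandpass_if_high_rate(rec)
    # 2. channel subset
    if cfg.channel_subset:
        rec = select_channel_subset(rec, cfg.channel_subset, cfg.ten_twenty)
    save("filtered", rec)
    n_user = rec.n_channels
    # 3. line noise
    if cfg.line_clean:
        rec = remove_line_noise(rec, LineNoiseConfig(
            target_freq=cfg.line_freq))
    # 4. bad channels (double pass); excluded until interpolation
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        bad = chn.detect_bad_channels(rec)
    for w in wlist:
        if "flagged bad" in str(w.message):
            flags.append("majority_bad_channels")
    good_ids = [c for c in rec.channel_ids if c not in bad.bad_ids]
    rec_good = select_channel_subset(
        Recording(rec.data, rec.sample_rate, rec.channel_ids,
                  events=rec.events, history=rec.history,
                  input_kind=rec.input_kind),
        good_ids)
    rec_good.montage = montage
    # 5. W-ICA
    post_wav, _, _ = wica_clean(rec_good, seed=file_seed,
                                ica_kwargs={"max_iter": cfg.ica_max_iter})
    save("wavclean", post_wav)
    # 6. ICA + automated component rejection
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dec = run_extended_infomax(post_wav.data, seed=file_seed + 1,
                                   channel_ids=post_wav.channel_ids,
                                   max_iter=cfg.ica_max_iter)
    if cfg.emit_intermediates:
        write_recording(post_wav, inter / f"{name}_ica.dat")
        (inter / f"{name}_ica_decomposition.json").write_text(json.dumps({
            "unmixing": dec.unmixing.tolist(),
            "mixing": dec.mixing.tolist(),
            "sphering": dec.sphering.tolist(),
            "channel_ids": dec.channel_ids,
            "seed": dec.seed,
            "converged": dec.converged,
            "n_iter": dec.n_iter,
        }))
    evals = cmp.classify_components(dec, montage, post_wav.sample_rate,
                                    classifier=classifier,
                                    ten_twenty=cfg.ten_twenty)
    post_rej = cmp.reject_and_project(post_wav, dec, evals)
    save("icaclean", post_rej)
    pct_var = cmp.percent_variance_kept(post_wav, post_rej)
    kept = [e.artifact_probability for e in evals if not e.rejected]
    n_rej = sum(e.rejected for e in evals)
    prob_stats = _kept_prob_stats(kept)

    # 7. optional segmentation branch
    n_epochs = float("nan")
    current = post_rej
    if cfg.segment_mode != "none":
        if cfg.input_kind == "event":
            segset = seg.segment_events(current, cfg.event_tags,
                                        cfg.event_window)
        else:
            segset = seg.segment_rest(current, cfg.seg_len_s)
        if cfg.segment_mode == "reject":
            segset = seg.reject_segments(
                segset, -cfg.amp_threshold_uv, cfg.amp_threshold_uv,
                roi=cfg.roi_channels)
            n_epochs = segset.n_retained
            current = segset.retained_recording()
        else:
            segset = seg.interpolate_within_segments(segset,
                                                     montage=montage)
            n_epochs = segset.n_segments
            current = segset.recording
        save("segmented", current)
    # 8. interpolate bad channels, restore user-selected order
    current = chn.interpolate_bad_channels(current, bad.bad_ids, montage)
    order = [c for c in rec.channel_ids if c in current.channel_ids]
    current = select_channel_subset(current, order)
    # 9. re-reference
    current = chn.rereference(current, cfg.reference,
                              cfg.reference_channels or None)
    write_recording(current, out_dir / "processed" / f"{name}_processed.dat")
    if cfg.semi_automated:
        export_psd(current, out_dir / "psd" / f"{name}_processed_psd.csv")

    n_good = len(good_ids)
    return {
        "Filename": name,
        "File_length_in_sec": rec.duration,
        "Number_channels_userSelected": n_user,
        "Number_epochs_post_epoch_rejection": n_epochs,
        "Number_good_channels_selected": n_good,
        "Percent_good_channels_selected": 100.0 * n_good / n_user,
        "Interpolated_channel_IDs": " ".join(bad.bad_ids),
        "Number_ICs_rejected": int(n_rej),
        "Percent_ICs_rejected": 100.0 * n_rej / dec.n_components,
        "Percent_variance_kept_of_post_waveleted_data": pct_var,
        "Median_artifact_probability_of_kept_ICs": prob_stats["Median"],
        "Mean_artifact_probability_of_kept_ICs": prob_stats["Mean"],
        "Range_artifact_probability_of_kept_ICs": prob_stats["Range"],
        "Min_artifact_probability_of_kept_ICs": prob_stats["Min"],
        "Max_artifact_probability_of_kept_ICs": prob_stats["Max"],
        "flags": ";".join(flags),
    }


def run_pipeline(cfg: PipelineConfig, files: list) -> pd.DataFrame:
    """Process a batch of files; returns the quality report (also saved).

    ``files`` may be paths (read with ``cfg.file_format``) or
    ``(name, Recording)`` pairs.  All files must share the channel
    layout.  If the configured subset fails the 30*C^2 ICA sample
    budget for the shortest file, this is a hard error before any file
    is processed.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "pipeline_config.json").write_text(cfg.to_json())
    montage = load_montage(cfg.montage, ten_twenty=cfg.ten_twenty)
    classifier = cmp.load_default_weights()

    loaded: list[tuple[str, Recording | Exception]] = []
    for f in files:
        if isinstance(f, tuple):
            loaded.append(f)
        else:
            p = Path(f)
            try:
                loaded.append((p.stem, read_recording(p, cfg.file_format)))
            except Exception as exc:       # isolated per file
                loaded.append((p.stem, exc))

    ok = [(n, r) for n, r in loaded if isinstance(r, Recording)]
    if ok:
        n_sub = len(cfg.channel_subset) if cfg.channel_subset \
            else min(r.n_channels for _, r in ok)
        shortest = min(ok, key=lambda nr: nr[1].n_samples)
        budget = ica_sample_budget(n_sub, shortest[1].n_samples)
        if not budget.sufficient:
            raise ValueError(
                f"ICA sample budget not met for {shortest[0]!r}: "
                f"{n_sub} channels require {budget.n_samples_required} "
                f"samples, file has {budget.n_samples_available}; select "
                f"a smaller channel subset")

    rows = []
    for i, (name, rec) in enumerate(loaded):
        if isinstance(rec, Exception):
            log.error("skipping %s: %s", name, rec)
            continue
        try:
            rows.append(_process_one(rec, name, cfg, montage,
                                     cfg.seed + 1000 * i, out_dir,
                                     classifier))
        except Exception as exc:
            log.error("failed to process %s: %s", name, exc)
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report.to_csv(out_dir / "happe_report.csv", index=False)
    return report


def summarize_cohort(report: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics (mean, std, quartiles) per report metric."""
    numeric = report.select_dtypes(include=[np.number])
    rows = {
        "Mean": numeric.mean(),
        "Std": numeric.std(ddof=1),
        "25%": numeric.quantile(0.25),
        "50%": numeric.quantile(0.50),
        "75%": numeric.quantile(0.75),
    }
    return pd.DataFrame(rows).T
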
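"""Device-specific EMG conditioning and envelope extraction.

Pipeline (fixed order):

wired:     20 Hz high-pass (zero phase) -> rectify -> epoch/bin (1000 ms)
           -> baseline-correct -> standardize within individual
wearable:  20 Hz high-pass -> subtract 51-point moving average -> rectify
           -> epoch/bin -> [baseline-correct] -> standardize

Baseline correction subtracts each trial's mean rectified envelope over the
10-s pre-stimulus window and is skipped in the no-baseline (exergame) mode.
Samples inside annotated artifact intervals are excluded before bin
averaging; a bin with more than half of its samples excluded is missing.
Standardization z-scores the concatenation of a participant's trials
(sample-SD convention, declared in the processing log); missing bins are
excluded from the mean/SD and stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import CS, MUSCLES, WEARABLE, ZM, FilterSpec
from .simulate import ParticipantData, RawEmgRecording

MOVING_AVERAGE_WINDOW = 51
ARTIFACT_EXCLUDED_FRACTION = 0.5


def highpass_filter(signal, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth high-pass (low-cut) filter.

    Forward–backward application squares the magnitude response and cancels
    the phase, so the envelope is not delayed relative to the rating clock.
    """
    x = np.asarray(signal, dtype=float)
    spec.validate(fs)
    if len(x) < 3 * (2 * spec.order + 1):
        raise ValueError(f"signal too short ({len(x)} samples) for order-{spec.order} filtering")
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="highpass", fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def subtract_moving_average(signal, window: int = MOVING_AVERAGE_WINDOW) -> np.ndarray:
    """Subtract the centered ``window``-point moving average (drift removal).

    Edges use shrunken (truncated) windows so output length equals input
    length. The window must be odd so the mean is centered on the sample.
    """
    x = np.asarray(signal, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd count, got {window}")
    if len(x) < window:
        raise ValueError(f"signal length {len(x)} shorter than window {window}")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(len(x))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, len(x) - 1)
    means = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return x - means


def rectify(signal) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    return np.abs(np.asarray(signal, dtype=float))


@dataclass
class BinnedSeries:
    """1 Hz rectified-envelope bins for one trial.

    ``values`` are µV before standardization and unitless z afterwards;
    missing bins (artifact-dominated) are NaN.
    """

    values: np.ndarray
    trial_id: str
    condition: str = ""
    participant: str = ""
    device: str = ""
    muscle: str = ""
    baseline_corrected: bool = False
    standardized: bool = False
    baseline_mean: float | None = None

    def __len__(self) -> int:
        return len(self.values)


def epoch_and_bin(
    signal,
    fs: float,
    events: pd.DataFrame,
    artifacts: pd.DataFrame | None = None,
    bin_ms: int = 1000,
    **provenance: str,
) -> list[BinnedSeries]:
    """Epoch a rectified signal into trials and average in 1000-ms bins.

    Bins are aligned to each trial's stimulus onset; a trailing partial bin
    is dropped. Artifact-interval samples are excluded from the averages and
    a bin with more than 50% of its samples excluded is marked missing (NaN).
    The per-trial baseline mean is computed over the full 10-s pre-stimulus
    window where one exists.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    bin_n = int(round(bin_ms * fs / 1000.0))
    keep = np.ones(n, dtype=bool)
    if artifacts is not None and len(artifacts):
        for _, a in artifacts.iterrows():
            i0 = max(int(round(a.artifact_start_s * fs)), 0)
            i1 = min(int(round(a.artifact_end_s * fs)), n)
            keep[i0:i1] = False
    out = []
    for _, ev in events.iterrows():
        i_start = int(round(ev.stim_start_s * fs))
        i_end = int(round(ev.stim_end_s * fs))
        if i_start < 0 or i_end > n:
            raise ValueError(
                f"trial {ev.trial_id}: stimulus window [{ev.stim_start_s}, "
                f"{ev.stim_end_s}] s lies outside the recording ({n / fs:.1f} s)"
            )
        n_bins = (i_end - i_start) // bin_n  # trailing partial bin dropped
        vals = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sl = slice(i_start + b * bin_n, i_start + (b + 1) * bin_n)
            good = keep[sl]
            if good.mean() > ARTIFACT_EXCLUDED_FRACTION:
                vals[b] = x[sl][good].mean()
        baseline_mean = None
        if "baseline_start_s" in ev.index and np.isfinite(ev.baseline_start_s):
            b0 = int(round(ev.baseline_start_s * fs))
            b1 = i_start
            if b0 < 0 or b1 > n:
                raise ValueError(f"trial {ev.trial_id}: baseline window outside recording")
            baseline_mean = float(x[b0:b1].mean())
        out.append(
            BinnedSeries(
                vals,
                trial_id=str(ev.trial_id),
                condition=str(ev.get("condition", "")),
                baseline_mean=baseline_mean,
                **provenance,
            )
        )
    return out


def baseline_correct(trial: BinnedSeries, baseline_mean: float | None = None) -> BinnedSeries:
    """Subtract the trial's pre-stimulus mean envelope from every bin."""
    mean = baseline_mean if baseline_mean is not None else trial.baseline_mean
    if mean is None:
        raise ValueError(f"trial {trial.trial_id}: no baseline available for correction")
    out = BinnedSeries(
        trial.values - mean,
        trial.trial_id,
        trial.condition,
        trial.participant,
        trial.device,
        trial.muscle,
        baseline_corrected=True,
        baseline_mean=mean,
    )
    return out


def standardize_within_individual(trials: list[BinnedSeries]) -> list[BinnedSeries]:
    """Z-score the concatenation of one participant's trials.

    Missing bins are excluded from the mean/SD and remain missing. Uses the
    sample-SD (n−1) convention; the downstream mixed-model t statistics are
    invariant to this choice.
    """
    concat = np.concatenate([t.values for t in trials])
    good = concat[np.isfinite(concat)]
    if len(good) < 2:
        who = trials[0].participant or "<unknown>"
        raise ValueError(f"participant {who}: fewer than 2 non-missing bins")
    mu = good.mean()
    sd = good.std(ddof=1)
    if sd == 0:
        who = trials[0].participant or "<unknown>"
        raise ValueError(f"participant {who}: zero variance across concatenated bins")
    out = []
    for t in trials:
        out.append(
            BinnedSeries(
                (t.values - mu) / sd,
                t.trial_id,
                t.condition,
                t.participant,
                t.device,
                t.muscle,
                baseline_corrected=t.baseline_corrected,
                standardized=True,
                baseline_mean=t.baseline_mean,
            )
        )
    return out


@dataclass
class ProcessingLog:
    """Conventions actually applied, persisted next to the tidy output."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    moving_average_window: int | None = None
    bin_ms: int = 1000
    baseline_corrected: bool = True
    sd_convention: str = "sample (ddof=1)"
    artifact_bin_missing_fraction: float = ARTIFACT_EXCLUDED_FRACTION

    def to_dict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        return d


def preprocess_recording(
    rec: RawEmgRecording,
    events: pd.DataFrame,
    artifacts: pd.DataFrame | None = None,
    spec: FilterSpec = FilterSpec(),
    bin_ms: int = 1000,
    baseline_mode: bool | None = None,
) -> dict[str, list[BinnedSeries]]:
    """Run the full conditioning/envelope pipeline for one recording.

    ``baseline_mode=None`` autodetects from the event table (baseline
    windows present -> correct; absent -> skip, exergame style).
    """
    if baseline_mode is None:
        baseline_mode = (
            "baseline_start_s" in events.columns
            and np.isfinite(events.baseline_start_s).all()
        )
    out: dict[str, list[BinnedSeries]] = {}
    for muscle in MUSCLES:
        x = highpass_filter(rec.samples[muscle], rec.sampling_rate_hz, spec)
        if rec.device == WEARABLE:
            x = subtract_moving_average(x, MOVING_AVERAGE_WINDOW)
        x = rectify(x)
        trials = epoch_and_bin(
            x,
            rec.sampling_rate_hz,
            events,
            artifacts=artifacts,
            bin_ms=bin_ms,
            participant=rec.participant_id,
            device=rec.device,
            muscle=muscle,
        )
        if baseline_mode:
            trials = [baseline_correct(t) for t in trials]
        out[muscle] = standardize_within_individual(trials)
    return out


def binned_to_frame(trials_by_muscle: dict[str, list[BinnedSeries]]) -> pd.DataFrame:
    """Flatten per-muscle BinnedSeries into the tidy long table."""
    rows = []
    for muscle, trials in trials_by_muscle.items():
        for t in trials:
            for i, v in enumerate(t.values):
                rows.append(
                    (
                        t.participant,
                        t.device,
                        muscle,
                        t.trial_id,
                        t.condition,
                        i,
                        v,
                        not np.isfinite(v),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "device",
            "muscle",
            "trial_id",
            "condition",
            "t_bin_s",
            "value_z",
            "missing_flag",
        ],
    )


def preprocess_participant(
    p: ParticipantData,
    spec: FilterSpec = FilterSpec(),
    bin_ms: int = 1000,
) -> pd.DataFrame:
    """Tidy 1 Hz standardized envelope table for every device x muscle."""
    frames = []
    for device in sorted(p.recordings):
        trials = preprocess_recording(
            p.recordings[device],
            p.events,
            artifacts=p.artifacts if len(p.artifacts) else None,
            spec=spec,
            bin_ms=bin_ms,
        )
        frames.append(binned_to_frame(trials))
    return pd.concat(frames, ignore_index=True)
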
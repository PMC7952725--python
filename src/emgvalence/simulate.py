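"""Synthetic facial-EMG experiment generator.

The generative model mirrors the structure the downstream analysis assumes:

* a latent subjective-valence process per trial — a mean-reverting
  (Ornstein–Uhlenbeck) process at 1 Hz around a condition-specific mean on
  the 1–9 rating scale, clipped to the scale bounds;
* a per-participant linear coupling between centered valence and the
  standardized EMG envelope, ``z(t) = (γ00 + u0j) + (γ10 + u1j)·(v(t) − 5)
  + ε(t)``, with bivariate-normal participant deviations ``(u0j, u1j)``;
* raw surface EMG as amplitude-modulated band-limited (20–400 Hz, truncated
  below Nyquist) Gaussian noise, plus slow baseline drift and optional
  high-amplitude artifact bursts inside annotated intervals.

Rectified-mean envelope extraction is therefore the matched estimator for
the simulated signal, and the mixed-model slope on the standardized scale
recovers γ10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import (
    CS,
    EXP1_AROUSAL_MEANS,
    EXP2_FRAME_MEAN_S,
    EXP2_FRAME_MIN_S,
    EXP2_FRAME_SD_S,
    EXP2_SESSION_S,
    EXP2_VALENCE_MEAN,
    MUSCLES,
    ZM,
    SimulationConfig,
    TrialSpec,
)

VALENCE_MIN, VALENCE_MAX, VALENCE_NEUTRAL = 1.0, 9.0, 5.0
CARRIER_LOW_HZ = 400.0  # upper edge of the surface-EMG band
CARRIER_BAND_BOTTOM_HZ = 20.0
INTER_TRIAL_GAP_S = 2.0
BASELINE_S = 10.0


def _rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_valence_trace(
    duration_s: float,
    smoothness_s: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
    mean: float = VALENCE_NEUTRAL,
    sd: float = 1.0,
    clip: bool = True,
) -> np.ndarray:
    """Simulate a 1 Hz continuous valence trace on the 1–9 scale.

    A discretized Ornstein–Uhlenbeck process with stationary SD ``sd`` and
    lag-1 autocorrelation ``exp(−1/smoothness_s)``, reverting to ``mean`` and
    clipped to the rating-scale bounds. ``clip=False`` returns the latent
    (unbounded) process, useful for checking the autocorrelation analytically.
    """
    if duration_s < 1:
        raise ValueError(f"duration_s must be >= 1 s, got {duration_s}")
    if smoothness_s <= 0:
        raise ValueError(f"smoothness_s must be > 0, got {smoothness_s}")
    rng = _rng(seed)
    n = int(np.floor(duration_s))
    phi = float(np.exp(-1.0 / smoothness_s))
    innov_sd = sd * np.sqrt(max(0.0, 1.0 - phi * phi))
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    shocks = innov_sd * rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + shocks[t - 1]
    if clip:
        x = np.clip(x, VALENCE_MIN, VALENCE_MAX)
    return x


def carrier_band(fs: float) -> tuple[float, float]:
    """Surface-EMG carrier band for a given sampling rate.

    20–400 Hz, with the upper edge truncated to 90% of Nyquist so the
    band-pass design stays well-conditioned (225 Hz at 500 Hz sampling).
    """
    upper = min(CARRIER_LOW_HZ, 0.45 * fs)
    if upper <= CARRIER_BAND_BOTTOM_HZ:
        raise ValueError(
            f"sampling rate {fs} Hz too low to carry the "
            f"{CARRIER_BAND_BOTTOM_HZ}-{CARRIER_LOW_HZ} Hz EMG band"
        )
    return CARRIER_BAND_BOTTOM_HZ, upper


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the EMG carrier band."""
    low, high = carrier_band(fs)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def _slow_drift(n: int, fs: float, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Baseline wander: random walk low-passed at the drift corner, scaled."""
    if cfg.drift_amplitude_uv == 0 or n < 32:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    corner = min(cfg.drift_corner_hz, 0.4 * fs)
    sos = sps.butter(2, corner, btype="lowpass", fs=fs, output="sos")
    drift = sps.sosfilt(sos, walk)
    drift -= drift.mean()
    s = drift.std()
    if s > 0:
        drift *= cfg.drift_amplitude_uv / s
    return drift


def envelope_uv(z: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Map the standardized-scale envelope to a physical µV amplitude.

    Affine with a positivity floor: ``amp · max(1 + depth·z, floor)``.
    Within the unflooored range the map is affine, so within-individual
    z-scoring of the extracted envelope inverts it exactly.
    """
    return cfg.amplitude_uv * np.maximum(
        1.0 + cfg.modulation_depth * z, cfg.envelope_floor
    )


@dataclass
class RawEmgRecording:
    """Raw two-channel EMG for one participant and device."""

    samples: dict[str, np.ndarray]  # muscle -> µV sequence
    sampling_rate_hz: float
    device: str
    participant_id: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.samples.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class ParticipantData:
    """Everything simulated for one participant."""

    participant_id: str
    sex: str
    events: pd.DataFrame  # trial_id, condition, baseline_start_s, stim_start_s, stim_end_s
    artifacts: pd.DataFrame  # trial_id, artifact_start_s, artifact_end_s
    valence: dict[str, np.ndarray]  # trial_id -> 1 Hz trace
    recall: dict[str, np.ndarray]  # cued-recall re-rating of the same trials
    overall: pd.DataFrame  # trial_id, condition, valence, arousal
    recordings: dict[str, RawEmgRecording]
    effects: dict[str, tuple[float, float]]  # muscle -> (slope_dev, intercept_dev)
    true_envelope: dict[str, dict[str, np.ndarray]]  # muscle -> trial_id -> noiseless z


def _draw_effects(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    cov = np.array(
        [
            [cfg.tau_slope**2, cfg.tau_corr * cfg.tau_slope * cfg.tau_intercept],
            [cfg.tau_corr * cfg.tau_slope * cfg.tau_intercept, cfg.tau_intercept**2],
        ]
    )
    # cholesky needs strict positive definiteness; fall back for degenerate
    # (zero-variance) random-effect settings
    method = "cholesky" if np.linalg.det(cov) > 1e-12 else "eigh"
    out = {}
    for m in MUSCLES:
        dev = rng.multivariate_normal([0.0, 0.0], cov, method=method)
        out[m] = (float(dev[0]), float(dev[1]))  # (slope_dev, intercept_dev)
    return out


def _exp2_frames(rng: np.random.Generator) -> list[TrialSpec]:
    """Draw game frames filling a ~10-min session."""
    frames: list[TrialSpec] = []
    total = 0.0
    while total < EXP2_SESSION_S - EXP2_FRAME_MIN_S:
        d = float(
            np.clip(
                rng.normal(EXP2_FRAME_MEAN_S, EXP2_FRAME_SD_S),
                EXP2_FRAME_MIN_S,
                EXP2_SESSION_S - total,
            )
        )
        frames.append(
            TrialSpec(d, "frame", has_baseline=False, valence_mean=EXP2_VALENCE_MEAN)
        )
        total += d
    return frames


def _layout_trials(trials: list[TrialSpec]) -> pd.DataFrame:
    rows = []
    t = INTER_TRIAL_GAP_S
    for k, tr in enumerate(trials, start=1):
        baseline_start = t if tr.has_baseline else np.nan
        stim_start = t + (BASELINE_S if tr.has_baseline else 0.0)
        stim_end = stim_start + tr.duration_s
        rows.append(
            {
                "trial_id": f"T{k:02d}",
                "condition": tr.condition,
                "baseline_start_s": baseline_start,
                "stim_start_s": stim_start,
                "stim_end_s": stim_end,
            }
        )
        t = stim_end + INTER_TRIAL_GAP_S
    return pd.DataFrame(rows)


def _draw_artifacts(
    events: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    if cfg.artifact_rate_per_min > 0:
        for _, ev in events.iterrows():
            dur = ev.stim_end_s - ev.stim_start_s
            lam = cfg.artifact_rate_per_min * dur / 60.0
            for _ in range(rng.poisson(lam)):
                a_dur = min(cfg.artifact_duration_s, dur)
                start = ev.stim_start_s + rng.uniform(0, dur - a_dur)
                rows.append(
                    {
                        "trial_id": ev.trial_id,
                        "artifact_start_s": start,
                        "artifact_end_s": start + a_dur,
                    }
                )
    return pd.DataFrame(rows, columns=["trial_id", "artifact_start_s", "artifact_end_s"])


def simulate_emg_channel(
    amp_1hz: np.ndarray,
    fs: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    artifact_samples: np.ndarray | None = None,
) -> np.ndarray:
    """Synthesize one raw EMG channel from a 1 Hz µV amplitude envelope.

    The envelope is held for each second and multiplies a unit-variance
    band-limited carrier; slow drift is added, and sample indices flagged in
    ``artifact_samples`` receive a high-amplitude broadband burst.
    """
    fs_int = int(round(fs))
    n = len(amp_1hz) * fs_int
    carrier = _bandlimited_carrier(n, fs, rng)
    amp = np.repeat(amp_1hz, fs_int)
    x = amp * carrier + _slow_drift(n, fs, cfg, rng)
    if artifact_samples is not None and artifact_samples.any():
        burst = _bandlimited_carrier(n, fs, rng)
        x = x + artifact_samples * (cfg.artifact_gain * cfg.amplitude_uv) * burst
    return x


def simulate_participant(
    cfg: SimulationConfig,
    participant_id: str,
    seed_seq: np.random.SeedSequence,
    sex: str = "f",
) -> ParticipantData:
    """Simulate one participant: events, ratings, and raw EMG per device."""
    ss_effects, ss_valence, ss_frames, ss_ratings, *ss_dev = seed_seq.spawn(
        4 + len(cfg.device_spec)
    )
    rng_eff = np.random.default_rng(ss_effects)
    effects = _draw_effects(cfg, rng_eff)

    trials = cfg.trial_spec if cfg.trial_spec else _exp2_frames(np.random.default_rng(ss_frames))
    events = _layout_trials(trials)
    rng_art = np.random.default_rng(ss_frames.spawn(1)[0])
    artifacts = _draw_artifacts(events, cfg, rng_art)

    rng_val = np.random.default_rng(ss_valence)
    valence: dict[str, np.ndarray] = {}
    recall: dict[str, np.ndarray] = {}
    for tr, (_, ev) in zip(trials, events.iterrows()):
        v = simulate_valence_trace(
            tr.duration_s, cfg.valence_smoothness_s, rng_val,
            mean=tr.valence_mean, sd=cfg.valence_sd,
        )
        valence[ev.trial_id] = v
        # cued recall: lightly smoothed, noisier re-rating of the same episode
        kernel = np.ones(5) / 5.0
        sm = np.convolve(np.pad(v, 2, mode="edge"), kernel, mode="valid")
        recall[ev.trial_id] = np.clip(
            sm + 0.5 * rng_val.standard_normal(len(v)), VALENCE_MIN, VALENCE_MAX
        )

    # standardized-scale envelope at 1 Hz over the whole recording extent
    total_s = int(np.ceil(events.stim_end_s.iloc[-1] + INTER_TRIAL_GAP_S))
    rng_env = np.random.default_rng(ss_valence.spawn(1)[0])
    z_env: dict[str, np.ndarray] = {}
    true_env: dict[str, dict[str, np.ndarray]] = {m: {} for m in MUSCLES}
    for m in MUSCLES:
        slope = cfg.gamma10(m) + effects[m][0]
        intercept = cfg.gamma00 + effects[m][1]
        # resting/baseline seconds: valence term absent
        z = intercept + cfg.noise_sd * rng_env.standard_normal(total_s)
        for tid, v in valence.items():
            ev = events.loc[events.trial_id == tid].iloc[0]
            s0 = int(round(ev.stim_start_s))
            clean = intercept + slope * (v - VALENCE_NEUTRAL)
            z[s0 : s0 + len(v)] = clean + cfg.noise_sd * rng_env.standard_normal(len(v))
            true_env[m][tid] = clean
        z_env[m] = z

    # overall ratings
    rng_rate = np.random.default_rng(ss_ratings)
    overall_rows = []
    for tr, (_, ev) in zip(trials, events.iterrows()):
        if tr.condition in EXP1_AROUSAL_MEANS:
            v_mu = tr.valence_mean
            a_mu = EXP1_AROUSAL_MEANS[tr.condition]
            arousal = int(np.clip(np.round(rng_rate.normal(a_mu, 1.0)), 1, 9))
        else:
            v_mu = float(valence[ev.trial_id].mean())
            arousal = np.nan
        v_rating = int(np.clip(np.round(rng_rate.normal(v_mu, 1.0)), 1, 9))
        overall_rows.append(
            {
                "trial_id": ev.trial_id,
                "condition": tr.condition,
                "valence": v_rating,
                "arousal": arousal,
            }
        )
    overall = pd.DataFrame(overall_rows)

    # raw EMG per device
    recordings: dict[str, RawEmgRecording] = {}
    for (device, fs), ss in zip(sorted(cfg.device_spec.items()), ss_dev):
        rng_d = np.random.default_rng(ss)
        fs_int = int(round(fs))
        n = total_s * fs_int
        art_mask = np.zeros(n)
        for _, a in artifacts.iterrows():
            i0 = int(round(a.artifact_start_s * fs_int))
            i1 = int(round(a.artifact_end_s * fs_int))
            art_mask[i0:i1] = 1.0
        samples = {
            m: simulate_emg_channel(
                envelope_uv(z_env[m], cfg), fs, cfg, rng_d,
                artifact_samples=art_mask if art_mask.any() else None,
            )
            for m in MUSCLES
        }
        recordings[device] = RawEmgRecording(samples, fs, device, participant_id)

    return ParticipantData(
        participant_id=participant_id,
        sex=sex,
        events=events,
        artifacts=artifacts,
        valence=valence,
        recall=recall,
        overall=overall,
        recordings=recordings,
        effects=effects,
        true_envelope=true_env,
    )


def iter_participants(cfg: SimulationConfig) -> Iterator[ParticipantData]:
    """Yield participants one at a time (raw EMG is memory-heavy at scale)."""
    root = np.random.SeedSequence(cfg.seed)
    seqs = root.spawn(cfg.n_participants)
    rng_sex = np.random.default_rng(root.spawn(1)[0])
    sexes = rng_sex.permutation(
        ["f"] * ((cfg.n_participants + 1) // 2) + ["m"] * (cfg.n_participants // 2)
    )
    for i, ss in enumerate(seqs):
        yield simulate_participant(cfg, f"P{i + 1:02d}", ss, sex=str(sexes[i]))


@dataclass
class ExperimentData:
    """A fully materialized synthetic dataset (small configs only)."""

    cfg: SimulationConfig
    participants: list[ParticipantData] = field(default_factory=list)


def simulate_experiment(cfg: SimulationConfig) -> ExperimentData:
    return ExperimentData(cfg, list(iter_participants(cfg)))


# ---------------------------------------------------------------------------
# fast 1 Hz-level generator: draws directly from the mixed model that the
# concordance analysis fits, for oracle-equivalence and recovery studies
# ---------------------------------------------------------------------------

def simulate_paired_series(
    cfg: SimulationConfig,
    muscle: str,
    seed: int | np.random.SeedSequence,
    trial_spec: list[TrialSpec] | None = None,
    obs_per_participant: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate aligned 1 Hz (valence, standardized-EMG) pairs directly.

    Skips the raw-signal synthesis and envelope extraction: the response is
    drawn from the random-slope model itself. Returns the paired table and a
    ground-truth dict with fixed and realized per-participant coefficients.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gamma10 = cfg.gamma10(muscle)
    rows = []
    truth = {"gamma10": gamma10, "gamma00": cfg.gamma00, "participants": {}}
    for i, ss in enumerate(root.spawn(cfg.n_participants)):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng(ss)
        slope_dev, int_dev = _draw_effects(cfg, rng)[muscle]
        slope = gamma10 + slope_dev
        intercept = cfg.gamma00 + int_dev
        truth["participants"][pid] = {"slope": slope, "intercept": intercept}
        if obs_per_participant is not None:
            trials = [TrialSpec(float(obs_per_participant), "flat", False, VALENCE_NEUTRAL)]
        else:
            trials = trial_spec if trial_spec is not None else (cfg.trial_spec or [])
            if not trials:
                trials = _exp2_frames(rng)
        for k, tr in enumerate(trials, start=1):
            v = simulate_valence_trace(
                tr.duration_s, cfg.valence_smoothness_s, rng,
                mean=tr.valence_mean, sd=cfg.valence_sd,
            )
            y = (
                intercept
                + slope * (v - VALENCE_NEUTRAL)
                + cfg.noise_sd * rng.standard_normal(len(v))
            )
            for t, (xv, yv) in enumerate(zip(v, y)):
                rows.append((pid, f"T{k:02d}", tr.condition, t, xv, yv))
    df = pd.DataFrame(
        rows, columns=["participant", "trial_id", "condition", "t_s", "valence", "emg_z"]
    )
    return df, truth


# ---------------------------------------------------------------------------
# on-disk dataset format
# ---------------------------------------------------------------------------

def write_dataset(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Materialize a synthetic experiment on disk, one directory per participant.

    Layout: ``<outdir>/P01/{emg_<device>.csv,.json, events.csv, artifacts.csv,
    ratings_continuous.csv, ratings_recall.csv, ratings_overall.csv}`` plus
    dataset-level ``config.json`` and ``ground_truth.json``.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e
    (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))

    truth: dict = {"participants": {}}
    for p in iter_participants(cfg):
        pdir = out / p.participant_id
        pdir.mkdir(exist_ok=True)
        for device, rec in sorted(p.recordings.items()):
            fs = rec.sampling_rate_hz
            t = np.arange(rec.n_samples) / fs
            df = pd.DataFrame(
                {"time_s": t, "cs_uv": rec.samples[CS], "zm_uv": rec.samples[ZM]}
            )
            df.to_csv(pdir / f"emg_{device}.csv", index=False, float_format="%.4f")
            meta = {
                "sampling_rate_hz": fs,
                "device": device,
                "participant_id": p.participant_id,
                "seed": cfg.seed,
            }
            (pdir / f"emg_{device}.json").write_text(json.dumps(meta, indent=2))
        p.events.to_csv(pdir / "events.csv", index=False)
        p.artifacts.to_csv(pdir / "artifacts.csv", index=False)
        cont = pd.concat(
            [
                pd.DataFrame({"trial_id": tid, "t_s": np.arange(len(v)), "valence": v})
                for tid, v in p.valence.items()
            ],
            ignore_index=True,
        )
        cont.to_csv(pdir / "ratings_continuous.csv", index=False, float_format="%.4f")
        rec_df = pd.concat(
            [
                pd.DataFrame({"trial_id": tid, "t_s": np.arange(len(v)), "valence": v})
                for tid, v in p.recall.items()
            ],
            ignore_index=True,
        )
        rec_df.to_csv(pdir / "ratings_recall.csv", index=False, float_format="%.4f")
        p.overall.to_csv(pdir / "ratings_overall.csv", index=False)
        truth["participants"][p.participant_id] = {
            "sex": p.sex,
            "effects": {m: list(p.effects[m]) for m in MUSCLES},
            "valence": {tid: v.tolist() for tid, v in p.valence.items()},
            "true_envelope": {
                m: {tid: e.tolist() for tid, e in p.true_envelope[m].items()}
                for m in MUSCLES
            },
        }
    truth["gamma10"] = {CS: cfg.gamma10_cs, ZM: cfg.gamma10_zm}
    (out / "ground_truth.json").write_text(json.dumps(truth))
    return out


def read_dataset(indir: str | Path) -> ExperimentData:
    """Load a dataset written by :func:`write_dataset`."""
    root = Path(indir)
    if not (root / "config.json").exists():
        raise FileNotFoundError(f"no config.json in {root}")
    cfg = SimulationConfig.from_dict(json.loads((root / "config.json").read_text()))
    truth = json.loads((root / "ground_truth.json").read_text())
    parts = []
    for pid in sorted(truth["participants"]):
        pdir = root / pid
        if not pdir.is_dir():
            raise FileNotFoundError(f"missing participant directory {pdir}")
        events = pd.read_csv(pdir / "events.csv")
        artifacts = pd.read_csv(pdir / "artifacts.csv")
        cont = pd.read_csv(pdir / "ratings_continuous.csv")
        valence = {
            tid: g.sort_values("t_s").valence.to_numpy()
            for tid, g in cont.groupby("trial_id")
        }
        rec_df = pd.read_csv(pdir / "ratings_recall.csv")
        recall = {
            tid: g.sort_values("t_s").valence.to_numpy()
            for tid, g in rec_df.groupby("trial_id")
        }
        overall = pd.read_csv(pdir / "ratings_overall.csv")
        recordings = {}
        for mpath in sorted(pdir.glob("emg_*.json")):
            meta = json.loads(mpath.read_text())
            df = pd.read_csv(pdir / f"emg_{meta['device']}.csv")
            recordings[meta["device"]] = RawEmgRecording(
                {CS: df.cs_uv.to_numpy(), ZM: df.zm_uv.to_numpy()},
                meta["sampling_rate_hz"],
                meta["device"],
                pid,
            )
        tp = truth["participants"][pid]
        parts.append(
            ParticipantData(
                participant_id=pid,
                sex=tp["sex"],
                events=events,
                artifacts=artifacts,
                valence=valence,
                recall=recall,
                overall=overall,
                recordings=recordings,
                effects={m: tuple(tp["effects"][m]) for m in MUSCLES},
                true_envelope={
                    m: {tid: np.asarray(e) for tid, e in tp["true_envelope"][m].items()}
                    for m in MUSCLES
                },
            )
        )
    return ExperimentData(cfg, parts)
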
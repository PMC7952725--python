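"""Configuration objects for simulation, preprocessing, and full pipeline runs.

Two experiment presets are provided:

* ``exp1`` — film viewing: 15 participants, five films of 138–205 s, each
  preceded by a 10-s pre-stimulus baseline, recorded simultaneously with a
  wired device (1000 Hz) and a wearable device (500 Hz).
* ``exp2`` — exergame play: 23 participants, ~10 min of game frames of mean
  ~27 s, wearable device only, no baseline windows, with artifact segments
  annotated for excision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

CS = "cs"  # corrugator supercilii (brow; frowning, negative valence)
ZM = "zm"  # zygomatic major (cheek; smiling, positive valence)
MUSCLES = (CS, ZM)

WIRED = "wired"
WEARABLE = "wearable"


@dataclass(frozen=True)
class TrialSpec:
    """One trial (film or game frame) of the simulated session."""

    duration_s: float
    condition: str
    has_baseline: bool = True
    valence_mean: float = 5.0  # latent valence process mean for this condition


@dataclass(frozen=True)
class FilterSpec:
    """High-pass (low-cut) filter specification.

    The 20 Hz low cut suppresses motion and drift artifacts below the
    surface-EMG band; it is applied zero-phase (forward–backward) so the
    envelope is not shifted relative to the rating timeline.
    """

    kind: str = "highpass"
    cutoff_hz: float = 20.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.kind != "highpass":
            raise ValueError(f"unsupported filter kind {self.kind!r}")
        if not 0 < self.cutoff_hz < fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie strictly below the "
                f"Nyquist frequency {fs / 2} Hz"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class SimulationConfig:
    """Ground-truth generative settings for a synthetic experiment.

    The coupling slopes ``gamma10_cs``/``gamma10_zm`` are fixed effects on the
    standardized-envelope scale (z units of EMG envelope per unit of 1–9
    valence); by-participant slope and intercept deviations are drawn from a
    bivariate normal with SDs ``tau_slope``/``tau_intercept`` and correlation
    ``tau_corr``.
    """

    n_participants: int = 15
    trial_spec: list[TrialSpec] = field(default_factory=list)
    device_spec: dict[str, float] = field(
        default_factory=lambda: {WIRED: 1000.0, WEARABLE: 500.0}
    )
    # fixed coupling slopes, standardized envelope scale
    gamma10_cs: float = -0.20
    gamma10_zm: float = 0.15
    gamma00: float = 0.0
    # random-effect structure
    tau_intercept: float = 0.15
    tau_slope: float = 0.10
    tau_corr: float = 0.0
    # residual envelope noise (z units at 1 Hz)
    noise_sd: float = 0.92
    # raw-signal nuisance structure
    amplitude_uv: float = 30.0  # resting envelope amplitude of the carrier
    modulation_depth: float = 0.25  # µV envelope = amp * max(1 + depth*z, floor)
    envelope_floor: float = 0.05
    drift_amplitude_uv: float = 20.0
    drift_corner_hz: float = 1.0
    artifact_rate_per_min: float = 0.0
    artifact_duration_s: float = 3.0
    artifact_gain: float = 15.0
    valence_smoothness_s: float = 10.0
    valence_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tau_intercept", "tau_slope", "noise_sd", "amplitude_uv",
            "drift_amplitude_uv", "artifact_rate_per_min",
            "artifact_duration_s", "valence_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.tau_corr <= 1.0:
            raise ValueError("tau_corr must lie in [-1, 1]")
        if self.valence_smoothness_s <= 0:
            raise ValueError("valence_smoothness_s must be > 0")
        for device, fs in self.device_spec.items():
            if fs <= 0:
                raise ValueError(f"sampling rate for {device!r} must be positive")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    def gamma10(self, muscle: str) -> float:
        if muscle == CS:
            return self.gamma10_cs
        if muscle == ZM:
            return self.gamma10_zm
        raise ValueError(f"unknown muscle {muscle!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["trial_spec"] = [dataclasses.asdict(t) for t in self.trial_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        d["trial_spec"] = [TrialSpec(**t) for t in d.get("trial_spec", [])]
        return cls(**d)


# Exp-1 film conditions: durations within the 138–205 s range (mean ~173 s),
# condition valence means spanning very negative to very positive around the
# neutral midpoint 5, and arousal means with the usual U-shape over valence.
EXP1_FILMS = [
    TrialSpec(205.0, "anger", True, 2.5),
    TrialSpec(173.0, "sadness", True, 3.5),
    TrialSpec(138.0, "neutral", True, 5.0),
    TrialSpec(160.0, "contentment", True, 6.5),
    TrialSpec(191.0, "amusement", True, 7.5),
]

EXP1_AROUSAL_MEANS = {
    "anger": 7.0,
    "sadness": 5.5,
    "neutral": 2.5,
    "contentment": 4.0,
    "amusement": 6.5,
}


def exp1_config(seed: int = 0, **overrides: Any) -> SimulationConfig:
    """Film-viewing preset: two devices, 10-s baselines, five films."""
    kwargs: dict[str, Any] = dict(
        n_participants=15,
        trial_spec=list(EXP1_FILMS),
        device_spec={WIRED: 1000.0, WEARABLE: 500.0},
        gamma10_cs=-0.20,
        gamma10_zm=0.15,
        tau_slope=0.10,
        artifact_rate_per_min=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def exp2_config(seed: int = 0, **overrides: Any) -> SimulationConfig:
    """Exergame preset: wearable only, no baselines, artifact excision.

    Game frames are drawn per participant to fill a ~10-min session
    (mean frame length ~27 s); trial_spec is left empty and frames are
    generated at simulation time. Coupling magnitudes are an order smaller
    than in the film preset: free play elicits subtler affect.
    """
    kwargs: dict[str, Any] = dict(
        n_participants=23,
        trial_spec=[],
        device_spec={WEARABLE: 500.0},
        gamma10_cs=-0.03,
        gamma10_zm=0.03,
        tau_slope=0.06,
        tau_intercept=0.10,
        artifact_rate_per_min=1.3,
        artifact_duration_s=3.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


EXP2_SESSION_S = 600.0
EXP2_FRAME_MEAN_S = 26.7
EXP2_FRAME_SD_S = 8.9
EXP2_FRAME_MIN_S = 8.0
EXP2_VALENCE_MEAN = 6.0

PRESETS = {"exp1": exp1_config, "exp2": exp2_config}


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    preset: str = "exp1"
    seed: int = 0
    outdir: str = "emgvalence_run"
    outlier_sd: float = 3.0
    bin_ms: int = 1000
    directions: dict[str, str] = field(
        default_factory=lambda: {CS: "negative", ZM: "positive"}
    )
    filter: FilterSpec = field(default_factory=FilterSpec)
    sim: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.sim is None:
            self.sim = PRESETS[self.preset](seed=self.seed)

    def to_json(self) -> str:
        d = {
            "preset": self.preset,
            "seed": self.seed,
            "outdir": self.outdir,
            "outlier_sd": self.outlier_sd,
            "bin_ms": self.bin_ms,
            "directions": self.directions,
            "filter": dataclasses.asdict(self.filter),
            "sim": self.sim.to_dict() if self.sim else None,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        filt = FilterSpec(**d.pop("filter", {}))
        sim = d.pop("sim", None)
        cfg = cls(filter=filt, sim=None, **d)
        if sim is not None:
            cfg.sim = SimulationConfig.from_dict(sim)
        return cfg
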
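"""End-to-end orchestration: simulate -> preprocess -> fit -> report.

Runs either from a materialized on-disk dataset or by streaming participants
in memory (raw EMG is generated, condensed to the 1 Hz envelope, and
discarded one participant at a time, which keeps full-scale runs in a few
hundred MB).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .concordance import ConcordanceLMM, group_summary, group_timecourse
from .config import MUSCLES, RunConfig
from .preprocess import ProcessingLog, preprocess_participant
from .ratings import overall_rating_table, recall_validation
from .simulate import (
    ExperimentData,
    ParticipantData,
    iter_participants,
    read_dataset,
    write_dataset,
)


def run_simulate(cfg: RunConfig, outdir: str | Path | None = None) -> Path:
    """Materialize the preset's synthetic dataset on disk."""
    out = Path(outdir if outdir is not None else cfg.outdir) / "dataset"
    path = write_dataset(cfg.sim, out)
    (path / "run_config.json").write_text(cfg.to_json())
    return path


def preprocess_stream(
    participants: Iterable[ParticipantData], cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict, dict]:
    """Preprocess participants and assemble analysis-ready tables.

    Returns (paired 1 Hz valence/EMG table, tidy envelope table, overall
    ratings, recall-trace dict pair, sex labels).
    """
    tidy_frames = []
    overall_frames = []
    online: dict = {}
    recall: dict = {}
    sex: dict = {}
    for p in participants:
        tidy = preprocess_participant(p, spec=cfg.filter, bin_ms=cfg.bin_ms)
        val = pd.concat(
            [
                pd.DataFrame(
                    {"trial_id": tid, "t_bin_s": range(len(v)), "valence": v}
                )
                for tid, v in p.valence.items()
            ],
            ignore_index=True,
        )
        tidy = tidy.merge(val, on=["trial_id", "t_bin_s"], how="left")
        tidy_frames.append(tidy)
        overall_frames.append(p.overall.assign(participant=p.participant_id))
        sex[p.participant_id] = p.sex
        for tid, v in p.valence.items():
            cond = p.events.loc[p.events.trial_id == tid, "condition"].iloc[0]
            online[(p.participant_id, cond, tid)] = v
            recall[(p.participant_id, cond, tid)] = p.recall[tid]
    tidy = pd.concat(tidy_frames, ignore_index=True)
    paired = tidy.loc[~tidy.missing_flag & tidy.valence.notna()].rename(
        columns={"value_z": "emg_z"}
    )
    overall = pd.concat(overall_frames, ignore_index=True)
    return paired, tidy, overall, {"online": online, "recall": recall}, sex


def fit_concordance_tables(paired: pd.DataFrame, cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Fit the concordance model per device x muscle; Table-style rows + logs."""
    rows = []
    logs: dict = {}
    for device in sorted(paired.device.unique()):
        for muscle in MUSCLES:
            sub = paired[(paired.device == device) & (paired.muscle == muscle)]
            if not len(sub):
                continue
            model = ConcordanceLMM.from_dataframe(sub, muscle=muscle, device=device)
            res = model.fit(
                direction=cfg.directions[muscle], outlier_threshold=cfg.outlier_sd
            )
            res.refit_without_outliers()
            rows.append(res.to_row())
            logs[f"{device}_{muscle}"] = {
                "converged": res.converged,
                "llf": res.llf,
                "sigma2": res.sigma2,
                "cov_re": res.cov_re.tolist(),
                "boundary_sigma": res.fit.boundary_sigma,
                "n_obs": res.fit.n_obs,
                "n_participants": res.fit.n_groups,
                "optimizer": res.fit.optimizer_message,
            }
    return pd.DataFrame(rows), logs


def run_full(
    cfg: RunConfig,
    data: ExperimentData | str | Path | None = None,
    outdir: str | Path | None = None,
    write: bool = True,
) -> dict:
    """Run the whole analysis; optionally persist report tables.

    ``data`` may be a loaded/materialized dataset or a dataset directory; by
    default participants are streamed in memory from the run's simulation
    config.
    """
    if data is None:
        participants: Iterable[ParticipantData] = iter_participants(cfg.sim)
    elif isinstance(data, (str, Path)):
        participants = read_dataset(data).participants
    else:
        participants = data.participants
    paired, tidy, overall, traces, sex = preprocess_stream(participants, cfg)

    results, fit_logs = fit_concordance_tables(paired, cfg)
    ratings_tab = overall_rating_table(overall)
    recall_tab = recall_validation(
        {(p, c): v for (p, c, t), v in traces["online"].items()},
        {(p, c): v for (p, c, t), v in traces["recall"].items()},
    )

    timecourses: dict[str, pd.DataFrame] = {}
    exp2_like = paired.condition.eq("frame").any()
    for device in sorted(paired.device.unique()):
        for muscle in MUSCLES:
            sub = paired[(paired.device == device) & (paired.muscle == muscle)]
            if len(sub):
                timecourses[f"{device}_{muscle}"] = group_timecourse(
                    sub, end_point_s=None if exp2_like else float(sub.t_bin_s.max() + 1)
                )
    scatter: dict[str, pd.DataFrame] = {}
    for device in sorted(paired.device.unique()):
        for muscle in MUSCLES:
            sub = paired[(paired.device == device) & (paired.muscle == muscle)]
            if len(sub):
                tab, line = group_summary(sub)
                tab.attrs["ols_line"] = line
                scatter[f"{device}_{muscle}"] = tab

    out = {
        "results": results,
        "ratings": ratings_tab,
        "recall": recall_tab,
        "timecourses": timecourses,
        "scatter": scatter,
        "paired": paired,
        "tidy": tidy,
        "sex": sex,
        "fit_logs": fit_logs,
    }
    if write:
        rd = Path(outdir if outdir is not None else cfg.outdir) / "report"
        rd.mkdir(parents=True, exist_ok=True)
        results.to_csv(rd / "concordance_results.csv", index=False, float_format="%.6g")
        ratings_tab.to_csv(rd / "ratings_overall_tests.csv", index=False, float_format="%.6g")
        recall_tab.to_csv(rd / "recall_validation.csv", index=False, float_format="%.6g")
        for key, tc in timecourses.items():
            tc.to_csv(rd / f"timecourse_{key}.csv", index=False, float_format="%.6g")
        for key, sc in scatter.items():
            sc.to_csv(rd / f"group_scatter_{key}.csv", index=False, float_format="%.6g")
        log = {
            "run_config": json.loads(cfg.to_json()),
            "processing": ProcessingLog(
                filter=cfg.filter,
                moving_average_window=51,
                bin_ms=cfg.bin_ms,
                baseline_corrected=not exp2_like,
            ).to_dict(),
            "fits": fit_logs,
        }
        (rd / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        (rd / "run_config.json").write_text(cfg.to_json())
    return out
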
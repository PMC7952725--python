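"""Valence–EMG concordance inference.

`ConcordanceLMM` fits, by from-scratch maximum likelihood, the random-slope
multilevel model

    emg_ij = gamma00 + gamma10 * valence_ij + u0j + u1j * valence_ij + e_ij

with continuous 1 Hz subjective valence as the predictor and the
standardized EMG envelope as the response, random by-participant slopes and
intercepts, one-tailed t-tests of the fixed slope on m − l − 1 degrees of
freedom (m participants, l participant-level predictors), standardized
conditional residuals with |z| > 3 outlier refitting, and group-mean
scatter/time-course summaries.

The hypothesized slope direction is fixed a priori per muscle: corrugator
(frowning) negative, zygomatic (smiling) positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .config import CS, ZM
from .lmm import LMMFit, fit_random_slope_ml

DEFAULT_DIRECTIONS = {CS: "negative", ZM: "positive"}
OUTLIER_SD = 3.0


def df_m_l_1(m: int, l: int = 0) -> int:
    """Degrees of freedom for level-2 inference: participants − predictors − 1.

    For a two-level model with m participants and l participant-level
    predictors; validated against Monte-Carlo studies of multilevel-model
    test calibration.
    """
    if m <= l + 1:
        raise ValueError(f"need m > l + 1 participants (m={m}, l={l})")
    return int(m) - int(l) - 1


def one_tailed_p(t: float, df: int, direction: str) -> float:
    """One-tailed tail probability of t in the hypothesized direction."""
    if direction == "negative":
        return float(spstats.t.cdf(t, df))
    if direction == "positive":
        return float(spstats.t.sf(t, df))
    raise ValueError(f"direction must be 'negative' or 'positive', got {direction!r}")


@dataclass
class ConcordanceResults:
    """Results of a concordance mixed-model fit.

    Carries the fixed slope (beta), its standard error from the observed
    information at the ML optimum, the one-tailed test on m − l − 1 df,
    variance components, per-participant predicted deviations, and the
    outlier-refit machinery.
    """

    model: "ConcordanceLMM"
    fit: LMMFit
    direction: str
    df: int
    outlier_threshold: float = OUTLIER_SD
    refit: "ConcordanceResults | None" = None
    removed_outliers: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    # -- headline statistics -------------------------------------------------
    @property
    def beta(self) -> float:
        return float(self.fit.beta[1])

    @property
    def se(self) -> float:
        return float(self.fit.bse[1])

    @property
    def tvalue(self) -> float:
        return self.beta / self.se

    @property
    def p_one_tailed(self) -> float:
        return one_tailed_p(self.tvalue, self.df, self.direction)

    @property
    def gamma00(self) -> float:
        return float(self.fit.beta[0])

    @property
    def llf(self) -> float:
        return self.fit.llf

    @property
    def cov_re(self) -> np.ndarray:
        return self.fit.cov_re

    @property
    def sigma2(self) -> float:
        return self.fit.sigma2

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def random_effects(self) -> dict:
        return self.fit.random_effects

    def covariate_test(self, index: int = 2) -> tuple[float, float, float]:
        """(estimate, t, two-tailed p) for a level-2 covariate coefficient."""
        est = float(self.fit.beta[index])
        t = est / float(self.fit.bse[index])
        p = 2.0 * float(spstats.t.sf(abs(t), self.df))
        return est, t, p

    # -- residual diagnostics ------------------------------------------------
    def standardized_residuals(self, kind: str = "conditional") -> np.ndarray:
        """Residuals divided by the estimated residual SD.

        ``conditional`` (default) uses y − fixed − predicted random part;
        ``marginal`` uses y − fixed part only (scaled by the same sigma).
        """
        if kind == "conditional":
            r = self.fit.resid
        elif kind == "marginal":
            r = self.fit.resid_marginal
        else:
            raise ValueError(f"kind must be 'conditional' or 'marginal', got {kind!r}")
        return r / np.sqrt(self.fit.sigma2)

    def outlier_mask(self, threshold: float | None = None, kind: str = "conditional") -> np.ndarray:
        thr = self.outlier_threshold if threshold is None else threshold
        return np.abs(self.standardized_residuals(kind)) > thr

    @property
    def outlier_fraction(self) -> float:
        """Percentage of observations with |standardized residual| > threshold."""
        return 100.0 * float(self.outlier_mask().mean())

    def refit_without_outliers(self, threshold: float | None = None) -> "ConcordanceResults":
        """Refit after dropping |z| > threshold observations.

        The degrees of freedom keep the m − l − 1 rule with the original
        participant count. A participant left with fewer than 3 observations
        would be retained with a warning (removal never drops participants).
        """
        if not self.fit.converged:
            raise RuntimeError("refusing to refit around a non-converged model")
        mask = self.outlier_mask(threshold)
        m = self.model
        keep = ~mask
        for g in np.unique(m.groups):
            left = int((keep & (m.groups == g)).sum())
            if left < 3:
                warnings.warn(
                    f"participant {g!r} would retain only {left} observations after "
                    "outlier removal; its outliers are kept",
                    stacklevel=2,
                )
                keep |= m.groups == g
        sub = ConcordanceLMM(
            m.endog[keep],
            m.exog_valence[keep],
            m.groups[keep],
            covariates=None if m.covariates is None else m.covariates[keep],
            muscle=m.muscle,
            device=m.device,
        )
        res = sub.fit(direction=self.direction, outlier_threshold=self.outlier_threshold)
        res.df = self.df  # participant count unchanged by observation removal
        res.removed_outliers = np.where(~keep)[0]
        self.refit = res
        return res

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        f = self.fit
        lines = [
            "Valence-EMG concordance: ML linear mixed model "
            "(random by-participant slopes and intercepts)",
            "=" * 78,
            f"muscle: {self.model.muscle or '-':<10} device: {self.model.device or '-':<10} "
            f"participants: {f.n_groups}   observations: {f.n_obs}",
            f"log-likelihood: {f.llf:.3f}   sigma^2: {f.sigma2:.4f}   "
            f"converged: {f.converged}" + ("   (sigma^2 at boundary)" if f.boundary_sigma else ""),
            "-" * 78,
            f"{'effect':<22}{'estimate':>10}{'SE':>10}{'t':>8}{'df':>5}{'p (1-tailed)':>14}",
            f"{'intercept (gamma00)':<22}{self.gamma00:>10.4f}{f.bse[0]:>10.4f}",
            f"{'valence slope (gamma10)':<22}{self.beta:>10.4f}{self.se:>10.4f}"
            f"{self.tvalue:>8.2f}{self.df:>5d}{self.p_one_tailed:>14.4f}",
        ]
        if len(f.beta) > 2:
            for k in range(2, len(f.beta)):
                est, t, p = self.covariate_test(k)
                lines.append(
                    f"{'covariate[%d]' % (k - 2):<22}{est:>10.4f}{f.bse[k]:>10.4f}"
                    f"{t:>8.2f}{self.df:>5d}{p:>14.4f}  (2-tailed)"
                )
        tau = self.cov_re
        lines += [
            "-" * 78,
            f"random effects: var(intercept)={tau[0, 0]:.4f}  var(slope)={tau[1, 1]:.4f}  "
            f"cov={tau[0, 1]:.4f}",
            f"hypothesized direction: {self.direction}   "
            f"outliers |z|>{self.outlier_threshold:g}: {self.outlier_fraction:.1f}%",
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        """One results-table row (optionally including the outlier refit)."""
        row = {
            "device": self.model.device,
            "muscle": self.model.muscle,
            "beta": self.beta,
            "se": self.se,
            "t": self.tvalue,
            "df": self.df,
            "p_one_tailed": self.p_one_tailed,
            "outlier_pct": self.outlier_fraction,
        }
        if self.refit is not None:
            row.update(
                beta_refit=self.refit.beta,
                t_refit=self.refit.tvalue,
                p_refit=self.refit.p_one_tailed,
            )
        return row

    def plot_group_scatter(self, ax=None):
        """Group-mean scatter of EMG on valence with its regression line."""
        import matplotlib.pyplot as plt

        tab, (b0, b1) = group_summary(self.model.frame())
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(tab.valence, tab.emg_mean, color="k", s=18)
        xs = np.linspace(tab.valence.min(), tab.valence.max(), 50)
        ax.plot(xs, b0 + b1 * xs, color="tab:red")
        ax.set_xlabel("valence rating")
        ax.set_ylabel("standardized EMG")
        ax.set_title(f"{self.model.muscle} {self.model.device}".strip())
        return ax


class ConcordanceLMM:
    """Random-slope concordance model between 1 Hz valence and EMG envelope.

    Parameters
    ----------
    endog : standardized EMG envelope values (z units), one per 1-s bin.
    exog_valence : aligned continuous valence ratings (1–9 scale).
    groups : participant labels.
    covariates : optional (n, k) participant-level covariates (e.g. sex),
        entering the fixed part only; the df rule then uses l = k.
    """

    def __init__(
        self,
        endog,
        exog_valence,
        groups,
        covariates=None,
        muscle: str = "",
        device: str = "",
    ):
        self.endog = np.asarray(endog, float)
        self.exog_valence = np.asarray(exog_valence, float)
        self.groups = np.asarray(groups)
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, float))
            if covariates.shape[0] != len(self.endog):
                covariates = covariates.T
        self.covariates = covariates
        self.muscle = muscle
        self.device = device
        ok = np.isfinite(self.endog) & np.isfinite(self.exog_valence)
        if not ok.all():
            self.endog = self.endog[ok]
            self.exog_valence = self.exog_valence[ok]
            self.groups = self.groups[ok]
            if self.covariates is not None:
                self.covariates = self.covariates[ok]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        emg_col: str = "emg_z",
        valence_col: str = "valence",
        group_col: str = "participant",
        covariate_cols: list[str] | None = None,
        muscle: str = "",
        device: str = "",
    ) -> "ConcordanceLMM":
        cov = data[covariate_cols].to_numpy(float) if covariate_cols else None
        return cls(
            data[emg_col].to_numpy(float),
            data[valence_col].to_numpy(float),
            data[group_col].to_numpy(),
            covariates=cov,
            muscle=muscle,
            device=device,
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.groups,
                "valence": self.exog_valence,
                "emg_z": self.endog,
            }
        )

    @property
    def n_participants(self) -> int:
        return len(np.unique(self.groups))

    @property
    def n_level2_predictors(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def design(self) -> np.ndarray:
        cols = [np.ones(len(self.endog)), self.exog_valence]
        if self.covariates is not None:
            cols.extend(self.covariates.T)
        return np.column_stack(cols)

    def fit(
        self,
        direction: str = "negative",
        outlier_threshold: float = OUTLIER_SD,
    ) -> ConcordanceResults:
        """ML fit; returns results with the one-tailed m − l − 1 df test."""
        fitres = fit_random_slope_ml(
            self.endog, self.design(), self.exog_valence, self.groups
        )
        df = df_m_l_1(self.n_participants, self.n_level2_predictors)
        return ConcordanceResults(
            model=self,
            fit=fitres,
            direction=direction,
            df=df,
            outlier_threshold=outlier_threshold,
        )


def slope_t_test(result: ConcordanceResults, direction: str | None = None) -> dict:
    """One-tailed t-test of the fixed valence slope at m − l − 1 df."""
    if not result.converged:
        raise RuntimeError("model did not converge; t-test refused")
    d = direction or result.direction
    t = result.tvalue
    return {
        "beta": result.beta,
        "se": result.se,
        "t": t,
        "df": result.df,
        "p": one_tailed_p(t, result.df, d),
        "direction": d,
    }


def zero_lag_correlation(x, y) -> float:
    """Pearson r between aligned 1 Hz series; NaN if either is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(spstats.pearsonr(x, y)[0])


def cross_correlation(x, y, max_lag_s: int) -> pd.DataFrame:
    """Pearson r at each integer-second lag over the overlapping support.

    Positive lag means ``y`` trails ``x`` by that many seconds (r computed
    between x[:n−L] and y[L:]).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = min(len(x), len(y))
    rows = []
    for lag in range(-max_lag_s, max_lag_s + 1):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:n]
        else:
            xs, ys = x[-lag:n], y[: n + lag]
        if len(xs) < 3:
            rows.append((lag, float("nan")))
        else:
            rows.append((lag, zero_lag_correlation(xs, ys)))
    return pd.DataFrame(rows, columns=["lag_s", "r"])


def group_summary(
    data: pd.DataFrame,
    valence_col: str = "valence",
    emg_col: str = "emg_z",
    decimals: int = 1,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Group-mean scatter table and least-squares line.

    Valence values are rounded to ``decimals`` and the EMG is averaged per
    rounded value over all participants; the (intercept, slope) of the
    ordinary least-squares line through the group means is returned for the
    regression-line overlay.
    """
    d = data[[valence_col, emg_col]].dropna()
    g = (
        d.assign(valence=d[valence_col].round(decimals))
        .groupby("valence")[emg_col]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "emg_mean", "sem": "emg_sem", "count": "n"})
    )
    slope, intercept = np.polyfit(g.valence, g.emg_mean, 1)
    return g, (float(intercept), float(slope))


def group_timecourse(
    data: pd.DataFrame,
    value_col: str = "emg_z",
    time_col: str = "t_bin_s",
    end_point_s: float | None = None,
    coverage: float = 0.90,
) -> pd.DataFrame:
    """Second-by-second group means ± SE across trials and participants.

    If ``end_point_s`` is omitted it is chosen as the shortest duration
    covering ``coverage`` of the trials (e.g. 90% of game frames), mirroring
    the end-point rule used for variable-length stimuli.
    """
    d = data.dropna(subset=[value_col])
    if end_point_s is None:
        lengths = d.groupby(["participant", "trial_id"])[time_col].max() + 1
        end_point_s = float(np.ceil(np.quantile(lengths, coverage)))
    d = d[d[time_col] < end_point_s]
    out = (
        d.groupby(time_col)[value_col]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "value_mean", "sem": "value_sem", "count": "n"})
    )
    out.attrs["end_point_s"] = end_point_s
    return out


def sex_covariate_sensitivity(
    data: pd.DataFrame,
    sex_by_participant: dict,
    direction: str,
    emg_col: str = "emg_z",
    valence_col: str = "valence",
    group_col: str = "participant",
) -> dict:
    """Refit with a participant-level sex covariate and compare.

    The covariate enters the fixed part; df becomes m − 1 − 1. Reports the
    original and covariate-adjusted slope tests, whether significance is
    unchanged at 0.05, and the covariate's two-tailed p.
    """
    levels = sorted(set(sex_by_participant.values()))
    if len(levels) < 2:
        raise ValueError("sex covariate requires both levels present")
    coded = data[group_col].map(lambda g: float(sex_by_participant[g] == levels[1]))
    base = ConcordanceLMM.from_dataframe(
        data, emg_col=emg_col, valence_col=valence_col, group_col=group_col
    ).fit(direction=direction)
    adj_model = ConcordanceLMM(
        data[emg_col].to_numpy(float),
        data[valence_col].to_numpy(float),
        data[group_col].to_numpy(),
        covariates=coded.to_numpy()[:, None],
    )
    adj = adj_model.fit(direction=direction)
    cov_est, cov_t, cov_p = adj.covariate_test(2)
    return {
        "beta_original": base.beta,
        "p_original": base.p_one_tailed,
        "beta_adjusted": adj.beta,
        "p_adjusted": adj.p_one_tailed,
        "df_adjusted": adj.df,
        "significance_unchanged": (base.p_one_tailed < 0.05) == (adj.p_one_tailed < 0.05),
        "covariate_estimate": cov_est,
        "covariate_t": cov_t,
        "covariate_p": cov_p,
    }
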
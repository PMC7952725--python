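"""Rating-side analyses.

Overall 9-point affect-grid ratings are tested against the neutral midpoint
(5) with two-tailed one-sample t-tests, Bonferroni-corrected across the
rating scales and conditions (10 tests in the film experiment). The
cued-recall continuous-rating procedure is validated by per-participant
Pearson correlations between on-line and recalled traces, themselves tested
against zero. Sample-size planning follows the two-step procedure: estimate
per-participant correlation coefficients, test their mean against zero with
a one-sample t-test, and find the smallest n reaching the target power
under the noncentral t distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as spstats

NEUTRAL = 5.0


def bonferroni(p: float, n_tests: int) -> float:
    """Multiply by the number of tests; clip at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(min(p * n_tests, 1.0))


def one_sample_t_vs_neutral(
    ratings, mu0: float = NEUTRAL, n_tests: int = 1
) -> dict:
    """Two-tailed one-sample t-test against the neutral state, corrected.

    Zero-variance input centered on ``mu0`` reports t = 0 (no evidence of a
    shift); zero variance away from ``mu0`` is degenerate and rejected.
    """
    x = np.asarray(ratings, float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError(f"need >= 2 ratings, got {n}")
    if x.std(ddof=1) == 0:
        if x.mean() == mu0:
            return {
                "mean": float(x.mean()), "sd": 0.0, "t": 0.0, "df": n - 1,
                "p_raw": 1.0, "p_bonferroni": 1.0, "n": n,
            }
        raise ValueError("zero variance with mean != mu0: t undefined")
    t, p = spstats.ttest_1samp(x, popmean=mu0)
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "t": float(t),
        "df": n - 1,
        "p_raw": float(p),
        "p_bonferroni": bonferroni(float(p), n_tests),
        "n": n,
    }


def overall_rating_table(
    overall: pd.DataFrame, scales: tuple[str, ...] = ("valence", "arousal"),
    mu0: float = NEUTRAL,
) -> pd.DataFrame:
    """Per-condition, per-scale tests vs neutral, Bonferroni over all tests."""
    conditions = list(pd.unique(overall.condition))
    present = [s for s in scales if s in overall and overall[s].notna().any()]
    n_tests = len(conditions) * len(present)
    rows = []
    for cond in conditions:
        sub = overall[overall.condition == cond]
        for scale in present:
            vals = sub.groupby("participant")[scale].mean() if "participant" in sub else sub[scale]
            res = one_sample_t_vs_neutral(vals, mu0=mu0, n_tests=n_tests)
            rows.append({"condition": cond, "scale": scale, **res})
    return pd.DataFrame(rows)


def recall_validation(
    online: dict,
    recall: dict,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Validate cued-recall traces against on-line traces.

    ``online`` and ``recall`` map (participant, condition) -> equal-length
    1 Hz traces. Per pair, the Pearson r is computed (constant traces are
    excluded as missing with a logged count); per condition, the r values
    are tested against zero with a Bonferroni-corrected two-tailed
    one-sample t-test.
    """
    rows = []
    n_excluded = 0
    for key, x in online.items():
        if key not in recall:
            raise KeyError(f"no recall trace for {key}")
        y = recall[key]
        if len(x) != len(y):
            raise ValueError(f"{key}: trace lengths differ ({len(x)} vs {len(y)})")
        participant, condition = key
        if np.std(x) == 0 or np.std(y) == 0:
            n_excluded += 1
            continue
        r = float(spstats.pearsonr(np.asarray(x, float), np.asarray(y, float))[0])
        rows.append({"participant": participant, "condition": condition, "r": r})
    per_pair = pd.DataFrame(rows)
    conditions = list(pd.unique(per_pair.condition)) if len(per_pair) else []
    if n_tests is None:
        n_tests = max(len(conditions), 1)
    out = []
    for cond in conditions:
        rs = per_pair.loc[per_pair.condition == cond, "r"].to_numpy()
        t, p = spstats.ttest_1samp(rs, popmean=0.0)
        out.append(
            {
                "condition": cond,
                "mean_r": float(rs.mean()),
                "sd_r": float(rs.std(ddof=1)) if len(rs) > 1 else float("nan"),
                "t": float(t),
                "df": len(rs) - 1,
                "p_bonf": bonferroni(float(p), n_tests),
                "n": len(rs),
            }
        )
    table = pd.DataFrame(out)
    table.attrs["n_excluded_constant"] = n_excluded
    return table


def power_one_sample_t(d: float, n: int, alpha: float = 0.05, tails: int = 1) -> float:
    """Power of the one-sample t-test at effect size d and sample size n."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 1:
        crit = spstats.t.ppf(1 - alpha, df)
        return float(spstats.nct.sf(crit, df, nc))
    crit = spstats.t.ppf(1 - alpha / 2, df)
    return float(spstats.nct.sf(crit, df, nc) + spstats.nct.cdf(-crit, df, nc))


def required_sample_size(
    effect_size_d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 1,
    n_max: int = 1000,
) -> int:
    """Smallest n whose one-sample t-test reaches the target power.

    Exhaustive integer scan using the noncentral t with noncentrality
    d·sqrt(n) and df n − 1 (exactness over closed-form approximation at
    this scale).
    """
    if effect_size_d <= 0:
        raise ValueError("effect size d must be > 0")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        if power_one_sample_t(effect_size_d, n, alpha, tails) >= power:
            return n
    raise ValueError(f"no n <= {n_max} reaches power {power} at d={effect_size_d}")
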
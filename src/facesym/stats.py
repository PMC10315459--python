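"""Group-level statistics on individual asymmetry scores.

Two-way ANOVA (sex × ethnicity) with Type II sums of squares — appropriate
for the mildly unbalanced designs these samples have (e.g. 29 vs 30 per
group) when the interaction is weak — plus Shapiro–Wilk and Bartlett
assumption checks on the residuals/groups; Tukey–Kramer post-hoc comparisons;
and a bootstrapped Welch two-sample t-test between databases.

The bootstrap follows the studentized null-shift scheme: both samples are
shifted to the combined mean, resampled with replacement B times, and the
Welch statistic recomputed; p = (1 + #{|t*| ≥ |t_obs|}) / (B + 1). The
confidence interval is the percentile interval of the mean difference over
the *unshifted* resamples (same resampling indices). Classical and bootstrap
p-values are always reported together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class TwoWayAnovaResult:
    """Type II ANOVA table plus residual diagnostics.

    ``table`` rows: sex, ethnicity, sex:ethnicity, Residual with columns
    SS, df, F, p. The diagnostics are reported, never used to switch methods
    automatically.
    """

    table: pd.DataFrame
    shapiro_stat: float
    shapiro_p: float
    bartlett_stat: float
    bartlett_p: float
    n: int


def two_way_anova(
    scores: Sequence[float],
    sex: Sequence[str],
    ethnicity: Sequence[str],
) -> TwoWayAnovaResult:
    """Two-way fixed-effects ANOVA of scores on sex × ethnicity (Type II SS).

    Every sex × ethnicity cell must be nonempty. Shapiro–Wilk runs on the
    model residuals, Bartlett across the cells.
    """
    df = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "sex": [str(x) for x in sex],
            "ethnicity": [str(x) for x in ethnicity],
        }
    )
    counts = df.groupby(["sex", "ethnicity"], sort=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(df["sex"].unique()), sorted(df["ethnicity"].unique())]
    )
    empty = [c for c in full if c not in counts.index]
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    if df["sex"].nunique() < 2 or df["ethnicity"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")

    degenerate = np.ptp(df["score"].to_numpy()) == 0.0
    with warnings.catch_warnings():
        if degenerate:
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.warn(
                "all scores identical: SS are 0 and F undefined (NaN)",
                UserWarning,
                stacklevel=2,
            )
        model = smf.ols("score ~ C(sex) * C(ethnicity)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    if degenerate:
        # the OLS solve leaves rounding noise in the SS; report the exact
        # degenerate values instead of noise ratios
        anova["sum_sq"] = 0.0
        anova["F"] = np.nan
        anova["PR(>F)"] = np.nan
    anova = anova.rename(
        index={
            "C(sex)": "sex",
            "C(ethnicity)": "ethnicity",
            "C(sex):C(ethnicity)": "sex:ethnicity",
        }
    )
    anova.columns = ["SS", "df", "F", "p"][: len(anova.columns)]

    resid = np.asarray(model.resid)
    if np.ptp(resid) > 0:
        sw_stat, sw_p = sps.shapiro(resid)
    else:
        sw_stat, sw_p = float("nan"), float("nan")
    cells = [g["score"].to_numpy() for _, g in df.groupby(["sex", "ethnicity"])]
    if all(np.ptp(c) > 0 for c in cells):
        bt_stat, bt_p = sps.bartlett(*cells)
    else:
        bt_stat, bt_p = float("nan"), float("nan")
    return TwoWayAnovaResult(
        table=anova,
        shapiro_stat=float(sw_stat),
        shapiro_p=float(sw_p),
        bartlett_stat=float(bt_stat),
        bartlett_p=float(bt_p),
        n=len(df),
    )


def tukey_hsd(
    scores: Sequence[float], group: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons (studentized range, unequal n).

    Returns a tidy frame with columns group1, group2, mean_diff, p_adj,
    ci_low, ci_high, reject.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([str(x) for x in group], dtype=object)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("tukey_hsd needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError(
            f"groups with fewer than 2 members: {list(uniq[counts < 2])}"
        )
    res = pairwise_tukeyhsd(scores, labels, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.lower() for c in res.summary().data[0]],
    )
    frame = frame.rename(
        columns={"meandiff": "mean_diff", "p-adj": "p_adj",
                 "lower": "ci_low", "upper": "ci_high"}
    )
    for col in ("mean_diff", "p_adj", "ci_low", "ci_high"):
        frame[col] = frame[col].astype(float)
    frame["reject"] = frame["reject"].astype(bool)
    return frame[
        ["group1", "group2", "mean_diff", "p_adj", "ci_low", "ci_high", "reject"]
    ]


@dataclass(frozen=True)
class BootWelchResult:
    t_obs: float
    satterthwaite_df: float
    mean_diff: float
    ci_low: float
    ci_high: float
    p_classical: float
    p_bootstrap: float
    n_boot: int
    seed: int | tuple[int, int] | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "t_obs": self.t_obs,
            "satterthwaite_df": self.satterthwaite_df,
            "mean_diff": self.mean_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_classical": self.p_classical,
            "p_bootstrap": self.p_bootstrap,
            "n_boot": self.n_boot,
            "seed": str(self.seed),
        }])


def _welch_t(
    mx: np.ndarray, vx: np.ndarray, nx: int, my: np.ndarray, vy: np.ndarray, ny: int
) -> np.ndarray:
    return (mx - my) / np.sqrt(vx / nx + vy / ny)


def boot_welch_t(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int | tuple[int, int] | None = None,
    ci: float = 0.95,
) -> BootWelchResult:
    """Welch two-sample t-test with a studentized bootstrap p-value and a
    percentile bootstrap CI for the mean difference (x minus y).

    ``seed`` may be an int (split into one child stream per sample) or an
    explicit ``(seed_x, seed_y)`` pair. With the pair form the procedure is
    exactly exchangeable: ``boot_welch_t(y, x, seed=(sy, sx))`` mirrors
    ``boot_welch_t(x, y, seed=(sx, sy))`` with flipped signs and identical
    p-values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least 2 observations")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("zero variance in both samples")

    se2x, se2y = vx / nx, vy / ny
    t_obs = float((x.mean() - y.mean()) / np.sqrt(se2x + se2y))
    df = float(
        (se2x + se2y) ** 2
        / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
    )
    p_classical = float(2.0 * sps.t.sf(abs(t_obs), df))

    if isinstance(seed, tuple):
        gx = np.random.default_rng(seed[0])
        gy = np.random.default_rng(seed[1])
    else:
        ss = np.random.SeedSequence(seed)
        cx, cy = ss.spawn(2)
        gx, gy = np.random.default_rng(cx), np.random.default_rng(cy)
    ix = gx.integers(0, nx, size=(n_boot, nx))
    iy = gy.integers(0, ny, size=(n_boot, ny))

    # null-enforced resamples for the p-value
    gm = np.concatenate([x, y]).mean()
    x0, y0 = x - x.mean() + gm, y - y.mean() + gm
    bx0, by0 = x0[ix], y0[iy]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = _welch_t(
            bx0.mean(axis=1), bx0.var(axis=1, ddof=1), nx,
            by0.mean(axis=1), by0.var(axis=1, ddof=1), ny,
        )
    t_star = t_star[np.isfinite(t_star)]
    p_boot = float((1.0 + np.sum(np.abs(t_star) >= abs(t_obs))) / (n_boot + 1.0))

    # unshifted resamples (same indices) for the percentile CI
    diffs = x[ix].mean(axis=1) - y[iy].mean(axis=1)
    alpha = 1.0 - ci
    ci_low, ci_high = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])

    mean_diff = float(x.mean() - y.mean())
    if not (ci_low <= mean_diff <= ci_high):
        warnings.warn(
            "percentile CI does not contain the observed mean difference",
            UserWarning,
            stacklevel=2,
        )
    return BootWelchResult(
        t_obs=t_obs,
        satterthwaite_df=df,
        mean_diff=mean_diff,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_classical=p_classical,
        p_bootstrap=p_boot,
        n_boot=n_boot,
        seed=seed,
    )
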
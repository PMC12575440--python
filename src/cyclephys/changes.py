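"""Pre/post change statistics: change scores, effect sizes, block contrast, regressions.

The study is a within-subject two-period design: every rider completes a
moderate-intensity block (MIT) and, after washout, a high-intensity block
(HIT).  Between-block comparison of pre→post changes uses a baseline-adjusted
within-subject analysis: the per-participant difference of change scores is
regressed on the (centred) difference of baselines, and the intercept is the
block×time contrast.  For complete balanced two-period data this reproduces
the contrast a mixed model with participant random intercepts would give.

Effect sizes are two-sample pooled-SD Cohen's d on percentage changes
(%-point changes for gross-efficiency and fractional-utilization outcomes),
interpreted on the Rhea scale for highly trained subjects; the paired d_z is
reported alongside for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChangeScore",
    "BlockComparison",
    "RegressionFit",
    "PERCENT_POINT_OUTCOMES",
    "change_scores",
    "cohens_d",
    "rhea_label",
    "compare_blocks",
    "fit_adjusted_regression",
]

#: Outcomes whose "percent change" is reported as %-point change (already-%
#: quantities: gross efficiency and fractional utilization).
PERCENT_POINT_OUTCOMES = frozenset(
    {
        "frac_util_4mmol",
        "frac_util_15min",
        "ge_fresh_3rd",
        "ge_fresh_2nd",
        "ge_tired_3rd",
        "ge_tired_2nd",
    }
)

KEYS = ["participant_id", "block", "outcome"]


@dataclass(frozen=True)
class ChangeScore:
    participant_id: str
    block: str
    outcome: str
    pre: float
    post: float

    @property
    def delta(self) -> float:
        return self.post - self.pre

    @property
    def pct(self) -> float:
        if self.pre == 0:
            raise ZeroDivisionError("percent change undefined for pre = 0")
        return 100.0 * self.delta / self.pre


def change_scores(pre: pd.DataFrame, post: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Match pre/post tables on (participant, block, outcome) and score changes.

    Input tables are long-format with columns participant_id, block, outcome,
    value.  Returns (scores, n_unmatched): scores has delta = post − pre and
    pct = 100·delta/pre per participant (NaN pct where pre = 0, or %-point
    delta for outcomes in PERCENT_POINT_OUTCOMES); unmatched rows on either
    side are excluded and counted.
    """
    for name, df in (("pre", pre), ("post", post)):
        missing = set(KEYS + ["value"]) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    merged = pre.merge(post, on=KEYS, how="outer", suffixes=("_pre", "_post"))
    unmatched = int(merged["value_pre"].isna().sum() + merged["value_post"].isna().sum())
    merged = merged.dropna(subset=["value_pre", "value_post"]).reset_index(drop=True)
    out = merged.rename(columns={"value_pre": "pre", "value_post": "post"})
    out["delta"] = out["post"] - out["pre"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * out["delta"] / out["pre"]
    pct[out["pre"] == 0] = np.nan
    pp = out["outcome"].isin(PERCENT_POINT_OUTCOMES)
    out["pct"] = np.where(pp, out["delta"], pct)
    return out[KEYS + ["pre", "post", "delta", "pct"]], unmatched


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample Cohen's d = (mean_a − mean_b) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def rhea_label(d: float) -> str:
    """Effect-size magnitude on the Rhea scale for highly trained subjects.

    |d| < 0.25 trivial, 0.25–0.49 small, 0.5–1.0 moderate, > 1.0 large.
    """
    m = abs(d)
    if m < 0.25:
        return "trivial"
    if m < 0.5:
        return "small"
    if m <= 1.0:
        return "moderate"
    return "large"


@dataclass
class BlockComparison:
    """Paired pre/post comparison of one outcome across two training blocks."""

    outcome: str
    blocks: tuple[str, str]
    n: int
    n_excluded: int
    mean_delta: dict      # block -> mean of post-pre
    sd_delta: dict
    mean_pct: dict        # block -> mean per-participant % (or %-point) change
    sd_pct: dict
    p_within: dict        # block -> paired t-test p (delta vs 0)
    contrast: float       # baseline-adjusted between-block difference of deltas (A - B)
    contrast_se: float
    contrast_p: float     # block x time p
    d: float              # pooled two-sample Cohen's d on pct changes (A vs B)
    d_label: str
    d_z: float            # paired d_z on pct-change differences (non-standard, reported alongside)


def _paired_t_p(x: np.ndarray) -> float:
    """Two-sided p for mean(x) = 0 (one-sample t)."""
    n = x.size
    se = x.std(ddof=1) / np.sqrt(n)
    if se == 0:
        return 1.0 if x.mean() == 0 else 0.0
    t = x.mean() / se
    return float(2 * stats.t.sf(abs(t), n - 1))


def compare_blocks(
    scores: pd.DataFrame,
    outcome: str,
    blocks: tuple[str, str] = ("MIT", "HIT"),
) -> BlockComparison:
    """Baseline-adjusted within-subject comparison of change scores between blocks.

    Only participants with complete data in both blocks enter (completed-cases
    design); incomplete pairs are excluded and counted.  Within-block p-values
    are paired t-tests of delta against zero.  The between-block contrast is
    the intercept of OLS of d_i = delta_A − delta_B on the centred baseline
    difference, with a t-test on n−2 degrees of freedom.
    """
    sub = scores[scores["outcome"] == outcome]
    a, b = blocks
    wide = sub.pivot_table(index="participant_id", columns="block",
                           values=["pre", "delta", "pct"], aggfunc="first")
    total = wide.shape[0]
    complete = wide.dropna()
    n_excluded = total - complete.shape[0]
    n = complete.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs for outcome {outcome!r}, got {n}")
    delta_a = complete[("delta", a)].to_numpy()
    delta_b = complete[("delta", b)].to_numpy()
    pct_a = complete[("pct", a)].to_numpy()
    pct_b = complete[("pct", b)].to_numpy()
    base_a = complete[("pre", a)].to_numpy()
    base_b = complete[("pre", b)].to_numpy()

    # baseline-adjusted paired ANCOVA: d_i = c + g*(x_i - mean x) + e
    d_i = delta_a - delta_b
    x = base_a - base_b
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx > 0 and n >= 3:
        g = float(xc @ d_i) / sxx
        resid = d_i - d_i.mean() - g * xc
        dof = n - 2
    else:  # identical baselines in both blocks: plain paired analysis
        resid = d_i - d_i.mean()
        dof = n - 1
    contrast = float(d_i.mean())
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 / n)
    if se == 0:
        p = 1.0 if contrast == 0 else 0.0
    else:
        p = float(2 * stats.t.sf(abs(contrast) / se, dof))

    d_diffs = pct_a - pct_b
    sd_diff = d_diffs.std(ddof=1)
    d_z = float(d_diffs.mean() / sd_diff) if sd_diff > 0 else float("nan")
    if np.all(pct_a == 0) and np.all(pct_b == 0):
        d_val = 0.0  # nothing changed anywhere: trivially no effect
    else:
        d_val = cohens_d(pct_a, pct_b)
    return BlockComparison(
        outcome=outcome,
        blocks=blocks,
        n=n,
        n_excluded=n_excluded,
        mean_delta={a: float(delta_a.mean()), b: float(delta_b.mean())},
        sd_delta={a: float(delta_a.std(ddof=1)), b: float(delta_b.std(ddof=1))},
        mean_pct={a: float(pct_a.mean()), b: float(pct_b.mean())},
        sd_pct={a: float(pct_a.std(ddof=1)), b: float(pct_b.std(ddof=1))},
        p_within={a: _paired_t_p(delta_a), b: _paired_t_p(delta_b)},
        contrast=contrast,
        contrast_se=float(se),
        contrast_p=p,
        d=d_val,
        d_label=rhea_label(d_val),
        d_z=d_z,
    )


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of a change score on a training variable with covariates."""

    predictor: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    r2: float
    r2_adj: float
    covariates: tuple[str, ...]
    n: int


def fit_adjusted_regression(
    data: pd.DataFrame,
    y: str,
    predictor: str,
    covariates: Sequence[str] = (),
) -> RegressionFit:
    """OLS of ``y`` on ``predictor`` plus covariates (baseline, Δbody mass, sex...).

    Reports the predictor's estimate with t-based 95% CI and p, plus R² and
    adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).  A rank-deficient design raises,
    naming the collinear columns.
    """
    import statsmodels.api as sm

    cols = [predictor, *covariates]
    X = data[cols].astype(float)
    yv = data[y].astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} observations for {k} predictors, got {n}")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        constant = [c for c in cols if X[c].nunique() <= 1]
        corr = X.corr().abs()
        collinear = sorted(
            {c for c in cols for c2 in cols if c != c2 and corr.loc[c, c2] > 0.999}
        )
        named = constant or collinear or cols
        raise ValueError(f"rank-deficient design; collinear columns: {named}")
    fit = sm.OLS(yv, Xc).fit()
    ci = fit.conf_int().loc[predictor]
    return RegressionFit(
        predictor=predictor,
        estimate=float(fit.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[predictor]),
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        covariates=tuple(covariates),
        n=n,
    )
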
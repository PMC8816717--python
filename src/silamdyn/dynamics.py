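"""Cohort statistics, mechanism classification, and aging trends.

Per-protein two-tailed two-sample t-tests compare the per-mouse
incorporation (turnover axis) and integrated abundance (amount axis)
between cohorts; the global average protein turnover (GAPT) summarizes
the whole quantified proteome; and each protein's (turnover change,
abundance change) coordinate is classified into one of six mechanistic
regimes — net synthesis up/down, net degradation up/down, or an
uncoupled repair-flux change up/down — the logic of the dynaplot.

The classical pooled-variance Student t-test is the default (with
cohorts of three, its fixed 4 degrees of freedom keep power and
calibration; the Welch variant, available via ``equal_var=False``, is
markedly conservative and underpowered at this sample size).  p-values are
nominal (no multiple-testing correction by default); Benjamini-Hochberg
adjusted columns can be added on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MECHANISM_PALETTE",
    "GaptSummary",
    "AgingTrend",
    "two_sample_pvalue",
    "turnover_tests",
    "abundance_tests",
    "compute_gapt",
    "classify_mechanism",
    "build_results",
    "aging_trend",
    "dynaplot",
]

_TINY_P = np.finfo(float).tiny

#: Dynaplot colors: net synthesis up (red) / down (blue), net
#: degradation up (magenta) / down (yellow), repair flux up (green) /
#: down (brown), unchanged (grey).
MECHANISM_PALETTE = {
    "synthesis_up": "#d62728",
    "synthesis_down": "#1f77b4",
    "degradation_up": "#e377c2",
    "degradation_down": "#bcbd22",
    "repair_up": "#2ca02c",
    "repair_down": "#8c564b",
    "unchanged": "#b0b0b0",
}


def _welch(m1, v1, n1, m2, v2, n2, equal_var: bool = False):
    """Vectorized two-sided two-sample t-test from group summaries.

    Returns (p, degenerate) where degenerate marks groups whose pooled
    variance is exactly zero: equal means give p = 1, unequal means the
    smallest positive float (the test statistic diverges).
    """
    m1, v1, n1 = (np.asarray(a, float) for a in (m1, v1, n1))
    m2, v2, n2 = (np.asarray(a, float) for a in (m2, v2, n2))
    diff = m2 - m1
    # variance indistinguishable from zero at float precision counts as zero
    scale = np.maximum(np.abs(m1), np.abs(m2))
    vtol = (1e-12 * scale) ** 2
    zero_var = (v1 <= vtol) & (v2 <= vtol)
    diff_zero = np.abs(diff) <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            df = n1 + n2 - 2
        else:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var & diff_zero, 1.0, p)
    p = np.where(zero_var & ~diff_zero, _TINY_P, p)
    degenerate = zero_var & ~diff_zero
    return np.clip(p, _TINY_P, 1.0), degenerate


def two_sample_pvalue(a, b, equal_var: bool = True) -> tuple[float, bool]:
    """Two-sided two-sample t-test on two value vectors (>= 2 each)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per cohort")
    p, degen = _welch(
        a.mean(), a.var(ddof=1), len(a), b.mean(), b.var(ddof=1), len(b), equal_var
    )
    return float(p), bool(degen)


def _cohort_tests(
    long: pd.DataFrame, value: str, equal_var: bool
) -> pd.DataFrame:
    """Per-protein cohort summaries and two-sample test from a long table."""
    g = long.groupby(["protein_id", "cohort"])[value]
    summ = g.agg(["mean", "var", "count"]).unstack("cohort")
    for cohort in ("control", "disease"):
        if ("mean", cohort) not in summ.columns:
            raise ValueError(f"cohort {cohort!r} missing from input")
    enough = (summ[("count", "control")] >= 2) & (summ[("count", "disease")] >= 2)
    n_drop = int((~enough).sum())
    if n_drop:
        logger.info("dropping %d proteins with <2 mice in a cohort", n_drop)
    summ = summ[enough]
    p, degen = _welch(
        summ[("mean", "control")],
        summ[("var", "control")],
        summ[("count", "control")],
        summ[("mean", "disease")],
        summ[("var", "disease")],
        summ[("count", "disease")],
        equal_var,
    )
    return pd.DataFrame(
        {
            "protein_id": summ.index,
            "mean_control": summ[("mean", "control")].to_numpy(),
            "mean_disease": summ[("mean", "disease")].to_numpy(),
            "n_control": summ[("count", "control")].to_numpy(dtype=int),
            "n_disease": summ[("count", "disease")].to_numpy(dtype=int),
            "p_value": p,
            "degenerate": degen,
        }
    ).reset_index(drop=True)


def turnover_tests(
    merged_incorporation: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Per-protein turnover comparison from merged incorporation values.

    Input is the long per-mouse table after the fraction merge.  Output
    columns: mean incorporation per cohort, delta (disease - control,
    incorporation fraction) and delta_pp (percentage points), two-tailed
    p-value, and a degenerate flag for zero-variance groups.
    """
    out = _cohort_tests(merged_incorporation, "incorporation", equal_var)
    out = out.rename(
        columns={
            "mean_control": "mean_incorporation_control",
            "mean_disease": "mean_incorporation_disease",
        }
    )
    out["delta"] = out["mean_incorporation_disease"] - out["mean_incorporation_control"]
    out["delta_pp"] = 100.0 * out["delta"]
    return out


def abundance_tests(profiles: pd.DataFrame, equal_var: bool = True) -> pd.DataFrame:
    """Per-protein abundance comparison from integrated profiles.

    delta is the raw intensity difference; log2_ratio is the ratiometric
    axis used by the dynaplot.  The t-test runs on raw intensities.
    """
    out = _cohort_tests(profiles, "abundance", equal_var)
    out = out.rename(
        columns={
            "mean_control": "mean_abundance_control",
            "mean_disease": "mean_abundance_disease",
        }
    )
    out["delta"] = out["mean_abundance_disease"] - out["mean_abundance_control"]
    with np.errstate(divide="ignore"):
        out["log2_ratio"] = np.log2(
            out["mean_abundance_disease"] / out["mean_abundance_control"]
        )
    return out


@dataclass(frozen=True)
class GaptSummary:
    """Global average protein turnover of the two cohorts."""

    gapt_control: float
    gapt_disease: float
    percent_change: float
    p_value: float
    n_proteins: int


def compute_gapt(
    turnover: pd.DataFrame, equal_var: bool = True, paired: bool = False
) -> GaptSummary:
    """Global average protein turnover over a matched protein set.

    GAPT per cohort is the mean, over proteins, of the cohort-mean
    incorporation; ``percent_change`` is 100 x (disease - control) /
    control.  Significance is a two-sided unpaired t-test across the
    per-protein cohort means (``paired=True`` switches to a paired test
    on the per-protein differences).
    """
    if turnover.empty:
        raise ValueError("compute_gapt: empty comparison set")
    c = turnover["mean_incorporation_control"].to_numpy(float)
    d = turnover["mean_incorporation_disease"].to_numpy(float)
    gc, gd = float(c.mean()), float(d.mean())
    if paired:
        diff = d - c
        if np.allclose(diff.var(ddof=1) if len(diff) > 1 else 0.0, 0.0):
            p = 1.0 if np.allclose(diff, 0.0) else float(_TINY_P)
        else:
            p = float(stats.ttest_rel(d, c).pvalue)
    else:
        p, _ = two_sample_pvalue(c, d, equal_var=equal_var)
    return GaptSummary(
        gapt_control=gc,
        gapt_disease=gd,
        percent_change=100.0 * (gd - gc) / gc,
        p_value=float(p),
        n_proteins=int(len(turnover)),
    )


def classify_mechanism(
    delta_turnover,
    p_turnover,
    delta_abundance,
    p_abundance,
    alpha: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify each protein into a dynaplot regime at level ``alpha``.

    Both axes significant: matching signs are net synthesis changes,
    opposing signs net degradation changes.  Turnover alone significant:
    a repair-flux change in the direction of the turnover delta.
    Abundance alone significant: a net-synthesis change by abundance
    sign, flagged uncoupled (the turnover axis did not move).  Neither:
    unchanged.  Returns (labels, uncoupled_flags).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    dt = np.atleast_1d(np.asarray(delta_turnover, float))
    pt = np.atleast_1d(np.asarray(p_turnover, float))
    da = np.atleast_1d(np.asarray(delta_abundance, float))
    pa = np.atleast_1d(np.asarray(p_abundance, float))
    t_sig = (pt < alpha) & (dt != 0)
    a_sig = (pa < alpha) & (da != 0)
    labels = np.full(dt.shape, "unchanged", dtype=object)
    uncoupled = np.zeros(dt.shape, dtype=bool)

    both = t_sig & a_sig
    labels[both & (dt > 0) & (da > 0)] = "synthesis_up"
    labels[both & (dt < 0) & (da < 0)] = "synthesis_down"
    labels[both & (dt > 0) & (da < 0)] = "degradation_up"
    labels[both & (dt < 0) & (da > 0)] = "degradation_down"
    t_only = t_sig & ~a_sig
    labels[t_only & (dt > 0)] = "repair_up"
    labels[t_only & (dt < 0)] = "repair_down"
    a_only = a_sig & ~t_sig
    labels[a_only & (da > 0)] = "synthesis_up"
    labels[a_only & (da < 0)] = "synthesis_down"
    uncoupled[a_only] = True
    return labels, uncoupled


def build_results(
    turnover: pd.DataFrame,
    abundances: pd.DataFrame,
    alpha_dynaplot: float = 0.01,
    alpha_table: float = 0.05,
) -> pd.DataFrame:
    """Join the two per-protein comparisons and classify mechanisms.

    Inner-joins turnover and abundance comparisons on protein_id (the
    unmatched count is logged), attaches significance flags at both the
    table (default 0.05) and dynaplot (default 0.01) thresholds, and the
    mechanism class at the dynaplot threshold.
    """
    t = turnover.rename(
        columns={"p_value": "p_turnover", "delta": "delta_turnover", "degenerate": "degenerate_turnover"}
    )
    a = abundances.rename(
        columns={
            "p_value": "p_abundance",
            "delta": "delta_abundance",
            "log2_ratio": "log2_abundance_ratio",
            "degenerate": "degenerate_abundance",
        }
    )[
        [
            "protein_id",
            "mean_abundance_control",
            "mean_abundance_disease",
            "delta_abundance",
            "log2_abundance_ratio",
            "p_abundance",
            "degenerate_abundance",
        ]
    ]
    res = t.merge(a, on="protein_id", how="inner")
    n_unmatched = len(t) + len(a) - 2 * len(res)
    if n_unmatched:
        logger.info(
            "build_results: %d proteins present on only one axis were dropped",
            n_unmatched,
        )
    labels, uncoupled = classify_mechanism(
        res["delta_turnover"],
        res["p_turnover"],
        res["delta_abundance"],
        res["p_abundance"],
        alpha=alpha_dynaplot,
    )
    res["mechanism_class"] = labels
    res["uncoupled"] = uncoupled
    res["sig_turnover"] = res["p_turnover"] < alpha_table
    res["sig_abundance"] = res["p_abundance"] < alpha_table
    return res.sort_values("protein_id", kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class AgingTrend:
    """Endpoint trend of incorporation across ordered ages."""

    fraction_decreasing: float
    p_value: float
    n_proteins: int
    slopes: pd.DataFrame  # protein_id, slope (incorporation / day)


def aging_trend(series: pd.DataFrame) -> AgingTrend:
    """Trend of per-protein incorporation over age.

    ``series`` is a long frame with columns age_days, protein_id,
    incorporation (one per-protein summary per age).  Proteins not
    measured at every age are dropped with a log note.  The headline
    fraction compares the oldest age against the youngest per protein;
    its p-value is a two-sided sign (binomial) test against 0.5.
    Per-protein least-squares slopes over age are reported alongside.
    """
    required = {"age_days", "protein_id", "incorporation"}
    if not required <= set(series.columns):
        raise ValueError(f"series needs columns {sorted(required)}")
    ages = np.sort(series["age_days"].unique())
    if len(ages) < 2:
        raise ValueError("need at least two ages")
    counts = series.groupby("protein_id")["age_days"].nunique()
    complete = counts.index[counts == len(ages)]
    dropped = len(counts) - len(complete)
    if dropped:
        logger.info("aging_trend: %d proteins not measured at all ages dropped", dropped)
    df = series[series["protein_id"].isin(complete)]
    if df["protein_id"].nunique() == 0:
        raise ValueError("no proteins measured at every age")
    wide = df.pivot_table(index="protein_id", columns="age_days", values="incorporation")
    young, old = wide[ages[0]], wide[ages[-1]]
    decreasing = old < young
    n = len(wide)
    n_dec = int(decreasing.sum())
    p = float(stats.binomtest(n_dec, n, 0.5, alternative="two-sided").pvalue)
    x = ages.astype(float)
    xc = x - x.mean()
    slopes = (wide[ages].to_numpy() @ xc) / (xc @ xc)
    slopes_df = pd.DataFrame({"protein_id": wide.index, "slope_per_day": slopes}).reset_index(
        drop=True
    )
    return AgingTrend(
        fraction_decreasing=n_dec / n,
        p_value=p,
        n_proteins=n,
        slopes=slopes_df,
    )


def dynaplot(
    results: pd.DataFrame,
    figure_path=None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Plot-ready dynaplot table, optionally rendered to a vector figure.

    x is the turnover change in percentage points of incorporation, y
    the log2 abundance ratio; points are colored by mechanism class.
    The returned table is stably ordered by protein_id; the figure (SVG)
    is written deterministically.
    """
    if results.empty:
        raise ValueError("dynaplot: empty results")
    table = results[
        [
            "protein_id",
            "delta_pp",
            "log2_abundance_ratio",
            "mechanism_class",
            "uncoupled",
            "p_turnover",
            "p_abundance",
        ]
    ].copy()
    table = table.rename(
        columns={"delta_pp": "turnover_delta_pp", "log2_abundance_ratio": "log2_abundance_ratio"}
    )
    table["color"] = table["mechanism_class"].map(MECHANISM_PALETTE)
    table = table.sort_values("protein_id", kind="mergesort").reset_index(drop=True)
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        with plt.rc_context({"svg.hashsalt": "silamdyn"}):
            fig, ax = plt.subplots(figsize=(6, 5))
            for label in MECHANISM_PALETTE:
                sub = table[table["mechanism_class"] == label]
                if sub.empty:
                    continue
                ax.scatter(
                    sub["turnover_delta_pp"],
                    sub["log2_abundance_ratio"],
                    s=12,
                    c=MECHANISM_PALETTE[label],
                    label=f"{label} (n={len(sub)})",
                    alpha=0.8,
                    linewidths=0,
                )
            ax.axhline(0, color="0.8", lw=0.8, zorder=0)
            ax.axvline(0, color="0.8", lw=0.8, zorder=0)
            ax.set_xlabel("Turnover change (K6 incorporation, percentage points)")
            ax.set_ylabel("Abundance change (log2 disease/control)")
            ax.set_title(f"Proteome dynamics (alpha = {alpha:g})")
            ax.legend(fontsize=7, frameon=False)
            fig.tight_layout()
            fig.savefig(figure_path, format="svg", metadata={"Date": None})
            plt.close(fig)
    return table
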
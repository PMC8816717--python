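"""Peptide evidence -> per-protein, per-mouse K6 incorporation.

Implements the quantification funnel used throughout the package:

1. per-peptide relative incorporation H/(H+L), keeping only peptide
   pairs supported by at least two scans (the double-count rule that
   suppresses spurious pairs);
2. peptide -> protein aggregation (median by default) per
   (protein, fraction, mouse), then the replicate rule: a protein is
   kept in a fraction only when quantified in at least 2 of 3 mice in
   both cohorts;
3. a nonredundant merge across detergent fractions keeping, per
   protein, the fraction with the greatest cohort difference in
   incorporation;
4. a precursor-pool control that estimates the free heavy-lysine
   fraction from the isotopologue pattern of double-lysine peptides,
   and a one-pool inversion from incorporation back to a degradation
   rate constant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .kinetics import LabelingSchedule, invert_incorporation

logger = logging.getLogger(__name__)

__all__ = [
    "compute_incorporation",
    "aggregate_to_protein",
    "merge_fractions",
    "estimate_precursor_pool",
    "fit_rate_constant",
]

_PEPTIDE_COLUMNS = [
    "protein_id",
    "peptide_sequence",
    "lysine_count",
    "fraction_id",
    "mouse_id",
    "cohort",
    "incorporation",
    "n_observations",
]


def compute_incorporation(
    evidence: pd.DataFrame, min_observations: int = 2
) -> pd.DataFrame:
    """Per-peptide relative incorporation with the double-count filter.

    Incorporation is heavy / (heavy + light) per evidence row.  Rows
    supported by fewer than ``min_observations`` scans are excluded, as
    are multi-lysine peptides with a nonzero mixed (HL) isotopologue —
    those carry partially labeled molecules and are reserved for the
    precursor-pool estimator.  Exclusion counts are logged; an empty
    result is allowed.
    """
    if min_observations < 1:
        raise ValueError("min_observations must be >= 1")
    n_in = len(evidence)
    mixed = evidence["intensity_mixed"] if "intensity_mixed" in evidence else 0.0
    is_pool_only = (evidence["lysine_count"] >= 2) & (mixed > 0)
    under_counted = evidence["n_observations"] < min_observations
    kept = evidence[~is_pool_only & ~under_counted].copy()
    logger.info(
        "compute_incorporation: %d rows in, %d under double-count rule, "
        "%d multi-K mixed reserved for pool estimate, %d quantified",
        n_in,
        int(under_counted.sum()),
        int((is_pool_only & ~under_counted).sum()),
        len(kept),
    )
    denom = kept["intensity_heavy"] + kept["intensity_light"]
    kept["incorporation"] = kept["intensity_heavy"] / denom
    return kept[_PEPTIDE_COLUMNS].reset_index(drop=True)


def aggregate_to_protein(
    peptides: pd.DataFrame,
    statistic: str = "median",
    min_mice_per_cohort: int = 2,
) -> pd.DataFrame:
    """Peptide -> protein incorporation per (protein, fraction, mouse).

    The per-group summary is the median of peptide incorporations
    (``statistic="mean"`` for the arithmetic mean).  Groups are then
    filtered by the replicate rule: a (protein, fraction) pair survives
    only if quantified in at least ``min_mice_per_cohort`` mice of every
    cohort present in the input.  Returns a long frame with columns
    protein_id, fraction_id, mouse_id, cohort, incorporation, n_peptides.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    if peptides.empty:
        return pd.DataFrame(
            columns=["protein_id", "fraction_id", "mouse_id", "cohort", "incorporation", "n_peptides"]
        )
    grouped = (
        peptides.groupby(["protein_id", "fraction_id", "mouse_id", "cohort"], sort=True)[
            "incorporation"
        ]
        .agg([statistic, "size"])
        .reset_index()
        .rename(columns={statistic: "incorporation", "size": "n_peptides"})
    )
    cohorts = sorted(peptides["cohort"].unique())
    support = (
        grouped.groupby(["protein_id", "fraction_id", "cohort"])["mouse_id"]
        .nunique()
        .unstack("cohort", fill_value=0)
    )
    ok = support[cohorts].ge(min_mice_per_cohort).all(axis=1)
    keep_keys = support.index[ok]
    before = grouped[["protein_id", "fraction_id"]].drop_duplicates().shape[0]
    grouped = grouped.set_index(["protein_id", "fraction_id"])
    grouped = grouped.loc[grouped.index.isin(keep_keys)].reset_index()
    logger.info(
        "aggregate_to_protein: %d (protein, fraction) groups in, %d pass the "
        ">=%d-mice-per-cohort rule over cohorts %s",
        before,
        len(keep_keys),
        min_mice_per_cohort,
        cohorts,
    )
    return grouped.sort_values(
        ["protein_id", "fraction_id", "cohort", "mouse_id"], kind="mergesort"
    ).reset_index(drop=True)


def merge_fractions(protein_incorporation: pd.DataFrame) -> pd.DataFrame:
    """Nonredundant merge across detergent fractions.

    For each protein measured in several fractions, keep exactly the
    fraction with the greatest absolute difference between the cohort
    mean incorporations.  Ties are broken by the larger total peptide
    support, then by lexicographically smallest fraction_id.  Proteins
    seen in a single cohort keep their best-supported fraction.
    """
    if protein_incorporation.empty:
        return protein_incorporation.copy()
    df = protein_incorporation
    means = (
        df.groupby(["protein_id", "fraction_id", "cohort"])["incorporation"]
        .mean()
        .unstack("cohort")
    )
    delta = (
        (means["disease"] - means["control"])
        if {"control", "disease"} <= set(means.columns)
        else pd.Series(0.0, index=means.index)
    )
    support = df.groupby(["protein_id", "fraction_id"])["n_peptides"].sum()
    choice = pd.DataFrame(
        {"abs_delta": delta.abs().fillna(0.0), "n_peptides": support}
    ).reset_index()
    choice = choice.sort_values(
        ["protein_id", "abs_delta", "n_peptides", "fraction_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = choice.groupby("protein_id", sort=True).head(1)[["protein_id", "fraction_id"]]
    merged = df.merge(best, on=["protein_id", "fraction_id"], how="inner")
    return merged.sort_values(
        ["protein_id", "cohort", "mouse_id"], kind="mergesort"
    ).reset_index(drop=True)


def estimate_precursor_pool(evidence: pd.DataFrame) -> pd.DataFrame:
    """Estimate the precursor heavy-lysine fraction from 2-K peptides.

    Among molecules synthesized during the pulse, each lysine is heavy
    with the precursor heavy fraction q, so the fully heavy (HH) and
    mixed (HL) isotopologues of a double-lysine peptide occur in the
    binomial ratio q^2 : 2q(1-q).  Per record, q = 2 HH / (2 HH + HL);
    the per-cohort estimate is the median over records.  Returns one row
    per cohort with columns cohort, q_hat, n_peptides_used; cohorts with
    no usable 2-K peptides report q_hat = NaN (explicitly not
    estimable).
    """
    cohorts = sorted(evidence["cohort"].unique())
    multi = evidence[(evidence["lysine_count"] >= 2)].copy()
    multi["_hl"] = multi["intensity_mixed"] if "intensity_mixed" in multi else 0.0
    multi = multi[(multi["intensity_heavy"] + multi["_hl"]) > 0]
    rows = []
    for cohort in cohorts:
        sub = multi[multi["cohort"] == cohort]
        if sub.empty:
            rows.append({"cohort": cohort, "q_hat": np.nan, "n_peptides_used": 0})
            continue
        q = 2.0 * sub["intensity_heavy"] / (2.0 * sub["intensity_heavy"] + sub["_hl"])
        rows.append(
            {"cohort": cohort, "q_hat": float(q.median()), "n_peptides_used": int(len(q))}
        )
    out = pd.DataFrame(rows)
    if len(out) == 2 and out["q_hat"].notna().all():
        logger.info(
            "precursor pool: q_hat control=%.4f disease=%.4f (difference %.4f)",
            out.loc[out["cohort"] == "control", "q_hat"].iloc[0],
            out.loc[out["cohort"] == "disease", "q_hat"].iloc[0],
            float(np.diff(out.sort_values("cohort")["q_hat"])[0]),
        )
    return out


def fit_rate_constant(
    incorporation,
    schedule: LabelingSchedule,
    q_hat: float | None = None,
):
    """Invert incorporation to a degradation rate constant (1/day).

    Uses the one-pool inversion ``k = -ln(1 - I/q) / t`` with ``q`` the
    precursor-pool heavy fraction (defaults to the schedule's plateau).
    Saturated values (I >= q) are flagged non-invertible and returned as
    NaN.  Monotone increasing in incorporation.
    """
    q = schedule.precursor_plateau if q_hat is None else q_hat
    k = invert_incorporation(incorporation, schedule.label_days, q)
    n_sat = int(np.sum(np.isnan(np.atleast_1d(k))))
    if n_sat:
        logger.warning(
            "fit_rate_constant: %d incorporation value(s) at or above the "
            "precursor heavy fraction %.3f are saturated (returned NaN)",
            n_sat,
            q,
        )
    return k
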
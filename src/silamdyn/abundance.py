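"""Label-free abundance integration across detergent fractions.

Per-fraction protein intensities (e.g. the output of an upstream LFQ
tool, or the simulator's abundance table) are consumed as provided.
A (protein, fraction) cell is trusted only when the protein was
quantified in every mouse of that fraction — the "six of six" rule for
two cohorts of three — and the surviving fractions are averaged on a
mouse-by-mouse basis, on the intensity scale by default.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["fraction_completeness_filter", "integrate_abundance"]


def fraction_completeness_filter(
    groups: pd.DataFrame, roster: list[str] | None = None
) -> pd.DataFrame:
    """Keep (protein, fraction) cells quantified in every mouse.

    ``roster`` is the full list of mice that must be present; by default
    it is every mouse seen anywhere in the table.  With two cohorts of
    three this is the six-of-six completeness rule; other roster sizes
    generalize to "all mice" with a log note.  Rows with nonpositive
    abundance do not count as quantified.
    """
    if roster is None:
        roster = sorted(groups["mouse_id"].unique())
    roster = sorted(roster)
    if len(roster) != 6:
        logger.info(
            "fraction_completeness_filter: roster has %d mice (not 6); "
            "requiring quantification in all of them",
            len(roster),
        )
    quant = groups[groups["abundance"] > 0]
    quant = quant[quant["mouse_id"].isin(roster)]
    counts = quant.groupby(["protein_id", "fraction_id"])["mouse_id"].nunique()
    complete = counts.index[counts == len(roster)]
    out = quant.set_index(["protein_id", "fraction_id"])
    out = out.loc[out.index.isin(complete)].reset_index()
    logger.info(
        "fraction_completeness_filter: %d of %d (protein, fraction) cells "
        "complete in all %d mice",
        len(complete),
        groups[["protein_id", "fraction_id"]].drop_duplicates().shape[0],
        len(roster),
    )
    return out.sort_values(
        ["protein_id", "fraction_id", "cohort", "mouse_id"], kind="mergesort"
    ).reset_index(drop=True)


def integrate_abundance(filtered: pd.DataFrame) -> pd.DataFrame:
    """Average complete fractions per mouse into one abundance profile.

    Input must already have passed :func:`fraction_completeness_filter`,
    so every retained fraction supports every mouse.  Per (protein,
    mouse) the profile is the arithmetic mean of that mouse's abundance
    across the retained fractions; ``n_fractions_integrated`` records
    how many fractions contributed.
    """
    if filtered.empty:
        return pd.DataFrame(
            columns=["protein_id", "mouse_id", "cohort", "abundance", "n_fractions_integrated"]
        )
    prof = (
        filtered.groupby(["protein_id", "mouse_id", "cohort"], sort=True)["abundance"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "abundance", "size": "n_fractions_integrated"})
    )
    # Support must be identical for every mouse of a protein by construction.
    spread = prof.groupby("protein_id")["n_fractions_integrated"].nunique()
    if (spread > 1).any():
        raise ValueError(
            "integrate_abundance: input not completeness-filtered "
            f"(uneven fraction support for {list(spread.index[spread > 1])[:5]})"
        )
    return prof.sort_values(
        ["protein_id", "cohort", "mouse_id"], kind="mergesort"
    ).reset_index(drop=True)
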
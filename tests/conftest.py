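import numpy as np
import pandas as pd
import pytest

import silamdyn as sd


@pytest.fixture(scope="session")
def schedule():
    """Study-design pulse: 6 days, precursor plateau 0.9, instant rise."""
    return sd.LabelingSchedule()


@pytest.fixture(scope="session")
def unit_schedule():
    """Idealized pulse with a fully heavy precursor pool."""
    return sd.LabelingSchedule(label_days=6.0, precursor_plateau=1.0)


@pytest.fixture(scope="session")
def archetype_fractions():
    """Equal shares of the six effect regimes plus an unchanged remainder."""
    fr = {label: 1 / 7 for label in sd.MECHANISM_LABELS}
    fr["unchanged"] = 1 - 6 / 7
    return fr


@pytest.fixture(scope="session")
def archetype_truth(archetype_fractions):
    return sd.make_truth(70, seed=1, mechanism_fractions=archetype_fractions)


@pytest.fixture(scope="session")
def noise_free_cohorts(archetype_truth, schedule):
    """Noise-free simulated evidence + abundance for the archetype truth."""
    return sd.simulate_cohorts(
        archetype_truth, schedule, sd.NoiseModel.zero(), seed=2
    )


@pytest.fixture()
def small_evidence():
    """Tiny hand-written evidence table covering the filter edge cases."""
    rows = [
        # protein A, fraction F1: quantified in 2 control + 2 disease mice
        ("A", "PEPTIDEK", 1, 2, "F1", "C1", "control", 75.0, 0.0, 25.0, 2),
        ("A", "PEPTIDEK", 1, 2, "F1", "C2", "control", 70.0, 0.0, 30.0, 3),
        ("A", "PEPTIDEK", 1, 2, "F1", "D1", "disease", 50.0, 0.0, 50.0, 2),
        ("A", "PEPTIDEK", 1, 2, "F1", "D2", "disease", 55.0, 0.0, 45.0, 2),
        # single-scan pair: must be excluded by the double-count rule
        ("A", "ACDEFGHK", 1, 2, "F1", "C1", "control", 50.0, 0.0, 50.0, 1),
        # protein B: only one disease mouse -> fails the replicate rule
        ("B", "WIDEPANK", 1, 3, "F1", "C1", "control", 80.0, 0.0, 20.0, 2),
        ("B", "WIDEPANK", 1, 3, "F1", "C2", "control", 82.0, 0.0, 18.0, 2),
        ("B", "WIDEPANK", 1, 3, "F1", "D1", "disease", 60.0, 0.0, 40.0, 2),
        # double-lysine peptide with a mixed species: pool estimator only
        ("A", "KACDEFGK", 2, 2, "F1", "C1", "control", 25.0, 50.0, 25.0, 2),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "peptide_sequence",
            "lysine_count",
            "charge",
            "fraction_id",
            "mouse_id",
            "cohort",
            "intensity_light",
            "intensity_mixed",
            "intensity_heavy",
            "n_observations",
        ],
    )


@pytest.fixture()
def small_groups():
    """Protein-group table: A complete in F1 (6/6), incomplete in F2 (5/6)."""
    mice = [("control", f"C{i}") for i in (1, 2, 3)] + [
        ("disease", f"D{i}") for i in (1, 2, 3)
    ]
    rows = []
    for i, (cohort, mouse) in enumerate(mice):
        rows.append(("A", "F1", mouse, cohort, 100.0 + i))
        if mouse != "D3":  # one missing mouse invalidates the fraction
            rows.append(("A", "F2", mouse, cohort, 200.0 + i))
        rows.append(("B", "F1", mouse, cohort, 50.0 + i))
    return pd.DataFrame(
        rows, columns=["protein_id", "fraction_id", "mouse_id", "cohort", "abundance"]
    )
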
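"""Forward simulation of a SILAM cohort experiment with known kinetics.

The generator emulates the study design this package analyzes: two
cohorts (control and disease) of three mice each, fed a heavy-lysine
(K6) diet for a fixed window, with tissue split into several detergent
fractions that are measured separately.  Every protein follows the
one-pool first-order model of :mod:`silamdyn.kinetics` with its own
synthesis rate ``s`` and degradation rate constant ``k`` per cohort, so
the expected incorporation and steady-state abundance of each protein
are known exactly and serve as the recovery oracle for the whole
downstream pipeline.

Peptide-level realism covered: one or two lysines per peptide (double-K
peptides carry the mixed HL isotopologue that feeds the precursor-pool
estimator), per-peptide response factors, per-fraction loading factors,
multiplicative log-normal intensity noise, per-observation dropout, a
repeat-scan count per peptide pair, and an unlabeled decoy sample in
which heavy matches are spurious single-scan events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import LabelingSchedule, expected_incorporation, steady_state_abundance

__all__ = [
    "MECHANISM_LABELS",
    "ARCHETYPE_RATIOS",
    "KineticGroundTruth",
    "NoiseModel",
    "assign_mechanism_label",
    "make_truth",
    "scale_incorporation_truth",
    "truth_to_frame",
    "simulate_cohorts",
    "simulate_decoy_unlabeled",
]

MECHANISM_LABELS = (
    "synthesis_up",
    "synthesis_down",
    "degradation_up",
    "degradation_down",
    "repair_up",
    "repair_down",
    "unchanged",
)

#: Canonical (s_disease/s_control, k_disease/k_control) ratio pairs that
#: place a protein unambiguously in each regime of the turnover-vs-
#: abundance plane.  Repair regimes use exact powers of two so that the
#: steady-state abundance s/k is bit-identical between cohorts in the
#: noise-free limit.
ARCHETYPE_RATIOS: Mapping[str, tuple[float, float]] = {
    "synthesis_up": (3.0, 1.5),
    "synthesis_down": (1.0 / 3.0, 1.0 / 1.5),
    "degradation_up": (1.0, 2.0),
    "degradation_down": (1.0, 0.5),
    "repair_up": (2.0, 2.0),
    "repair_down": (0.5, 0.5),
    "unchanged": (1.0, 1.0),
}

# Residues used for synthetic tryptic peptide sequences (no K/R internally
# so the lysine count is controlled exactly).
_SEQ_ALPHABET = np.array(list("ACDEFGHILMNPQSTVWY"))


def assign_mechanism_label(s_ratio: float, k_ratio: float, tolerance: float = 0.05) -> str:
    """Map rate-change ratios to one of the six mechanism regimes.

    The steady-state abundance ratio is ``A = s_ratio / k_ratio``.  Both
    the turnover axis (``k_ratio``) and the abundance axis are compared
    against a symmetric relative dead-band around unity: a ratio r is
    "unchanged" when ``1/(1+tolerance) <= r <= 1+tolerance``.

    Regimes: turnover and abundance both up means net synthesis has
    increased; both down, net synthesis decreased; turnover up with
    abundance down, net degradation increased; turnover down with
    abundance up, net degradation decreased; a turnover change without
    an abundance change is a change in repair flux; an abundance change
    with no turnover change is again a net-synthesis change (synthesis
    moved while the rate constant did not).
    """
    if s_ratio <= 0 or k_ratio <= 0:
        raise ValueError("rate ratios must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    a_ratio = s_ratio / k_ratio
    hi, lo = 1.0 + tolerance, 1.0 / (1.0 + tolerance)
    k_up, k_down = k_ratio > hi, k_ratio < lo
    a_up, a_down = a_ratio > hi, a_ratio < lo
    if not (k_up or k_down):
        if a_up:
            return "synthesis_up"
        if a_down:
            return "synthesis_down"
        return "unchanged"
    if k_up:
        if a_up:
            return "synthesis_up"
        if a_down:
            return "degradation_up"
        return "repair_up"
    # k_down
    if a_down:
        return "synthesis_down"
    if a_up:
        return "degradation_down"
    return "repair_down"


@dataclass(frozen=True)
class KineticGroundTruth:
    """Per-protein kinetic parameters of both cohorts plus the regime label."""

    protein_id: str
    s_control: float
    k_control: float
    s_disease: float
    k_disease: float
    mechanism_label: str

    def __post_init__(self) -> None:
        for name in ("s_control", "k_control", "s_disease", "k_disease"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mechanism_label not in MECHANISM_LABELS:
            raise ValueError(f"unknown mechanism_label {self.mechanism_label!r}")

    @classmethod
    def from_rates(
        cls,
        protein_id: str,
        s_control: float,
        k_control: float,
        s_disease: float,
        k_disease: float,
        tolerance: float = 0.05,
    ) -> "KineticGroundTruth":
        label = assign_mechanism_label(
            s_disease / s_control, k_disease / k_control, tolerance
        )
        return cls(protein_id, s_control, k_control, s_disease, k_disease, label)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for the simulated tables.

    intensity_cv
        Coefficient of variation of the multiplicative log-normal noise
        applied independently to every isotopologue intensity.
    missing_rate
        Per-observation dropout probability (evidence rows and abundance
        cells alike).
    observations_per_peptide
        Probability distribution of the repeat-scan count supporting a
        peptide pair, as a mapping count -> probability.
    decoy_pair_rate
        Probability that a peptide in an unlabeled decoy sample acquires
        a spurious single-scan heavy match.
    """

    intensity_cv: float = 0.10
    missing_rate: float = 0.05
    observations_per_peptide: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.5, 3: 0.3}
    )
    decoy_pair_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")
        for name in ("missing_rate", "decoy_pair_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        probs = dict(self.observations_per_peptide)
        if not probs or any(c < 1 for c in probs) or any(p < 0 for p in probs.values()):
            raise ValueError("observations_per_peptide needs counts >= 1, probs >= 0")
        total = sum(probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("observations_per_peptide probabilities must sum to 1")

    @classmethod
    def zero(cls) -> "NoiseModel":
        """Noise-free limit: exact intensities, no dropout, two scans per pair."""
        return cls(
            intensity_cv=0.0,
            missing_rate=0.0,
            observations_per_peptide={2: 1.0},
            decoy_pair_rate=0.0,
        )

    def _draw_obs_counts(self, rng: np.random.Generator, size: int) -> np.ndarray:
        counts = np.array(sorted(self.observations_per_peptide), dtype=int)
        probs = np.array([self.observations_per_peptide[c] for c in counts], float)
        return rng.choice(counts, size=size, p=probs / probs.sum())

    def _intensity_eps(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.intensity_cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(self.intensity_cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def make_truth(
    n_proteins: int,
    seed: int | np.random.Generator = 0,
    *,
    mechanism_fractions: Mapping[str, float] | None = None,
    half_life_median: float = 15.0,
    half_life_sigma: float = 0.7,
    abundance_median: float = 1e7,
    abundance_sigma: float = 1.2,
    effect_ratios: Mapping[str, tuple[float, float]] = ARCHETYPE_RATIOS,
    dead_band: float = 0.05,
) -> list[KineticGroundTruth]:
    """Draw a ground-truth proteome with log-normal kinetics.

    Control half-lives ln(2)/k are log-normal (median ``half_life_median``
    days, log-sd ``half_life_sigma``), which at a 6-day pulse spans the
    few-percent to ~70% incorporation range typical of brain tissue.
    Control abundances s/k are log-normal; disease rates apply the
    archetype ratio pair of each protein's assigned mechanism regime.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fractions = dict(mechanism_fractions or {"unchanged": 1.0})
    unknown = set(fractions) - set(MECHANISM_LABELS)
    if unknown:
        raise ValueError(f"unknown mechanism labels: {sorted(unknown)}")
    if not np.isclose(sum(fractions.values()), 1.0):
        raise ValueError("mechanism_fractions must sum to 1")

    # Deterministic label counts, order shuffled by the generator.
    labels: list[str] = []
    for lab in MECHANISM_LABELS:
        labels.extend([lab] * int(round(fractions.get(lab, 0.0) * n_proteins)))
    while len(labels) < n_proteins:
        labels.append("unchanged")
    labels = list(np.array(labels[:n_proteins])[rng.permutation(n_proteins)])

    half_lives = rng.lognormal(np.log(half_life_median), half_life_sigma, n_proteins)
    k_control = np.log(2.0) / half_lives
    abundances = rng.lognormal(np.log(abundance_median), abundance_sigma, n_proteins)
    s_control = abundances * k_control

    width = len(str(n_proteins))
    truth = []
    for i in range(n_proteins):
        s_ratio, k_ratio = effect_ratios[labels[i]]
        truth.append(
            KineticGroundTruth.from_rates(
                protein_id=f"P{i:0{width}d}",
                s_control=float(s_control[i]),
                k_control=float(k_control[i]),
                s_disease=float(s_control[i] * s_ratio),
                k_disease=float(k_control[i] * k_ratio),
                tolerance=dead_band,
            )
        )
    return truth


def scale_incorporation_truth(
    truth: Sequence[KineticGroundTruth],
    scale: float,
    schedule: LabelingSchedule,
    dead_band: float = 0.05,
) -> list[KineticGroundTruth]:
    """Return a truth set whose disease incorporation is ``scale`` x control.

    Solves ``1 - e^{-k_d t} = scale (1 - e^{-k_c t})`` for every protein,
    which injects an exactly uniform relative change in incorporation
    (e.g. ``scale = 0.939`` is a global 6.1% turnover slowdown).  The
    synthesis rate is co-scaled so steady-state abundance is untouched.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    t = schedule.label_days
    out = []
    for gt in truth:
        f_c = -np.expm1(-gt.k_control * t)
        f_d = scale * f_c
        if not 0 < f_d < 1:
            raise ValueError(
                f"scaled turnover fraction {f_d:.3g} for {gt.protein_id} not in (0, 1)"
            )
        k_d = -np.log1p(-f_d) / t
        s_d = gt.s_control * k_d / gt.k_control  # keeps s/k fixed
        out.append(
            KineticGroundTruth.from_rates(
                gt.protein_id, gt.s_control, gt.k_control, float(s_d), float(k_d),
                tolerance=dead_band,
            )
        )
    return out


def truth_to_frame(
    truth: Sequence[KineticGroundTruth], schedule: LabelingSchedule | None = None
) -> pd.DataFrame:
    """Tabulate ground truth; with a schedule, adds expected observables."""
    df = pd.DataFrame(
        {
            "protein_id": [t.protein_id for t in truth],
            "s_control": [t.s_control for t in truth],
            "k_control": [t.k_control for t in truth],
            "s_disease": [t.s_disease for t in truth],
            "k_disease": [t.k_disease for t in truth],
            "mechanism_label": [t.mechanism_label for t in truth],
        }
    )
    if schedule is not None:
        df["incorporation_control"] = expected_incorporation(
            df["k_control"].to_numpy(), schedule
        )
        df["incorporation_disease"] = expected_incorporation(
            df["k_disease"].to_numpy(), schedule
        )
        df["abundance_control"] = steady_state_abundance(
            df["s_control"].to_numpy(), df["k_control"].to_numpy()
        )
        df["abundance_disease"] = steady_state_abundance(
            df["s_disease"].to_numpy(), df["k_disease"].to_numpy()
        )
    return df.sort_values("protein_id", kind="mergesort").reset_index(drop=True)


def _peptide_sequences(
    rng: np.random.Generator, n: int, lysine_counts: np.ndarray
) -> list[str]:
    seqs = []
    for i in range(n):
        length = int(rng.integers(7, 15))
        body = "".join(rng.choice(_SEQ_ALPHABET, size=length))
        if lysine_counts[i] == 2:
            pos = int(rng.integers(1, length))
            body = body[:pos] + "K" + body[pos:]
        seqs.append(body + "K")  # tryptic C-terminal lysine
    return seqs


def simulate_cohorts(
    truth: Sequence[KineticGroundTruth],
    schedule: LabelingSchedule,
    noise: NoiseModel,
    n_mice: int = 3,
    n_fractions: int = 3,
    *,
    peptides_per_protein: int = 10,
    double_k_fraction: float = 0.2,
    fraction_effect_sigma: float = 0.3,
    peptide_response_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate evidence and per-fraction abundance tables for two cohorts.

    Each protein gets ``peptides_per_protein`` peptides; the first is
    always single-lysine (so every protein is quantifiable) and the rest
    are double-lysine with probability ``double_k_fraction``.  Peptides
    are assigned to detergent fractions; per-peptide response and
    per-(protein, fraction) loading factors are fixed biology shared by
    all mice, so they cancel from incorporation ratios.  Double-lysine
    peptides carry the binomial LL/HL/HH isotopologue split of the
    precursor pool.  Returns ``(evidence, abundance)`` data frames; both
    are reproducible byte-for-byte for a fixed seed.
    """
    if not truth:
        raise ValueError("truth list must not be empty")
    if n_mice < 2:
        raise ValueError("n_mice must be >= 2 per cohort")
    if peptides_per_protein < 1:
        raise ValueError("need at least one peptide per protein")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    rng = np.random.default_rng(seed)

    n_prot = len(truth)
    n_pep = n_prot * peptides_per_protein
    protein_ids = np.array([t.protein_id for t in truth])
    fraction_ids = np.array([f"F{i + 1}" for i in range(n_fractions)])
    mice = [("control", f"C{i + 1}") for i in range(n_mice)] + [
        ("disease", f"D{i + 1}") for i in range(n_mice)
    ]

    # Per-cohort expected observables.
    k_by_cohort = {
        "control": np.array([t.k_control for t in truth]),
        "disease": np.array([t.k_disease for t in truth]),
    }
    abund_by_cohort = {
        c: steady_state_abundance(
            np.array([getattr(t, f"s_{c}") for t in truth]), k_by_cohort[c]
        )
        for c in ("control", "disease")
    }
    inc_by_cohort = {
        c: expected_incorporation(k_by_cohort[c], schedule) for c in ("control", "disease")
    }
    newfrac_by_cohort = {c: -np.expm1(-k_by_cohort[c] * schedule.label_days) for c in ("control", "disease")}

    # Peptide catalogue (biology fixed across mice).
    pep_protein_idx = np.repeat(np.arange(n_prot), peptides_per_protein)
    lys = np.where(rng.random(n_pep) < double_k_fraction, 2, 1)
    lys[np.arange(n_pep) % peptides_per_protein == 0] = 1  # first peptide of each protein
    sequences = np.array(_peptide_sequences(rng, n_pep, lys))
    charges = rng.choice([2, 3], size=n_pep, p=[0.7, 0.3])
    pep_fraction = rng.integers(0, n_fractions, size=n_pep)
    response = rng.lognormal(0.0, peptide_response_sigma, n_pep)
    loading = rng.lognormal(0.0, fraction_effect_sigma, (n_prot, n_fractions))

    ev_parts = []
    for cohort, mouse in mice:
        inc_prot = inc_by_cohort[cohort]
        new_prot = newfrac_by_cohort[cohort]
        a_prot = abund_by_cohort[cohort]
        total = (
            a_prot[pep_protein_idx]
            * loading[pep_protein_idx, pep_fraction]
            * response
        )
        inc = inc_prot[pep_protein_idx]
        fnew = new_prot[pep_protein_idx]
        # Effective per-lysine heavy probability among new molecules.
        with np.errstate(invalid="ignore", divide="ignore"):
            q_eff = np.where(fnew > 0, inc / fnew, 0.0)
        single = lys == 1
        light = np.where(single, (1.0 - inc) * total, 0.0)
        mixed = np.zeros(n_pep)
        heavy = np.where(single, inc * total, 0.0)
        dbl = ~single
        if dbl.any():
            old = 1.0 - fnew[dbl]
            q2 = q_eff[dbl]
            light[dbl] = (old + fnew[dbl] * (1.0 - q2) ** 2) * total[dbl]
            mixed[dbl] = fnew[dbl] * 2.0 * q2 * (1.0 - q2) * total[dbl]
            heavy[dbl] = fnew[dbl] * q2**2 * total[dbl]
        light = light * noise._intensity_eps(rng, n_pep)
        mixed = np.where(mixed > 0, mixed * noise._intensity_eps(rng, n_pep), 0.0)
        heavy = heavy * noise._intensity_eps(rng, n_pep)
        n_obs = noise._draw_obs_counts(rng, n_pep)
        keep = rng.random(n_pep) >= noise.missing_rate
        ev_parts.append(
            pd.DataFrame(
                {
                    "protein_id": protein_ids[pep_protein_idx[keep]],
                    "peptide_sequence": sequences[keep],
                    "lysine_count": lys[keep],
                    "charge": charges[keep],
                    "fraction_id": fraction_ids[pep_fraction[keep]],
                    "mouse_id": mouse,
                    "cohort": cohort,
                    "intensity_light": light[keep],
                    "intensity_mixed": mixed[keep],
                    "intensity_heavy": heavy[keep],
                    "n_observations": n_obs[keep],
                }
            )
        )
    evidence = pd.concat(ev_parts, ignore_index=True)
    evidence = evidence.sort_values(
        ["protein_id", "peptide_sequence", "fraction_id", "cohort", "mouse_id"],
        kind="mergesort",
    ).reset_index(drop=True)

    ab_parts = []
    for cohort, mouse in mice:
        a_prot = abund_by_cohort[cohort]
        for fi, frac in enumerate(fraction_ids):
            vals = a_prot * loading[:, fi] * noise._intensity_eps(rng, n_prot)
            keep = rng.random(n_prot) >= noise.missing_rate
            ab_parts.append(
                pd.DataFrame(
                    {
                        "protein_id": protein_ids[keep],
                        "fraction_id": frac,
                        "mouse_id": mouse,
                        "cohort": cohort,
                        "abundance": vals[keep],
                    }
                )
            )
    abundance = pd.concat(ab_parts, ignore_index=True)
    abundance = abundance.sort_values(
        ["protein_id", "fraction_id", "cohort", "mouse_id"], kind="mergesort"
    ).reset_index(drop=True)
    return evidence, abundance


def simulate_decoy_unlabeled(
    n_proteins: int,
    noise: NoiseModel,
    seed: int = 0,
    *,
    base_intensity: float = 1e7,
) -> pd.DataFrame:
    """Simulate an unlabeled (fully light) decoy sample, one peptide per protein.

    No true heavy signal exists.  A peptide acquires a spurious heavy
    match as a single-scan event with probability ``decoy_pair_rate``;
    an independent second spurious scan (probability ``decoy_pair_rate``
    again, hence rate squared overall) upgrades it to a double-counted
    pair.  Evidence rows without a spurious match keep a zero heavy
    intensity and are undetectable as pairs downstream.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    rate = noise.decoy_pair_rate
    width = len(str(n_proteins))
    protein_ids = np.array([f"U{i:0{width}d}" for i in range(n_proteins)])
    lys = np.ones(n_proteins, dtype=int)
    sequences = np.array(_peptide_sequences(rng, n_proteins, lys))
    light = base_intensity * rng.lognormal(0.0, 1.0, n_proteins)
    first = rng.random(n_proteins) < rate
    second = (rng.random(n_proteins) < rate) & first
    heavy = np.where(first, 0.02 * light * rng.lognormal(0.0, 0.5, n_proteins), 0.0)
    n_obs = np.where(second, 2, 1)
    df = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "peptide_sequence": sequences,
            "lysine_count": lys,
            "charge": rng.choice([2, 3], size=n_proteins, p=[0.7, 0.3]),
            "fraction_id": "F1",
            "mouse_id": "U1",
            "cohort": "control",
            "intensity_light": light,
            "intensity_mixed": 0.0,
            "intensity_heavy": heavy,
            "n_observations": n_obs,
        }
    )
    return df.sort_values("protein_id", kind="mergesort").reset_index(drop=True)
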
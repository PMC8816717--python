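"""First-order kinetics of dietary heavy-lysine (K6) labeling.

A protein pool at steady state turns over with synthesis rate ``s``
(abundance units per day) and first-order degradation rate constant ``k``
(per day), so its steady-state abundance is ``A = s / k``.  During a K6
feeding pulse of length ``t`` days, the fraction of molecules synthesized
within the pulse is ``1 - exp(-k t)``.  Each lysine of a newly made
molecule is heavy with a probability set by the free-lysine precursor
pool, which rises toward an asymptotic heavy fraction (the plateau) with
an optional equilibration time constant ``tau``.  The expected relative
incorporation of a single-lysine peptide is the product of the precursor
term and the turnover term; for ``tau = 0`` it is the familiar

    I(k) = plateau * (1 - exp(-k * t)).

With a finite precursor rise time the one-pool turnover term is replaced
by the two-compartment convolution

    I(k) = plateau * [1 - (k e^{-t/tau} - (1/tau) e^{-k t}) / (k - 1/tau)]

whose ``k -> 1/tau`` limit is ``plateau * (1 - (1 + k t) e^{-k t})``.

These three functions (forward incorporation, steady-state abundance, and
the one-pool inversion back to ``k``) are shared by the simulator and the
turnover-fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabelingSchedule",
    "expected_incorporation",
    "steady_state_abundance",
    "invert_incorporation",
]


@dataclass(frozen=True)
class LabelingSchedule:
    """Design of the dietary labeling pulse.

    Parameters
    ----------
    label_days
        Duration of K6 feeding in days.  The study design this package
        emulates uses 6 days for disease cohorts and 8 days for the
        oldest aging cohort; any positive value is accepted.
    precursor_plateau
        Asymptotic heavy fraction of the free lysine pool, in (0, 1].
    precursor_rise_time
        Time constant (days) of precursor-pool equilibration; 0 means
        the pool is at its plateau from the first day of feeding.
    """

    label_days: float = 6.0
    precursor_plateau: float = 0.9
    precursor_rise_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.label_days > 0:
            raise ValueError(f"label_days must be positive, got {self.label_days}")
        if not 0 < self.precursor_plateau <= 1:
            raise ValueError(
                f"precursor_plateau must be in (0, 1], got {self.precursor_plateau}"
            )
        if self.precursor_rise_time < 0:
            raise ValueError(
                f"precursor_rise_time must be >= 0, got {self.precursor_rise_time}"
            )


def _validated_rates(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive and finite")
    return arr


def expected_incorporation(k, schedule: LabelingSchedule):
    """Expected heavy fraction H/(H+L) of a single-lysine peptide.

    Parameters
    ----------
    k
        Degradation rate constant(s), 1/day; scalar or array, all > 0.
    schedule
        Labeling pulse design.

    Returns
    -------
    Incorporation fraction(s) in ``[0, precursor_plateau]``, same shape
    as ``k``.
    """
    scalar = np.isscalar(k)
    karr = _validated_rates(k, "k")
    t = schedule.label_days
    q = schedule.precursor_plateau
    tau = schedule.precursor_rise_time
    if tau == 0:
        frac = -np.expm1(-karr * t)
    else:
        b = 1.0 / tau
        # Closed-form two-compartment convolution; the removable
        # singularity at k == 1/tau uses its analytic limit.
        near = np.isclose(karr, b, rtol=1e-9, atol=0.0)
        ksafe = np.where(near, b * 2.0, karr)  # dummy, masked below
        general = 1.0 - (ksafe * np.exp(-b * t) - b * np.exp(-ksafe * t)) / (ksafe - b)
        limit = 1.0 - (1.0 + karr * t) * np.exp(-karr * t)
        frac = np.where(near, limit, general)
    out = q * np.clip(frac, 0.0, 1.0)
    return float(out) if scalar else out


def steady_state_abundance(s, k):
    """Steady-state abundance ``A = s / k`` of a first-order pool."""
    scalar = np.isscalar(s) and np.isscalar(k)
    sarr = _validated_rates(s, "s")
    karr = _validated_rates(k, "k")
    out = sarr / karr
    return float(out) if scalar else out


def invert_incorporation(incorporation, label_days: float, q: float):
    """Invert the one-pool labeling model: incorporation -> rate constant.

    ``k = -ln(1 - I/q) / t`` where ``q`` is the precursor-pool heavy
    fraction (plateau, or its estimate from multi-lysine peptides).
    Incorporation at or above ``q`` is saturated and not invertible;
    those entries come back as NaN.  Zero incorporation maps to k = 0.
    """
    if not label_days > 0:
        raise ValueError("label_days must be positive")
    if not 0 < q <= 1:
        raise ValueError("precursor heavy fraction q must be in (0, 1]")
    scalar = np.isscalar(incorporation)
    inc = np.asarray(incorporation, dtype=float)
    if np.any(inc < 0):
        raise ValueError("incorporation must be nonnegative")
    ratio = inc / q
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(ratio < 1.0, -np.log1p(-np.minimum(ratio, 1.0 - 1e-300)) / label_days, np.nan)
    return float(k) if scalar else k
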
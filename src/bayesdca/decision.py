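"""Treat/no-treat decision trees, treatment thresholds, sensitivity sweeps.

The decision problem is binary at the top (treat vs. do not treat) and
binary at each chance node (the patient has the target disease or does
not).  Four outcome utilities on a 0-100 scale value the leaves:

======================  ==============================================
treated disease         treatment given, disease present
treated no disease      treatment given, disease absent (overtreatment)
untreated disease       treatment withheld, disease present (missed)
untreated no disease    treatment withheld, disease absent (default 100)
======================  ==============================================

With disease probability *p* (percent), each choice's expected value is
the probability-weighted mean of its two leaf utilities.  The two
expected-value lines are linear in *p*, so they cross at one point — the
*treatment threshold*

    p* = 1 / (1 + benefit / harm),

where benefit = U(treated disease) − U(untreated disease) is what
treatment gains the diseased, and harm = U(untreated no disease) −
U(treated no disease) is what it costs the healthy.  Below p* the
no-treat branch has the higher expected value; above it, treating wins;
at p* exactly the choices are equivalent.  High benefit:harm treatments
(cheap, safe) justify acting on low diagnostic confidence; low
benefit:harm ones (invasive, costly) demand near-certainty.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .elicitation import BeliefState
from .errors import DominanceError
from .inference import PosteriorResult, posterior as _posterior

__all__ = [
    "OutcomeUtilities",
    "DecisionResult",
    "SensitivitySweep",
    "expected_values",
    "treatment_threshold",
    "sensitivity_sweep",
    "decide",
    "INDIFFERENCE_TOLERANCE",
]

#: Expected-value difference (0-100 scale) below which the two choices
#: are reported as "indifferent" rather than tie-broken arbitrarily.
INDIFFERENCE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class OutcomeUtilities:
    """Utilities of the four treat x disease outcomes, 0-100 scale.

    Utility here is *relative* utility — a composite of survival and the
    medical and financial cost of the intervention, elicited on a rating
    scale.  ``untreated_no_disease`` defaults to the maximum 100: no
    disease and no intervention spares both risk and expense, and fixing
    the scale's top anchors the other three ratings.
    """

    treated_disease: float
    treated_no_disease: float
    untreated_disease: float
    untreated_no_disease: float = 100.0

    def __post_init__(self):
        for name in (
            "treated_disease",
            "treated_no_disease",
            "untreated_disease",
            "untreated_no_disease",
        ):
            v = float(getattr(self, name))
            if not np.isfinite(v) or not (0.0 <= v <= 100.0):
                raise ValueError(f"utility {name}={v!r} must be in [0, 100]")

    @property
    def benefit(self) -> float:
        """Utility gained by treating the diseased."""
        return self.treated_disease - self.untreated_disease

    @property
    def harm(self) -> float:
        """Utility lost by treating the healthy."""
        return self.untreated_no_disease - self.treated_no_disease

    @property
    def has_threshold(self) -> bool:
        """True iff a treatment threshold exists (benefit > 0 and harm > 0)."""
        return self.benefit > 0 and self.harm > 0

    @classmethod
    def mean(cls, ratings: Sequence["OutcomeUtilities"]) -> "OutcomeUtilities":
        """Composite utilities: cell-wise arithmetic mean over raters."""
        if not ratings:
            raise ValueError("cannot average an empty list of utility ratings")
        return cls(
            treated_disease=float(np.mean([u.treated_disease for u in ratings])),
            treated_no_disease=float(np.mean([u.treated_no_disease for u in ratings])),
            untreated_disease=float(np.mean([u.untreated_disease for u in ratings])),
            untreated_no_disease=float(np.mean([u.untreated_no_disease for u in ratings])),
        )


@dataclass(frozen=True)
class DecisionResult:
    """Expected values of both choices at a given disease probability.

    ``optimal`` is a three-valued verdict: ``"treat"``, ``"no-treat"``
    or ``"indifferent"`` (expected values equal to within
    :data:`INDIFFERENCE_TOLERANCE`).  ``threshold`` is the crossing
    probability in percent, or ``None`` when one choice dominates.
    All values are full precision; display rounding is the caller's
    business.
    """

    p_disease: float
    ev_treat: float
    ev_no_treat: float
    optimal: str
    threshold: float | None
    utilities: OutcomeUtilities

    @property
    def ev_optimal(self) -> float:
        return max(self.ev_treat, self.ev_no_treat)


def expected_values(p_disease: float, utilities: OutcomeUtilities) -> DecisionResult:
    """Evaluate the two-branch decision tree at disease probability ``p_disease`` (%).

    ev_treat    = p·U(treated disease)   + (1−p)·U(treated no disease)
    ev_no_treat = p·U(untreated disease) + (1−p)·U(untreated no disease)
    """
    if not (0.0 <= p_disease <= 100.0):
        raise ValueError(f"disease probability {p_disease!r}% outside [0, 100]")
    p = p_disease / 100.0
    ev_treat = p * utilities.treated_disease + (1 - p) * utilities.treated_no_disease
    ev_no_treat = p * utilities.untreated_disease + (1 - p) * utilities.untreated_no_disease
    if abs(ev_treat - ev_no_treat) < INDIFFERENCE_TOLERANCE:
        optimal = "indifferent"
    elif ev_treat > ev_no_treat:
        optimal = "treat"
    else:
        optimal = "no-treat"
    threshold = treatment_threshold(utilities) if utilities.has_threshold else None
    return DecisionResult(p_disease, ev_treat, ev_no_treat, optimal, threshold, utilities)


def treatment_threshold(utilities: OutcomeUtilities) -> float:
    """Disease probability (%) at which treating and not treating break even.

    Computed as ``100 / (1 + benefit/harm)``; the result is cross-checked
    to make the two expected values equal.  Raises
    :class:`~bayesdca.errors.DominanceError` when benefit or harm is not
    strictly positive (one choice then dominates at every probability and
    no threshold exists).
    """
    b, h = utilities.benefit, utilities.harm
    if b <= 0 or h <= 0:
        if b <= 0 and h > 0:
            detail = "treatment is dominated (no benefit to the diseased): never treat"
        elif h <= 0 and b > 0:
            detail = "treatment is dominant (no harm to the healthy): always treat"
        else:
            detail = "treatment neither benefits the diseased nor harms the healthy"
        raise DominanceError(
            f"no treatment threshold exists: benefit={b:g}, harm={h:g}; {detail}"
        )
    t = 100.0 / (1.0 + b / h)
    # internal consistency: EVs must cross here
    p = t / 100.0
    ev_t = p * utilities.treated_disease + (1 - p) * utilities.treated_no_disease
    ev_n = p * utilities.untreated_disease + (1 - p) * utilities.untreated_no_disease
    assert abs(ev_t - ev_n) < 1e-9, "threshold failed the expected-value crossing check"
    return t


@dataclass(frozen=True)
class SensitivitySweep:
    """One-way sensitivity analysis of the decision over disease probability.

    ``crossing`` is the interpolated probability (%) where the two
    expected-value curves intersect, or ``None`` with ``verdict``
    ``"always treat"`` / ``"never treat"`` when they never cross on the
    grid.
    """

    p_grid: np.ndarray
    ev_treat: np.ndarray
    ev_no_treat: np.ndarray
    crossing: float | None
    verdict: str  # "crossing" | "always treat" | "never treat"

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "p_disease_pct": self.p_grid,
                "ev_treat": self.ev_treat,
                "ev_no_treat": self.ev_no_treat,
            }
        )


def sensitivity_sweep(
    utilities: OutcomeUtilities,
    grid: Sequence[float] | None = None,
    step: float = 1.0,
) -> SensitivitySweep:
    """Sweep disease probability across [0, 100] and locate the decision flip.

    The expected-value difference is linear in *p*, so the crossing is
    located exactly by linear interpolation between the bracketing grid
    points and agrees with :func:`treatment_threshold` to floating
    precision whenever the curves cross strictly inside the grid.
    """
    if grid is None:
        grid = np.arange(0.0, 100.0 + step / 2, step)
    p = np.asarray(grid, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("probability grid must be one-dimensional with >= 2 points")
    if p.min() < 0 or p.max() > 100:
        raise ValueError("probability grid must lie within [0, 100]")

    frac = p / 100.0
    ev_t = frac * utilities.treated_disease + (1 - frac) * utilities.treated_no_disease
    ev_n = frac * utilities.untreated_disease + (1 - frac) * utilities.untreated_no_disease
    diff = ev_t - ev_n

    # the EV difference is linear in p, so it changes sign at most once;
    # touching zero only at a grid endpoint still counts as dominance
    crossing = None
    has_pos, has_neg = bool(np.any(diff > 0)), bool(np.any(diff < 0))
    if has_pos and has_neg:
        verdict = "crossing"
        exact = np.flatnonzero(diff == 0)
        if exact.size:
            crossing = float(p[exact[0]])
        else:
            k = int(np.flatnonzero(np.sign(diff[:-1]) != np.sign(diff[1:]))[0])
            w = diff[k] / (diff[k] - diff[k + 1])
            crossing = float(p[k] + w * (p[k + 1] - p[k]))
    elif has_pos:
        verdict = "always treat"
    elif has_neg:
        verdict = "never treat"
    else:
        verdict = "indifferent"
    return SensitivitySweep(p, ev_t, ev_n, crossing, verdict)


def decide(
    belief: BeliefState | PosteriorResult,
    disease_label: str,
    utilities: OutcomeUtilities,
) -> DecisionResult:
    """Collapse a multi-diagnosis posterior to a binary decision and evaluate it.

    ``p(disease)`` is the posterior percent of ``disease_label``;
    ``p(no disease)`` is everything else combined (the differential is
    exhaustive and mutually exclusive).  A plain
    :class:`~bayesdca.elicitation.BeliefState` is accepted too, in which
    case its renormalized priors stand in for the posterior (no evidence
    yet conditioned on).
    """
    if isinstance(belief, BeliefState):
        result = _posterior(belief, findings_used=())
    else:
        result = belief
    result.differential.index(disease_label)  # raises UnknownLabelError if absent
    return expected_values(result[disease_label], utilities)
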
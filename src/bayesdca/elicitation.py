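"""Expert probability elicitations and their aggregation.

The elicitation model follows standard practice in structured expert
judgment for differential diagnosis: each expert supplies, on a 0-100
percent scale,

* a *prior* probability for every diagnosis in a fixed differential set
  (how likely each diagnosis is given only signalment and history), and
* a *conditional* probability for every (diagnosis, finding) pair — the
  percentage of patients with that diagnosis that would show that
  diagnostic finding.

Estimates are floored at 1%: values below 1 in 100 are considered beyond
the resolution an individual clinician's case experience can support, so
anything smaller is treated as an elicitation error rather than silently
accepted (zeros in particular would irreversibly zero out a posterior).

A panel of experts is pooled cell-by-cell into a single composite belief.
The default pool is the arithmetic mean (the linear opinion pool);
geometric-mean and median pools are available for sensitivity
exploration but are never the default.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PanelMismatchError, UnknownLabelError, ZeroProbabilityError

logger = logging.getLogger(__name__)

#: Elicitation floor, percent.  Estimates below this are validation errors.
PROBABILITY_FLOOR = 1.0

#: How far a prior vector's sum may drift from 100 (percentage points)
#: before validation flags it.  Rounded composite priors drift a little
#: (e.g. a printed composite summing to 100.7), which is accepted as-is;
#: renormalization is explicit, never automatic.
PRIOR_SUM_TOLERANCE = 2.0

AGGREGATION_METHODS = ("mean", "geometric", "median")


def _normalize_label(label: str) -> str:
    return " ".join(label.split()).casefold()


@dataclass(frozen=True)
class DifferentialSet:
    """Ordered, mutually exclusive, exhaustive list of candidate diagnoses.

    Exhaustiveness is the modeller's responsibility (an aggregated
    "other" category is the usual device); mutual exclusivity is assumed
    by the posterior normalization.
    """

    diagnoses: tuple[str, ...]

    def __init__(self, diagnoses: Sequence[str]):
        object.__setattr__(self, "diagnoses", tuple(diagnoses))
        if len(self.diagnoses) < 2:
            raise ValueError(
                f"a differential set needs at least 2 diagnoses, got {len(self.diagnoses)}"
            )
        seen: dict[str, str] = {}
        for label in self.diagnoses:
            key = _normalize_label(label)
            if key in seen:
                raise ValueError(
                    f"duplicate diagnosis label (after whitespace/case "
                    f"normalization): {label!r} vs {seen[key]!r}"
                )
            seen[key] = label

    def __len__(self) -> int:
        return len(self.diagnoses)

    def __iter__(self):
        return iter(self.diagnoses)

    def __contains__(self, label: str) -> bool:
        return _normalize_label(label) in {_normalize_label(d) for d in self.diagnoses}

    def index(self, label: str) -> int:
        key = _normalize_label(label)
        for i, d in enumerate(self.diagnoses):
            if _normalize_label(d) == key:
                return i
        raise UnknownLabelError(
            f"diagnosis {label!r} is not in the differential set {list(self.diagnoses)}"
        )


@dataclass(frozen=True)
class FindingSet:
    """Ordered list of diagnostic findings.

    The declared order is the default evidence-incorporation sequence
    for iterative (trajectory) updates; posterior values themselves are
    order-invariant.
    """

    findings: tuple[str, ...]

    def __init__(self, findings: Sequence[str]):
        object.__setattr__(self, "findings", tuple(findings))
        seen: dict[str, str] = {}
        for label in self.findings:
            key = _normalize_label(label)
            if key in seen:
                raise ValueError(f"duplicate finding label: {label!r}")
            seen[key] = label

    def __len__(self) -> int:
        return len(self.findings)

    def __iter__(self):
        return iter(self.findings)

    def index(self, label: str) -> int:
        key = _normalize_label(label)
        for i, f in enumerate(self.findings):
            if _normalize_label(f) == key:
                return i
        raise UnknownLabelError(
            f"finding {label!r} is not in the finding set {list(self.findings)}"
        )


@dataclass(frozen=True)
class ExpertElicitation:
    """One expert's raw elicitation, exactly as supplied.

    ``priors`` maps diagnosis -> percent; ``conditionals`` maps
    diagnosis -> finding -> percent.  No validation happens here —
    :func:`validate_elicitation` reports problems without raising, so
    that a whole panel can be checked and all problems shown at once.
    """

    expert_id: str
    priors: Mapping[str, float]
    conditionals: Mapping[str, Mapping[str, float]]


@dataclass(frozen=True)
class ValidationFinding:
    """One problem (or advisory) found in an elicitation.

    ``rule`` is a stable machine-readable code:

    - ``"floor"``      value below the 1% elicitation floor
    - ``"range"``      value above 100
    - ``"not-finite"`` NaN or infinite value
    - ``"missing"``    a required cell is absent
    - ``"prior-sum"``  priors do not sum to ~100 (advisory, not an error)
    """

    rule: str
    cell: str
    message: str
    severity: str = "error"  # "error" | "advisory"

    def __str__(self) -> str:
        return f"[{self.severity}:{self.rule}] {self.cell}: {self.message}"


def _check_value(value: float, cell: str, out: list[ValidationFinding]) -> None:
    if not math.isfinite(value):
        out.append(ValidationFinding("not-finite", cell, f"value {value!r} is not finite"))
    elif value < PROBABILITY_FLOOR:
        out.append(
            ValidationFinding(
                "floor",
                cell,
                f"value {value:g} is below the {PROBABILITY_FLOOR:g}% elicitation floor",
            )
        )
    elif value > 100:
        out.append(ValidationFinding("range", cell, f"value {value:g} exceeds 100%"))


def validate_elicitation(
    elicitation: ExpertElicitation,
    differential: DifferentialSet,
    findings: FindingSet,
) -> list[ValidationFinding]:
    """Check one expert's elicitation against a differential and finding set.

    Returns an empty list iff every invariant holds.  Violations are
    reported per cell; validation never raises.  A prior vector whose sum
    is outside 100 +/- :data:`PRIOR_SUM_TOLERANCE` yields an *advisory*
    (severity ``"advisory"``), not an error — rounded composites drift
    slightly and are legitimate.
    """
    out: list[ValidationFinding] = []
    eid = elicitation.expert_id

    for dx in differential:
        if dx not in elicitation.priors:
            out.append(
                ValidationFinding("missing", f"{eid}: prior[{dx}]", "prior estimate missing")
            )
        else:
            _check_value(float(elicitation.priors[dx]), f"{eid}: prior[{dx}]", out)
        row = elicitation.conditionals.get(dx)
        for f in findings:
            cell = f"{eid}: conditional[{dx}, {f}]"
            if row is None or f not in row:
                out.append(ValidationFinding("missing", cell, "conditional estimate missing"))
            else:
                _check_value(float(row[f]), cell, out)

    present = [float(elicitation.priors[dx]) for dx in differential if dx in elicitation.priors]
    if len(present) == len(differential):
        total = sum(present)
        if abs(total - 100.0) > PRIOR_SUM_TOLERANCE:
            out.append(
                ValidationFinding(
                    "prior-sum",
                    f"{eid}: priors",
                    f"priors sum to {total:g}, outside 100 ± {PRIOR_SUM_TOLERANCE:g}; "
                    "consider renormalizing",
                    severity="advisory",
                )
            )
    return out


@dataclass(frozen=True)
class BeliefState:
    """A prior vector plus a conditional matrix, ready for inference.

    Values are percents.  ``priors`` has shape ``(n_diagnoses,)``;
    ``conditionals`` has shape ``(n_diagnoses, n_findings)`` in the order
    of ``differential`` and ``findings``.  All values must be strictly
    positive: a zero would pin a posterior at zero regardless of further
    evidence, so zeros are rejected at construction
    (:class:`~bayesdca.errors.ZeroProbabilityError`).

    ``provenance`` records how the belief arose: ``"single-expert"``,
    ``"composite"`` or ``"chained-posterior"``.
    """

    differential: DifferentialSet
    findings: FindingSet
    priors: np.ndarray
    conditionals: np.ndarray
    provenance: str = "single-expert"
    prior_sum_tolerance: float = field(default=PRIOR_SUM_TOLERANCE, compare=False)

    def __post_init__(self):
        priors = np.asarray(self.priors, dtype=float)
        conditionals = np.asarray(self.conditionals, dtype=float)
        if priors.shape != (len(self.differential),):
            raise ValueError(
                f"priors shape {priors.shape} does not match "
                f"{len(self.differential)} diagnoses"
            )
        if conditionals.shape != (len(self.differential), len(self.findings)):
            raise ValueError(
                f"conditionals shape {conditionals.shape} does not match "
                f"({len(self.differential)}, {len(self.findings)})"
            )
        if not (np.all(np.isfinite(priors)) and np.all(np.isfinite(conditionals))):
            raise ValueError("belief state contains non-finite values")
        if np.any(priors <= 0) or np.any(conditionals <= 0):
            raise ZeroProbabilityError(
                "every prior and conditional probability must be strictly positive: "
                "a probability of 0 forces that diagnosis's posterior to 0 no matter "
                "what other evidence says; use the 1% floor for 'possible but very "
                "unlikely'"
            )
        object.__setattr__(self, "priors", priors)
        object.__setattr__(self, "conditionals", conditionals)

    # -- convenience accessors -------------------------------------------------

    def prior(self, diagnosis: str) -> float:
        return float(self.priors[self.differential.index(diagnosis)])

    def conditional(self, diagnosis: str, finding: str) -> float:
        return float(
            self.conditionals[self.differential.index(diagnosis), self.findings.index(finding)]
        )

    @property
    def needs_renormalization(self) -> bool:
        """True if the prior sum drifts from 100 by more than the tolerance."""
        return abs(float(self.priors.sum()) - 100.0) > self.prior_sum_tolerance

    def renormalized(self) -> "BeliefState":
        """Return a copy whose priors are rescaled to sum to exactly 100."""
        return replace(self, priors=self.priors * (100.0 / self.priors.sum()))

    @classmethod
    def from_tables(
        cls,
        differential: DifferentialSet,
        findings: FindingSet,
        priors: Mapping[str, float],
        conditionals: Mapping[str, Mapping[str, float]],
        provenance: str = "single-expert",
        floor: bool = False,
    ) -> "BeliefState":
        """Build a belief state from label-keyed mappings.

        With ``floor=True``, values below the 1% elicitation floor are
        clamped up to it (with a logged warning) instead of being
        rejected.
        """
        p = np.array([float(priors[dx]) for dx in differential])
        c = np.array([[float(conditionals[dx][f]) for f in findings] for dx in differential])
        if floor:
            n_low = int(np.sum(p < PROBABILITY_FLOOR) + np.sum(c < PROBABILITY_FLOOR))
            if n_low:
                logger.warning(
                    "clamped %d value(s) below the %g%% elicitation floor", n_low,
                    PROBABILITY_FLOOR,
                )
            p = np.maximum(p, PROBABILITY_FLOOR)
            c = np.maximum(c, PROBABILITY_FLOOR)
        return cls(differential, findings, p, c, provenance=provenance)


def belief_from_expert(
    elicitation: ExpertElicitation,
    differential: DifferentialSet,
    findings: FindingSet,
    floor: bool = False,
) -> BeliefState:
    """Turn a single expert's elicitation into a belief state."""
    return BeliefState.from_tables(
        differential,
        findings,
        elicitation.priors,
        elicitation.conditionals,
        provenance="single-expert",
        floor=floor,
    )


def _pool(cells: np.ndarray, method: str) -> np.ndarray:
    """Pool expert cells along axis 0."""
    if method == "mean":
        return cells.mean(axis=0)
    if method == "geometric":
        return np.exp(np.log(cells).mean(axis=0))
    if method == "median":
        return np.median(cells, axis=0)
    raise ValueError(f"unknown aggregation method {method!r}; choose from {AGGREGATION_METHODS}")


def aggregate_experts(
    panel: Sequence[ExpertElicitation],
    differential: DifferentialSet,
    findings: FindingSet,
    method: str = "mean",
    clamp: bool = False,
) -> BeliefState:
    """Pool a panel of expert elicitations into a composite belief.

    Every cell of the result is the pool (arithmetic mean by default) of
    the corresponding expert cells.  All elicitations must cover exactly
    the diagnoses and findings given; a missing cell raises
    :class:`~bayesdca.errors.PanelMismatchError` naming it.

    Parameters
    ----------
    method
        ``"mean"`` (linear opinion pool, the default), ``"geometric"``
        or ``"median"``.  The alternatives exist for sensitivity
        exploration only.
    clamp
        Apply the 1% floor to out-of-range inputs (with a logged
        warning) instead of rejecting them downstream.
    """
    if len(panel) == 0:
        raise ValueError("cannot aggregate an empty expert panel")

    n_dx, n_f = len(differential), len(findings)
    prior_cells = np.empty((len(panel), n_dx))
    cond_cells = np.empty((len(panel), n_dx, n_f))
    for k, e in enumerate(panel):
        for i, dx in enumerate(differential):
            if dx not in e.priors:
                raise PanelMismatchError(
                    f"expert {e.expert_id!r} has no prior for diagnosis {dx!r}"
                )
            prior_cells[k, i] = float(e.priors[dx])
            row = e.conditionals.get(dx)
            for j, f in enumerate(findings):
                if row is None or f not in row:
                    raise PanelMismatchError(
                        f"expert {e.expert_id!r} has no conditional for ({dx!r}, {f!r})"
                    )
                cond_cells[k, i, j] = float(row[f])

    if clamp:
        n_low = int(np.sum(prior_cells < PROBABILITY_FLOOR) + np.sum(cond_cells < PROBABILITY_FLOOR))
        if n_low:
            logger.warning(
                "clamped %d panel value(s) up to the %g%% elicitation floor",
                n_low, PROBABILITY_FLOOR,
            )
        prior_cells = np.maximum(prior_cells, PROBABILITY_FLOOR)
        cond_cells = np.maximum(cond_cells, PROBABILITY_FLOOR)

    return BeliefState(
        differential,
        findings,
        _pool(prior_cells, method),
        _pool(cond_cells, method),
        provenance="composite",
    )


def reconstruct_unrounded(values, denominator: int = 3, tolerance: float = 0.034):
    """Snap printed one-decimal composites back to exact n-expert means.

    A composite that is the arithmetic mean of ``denominator`` integer
    estimates is an exact multiple of ``1/denominator``; printing it to
    one decimal loses at most ~0.033.  Values within ``tolerance`` of
    such a multiple are snapped to it; anything farther (a value that was
    never a clean multiple, e.g. a mean involving a decimal estimate) is
    returned unchanged.  Used to reproduce full-precision product
    columns from a table printed at one decimal.
    """
    x = np.asarray(values, dtype=float)
    snapped = np.round(x * denominator) / denominator
    return np.where(np.abs(x - snapped) <= tolerance, snapped, x)
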
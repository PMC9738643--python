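"""Synthetic expert panels and patient cases with known ground truth.

Only one real elicited case ships with the package, so correctness
beyond that single fixture is established on synthetic data where the
truth is known by construction.  Two generators are provided:

* :func:`simulate_panel` draws a panel of imperfect experts around a
  ground-truth belief.  Per-expert priors come from a Dirichlet
  distribution centred on the true prior vector (concentration
  controls agreement: higher = tighter panel); per-expert conditionals
  are the true conditionals perturbed by multiplicative log-normal
  noise with unit mean on the linear scale, so the arithmetic-mean
  pool is unbiased for the truth.  Both noise models are modelling
  choices of this package, not estimates fitted to any real panel;
  they give positive, percent-scale values with controllable spread,
  which is all the tests require.

* :func:`simulate_case` draws one patient: given the true diagnosis,
  each diagnostic finding "matches" the case picture independently with
  the true conditional probability, and the posterior is scored on the
  realized evidence (conditional ``c`` for a matching finding,
  ``100 − c`` for a non-matching one, floored at 1).

All draws go through an explicit ``numpy`` Generator seeded from the
model; the same seed always reproduces the same panel or case.
Generated values are clamped into the elicitable range [1, 100] and the
number of clamp events is reported, so parameter regimes where clamping
distorts the noise model are visible rather than silent.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .elicitation import (
    PROBABILITY_FLOOR,
    BeliefState,
    ExpertElicitation,
)
from .inference import PosteriorResult, posterior

__all__ = ["PanelModel", "PanelSample", "CaseSample", "simulate_panel", "simulate_case", "simulate_cases"]


@dataclass(frozen=True)
class PanelModel:
    """Generative model for a synthetic expert panel.

    Parameters
    ----------
    true_belief
        Ground-truth priors and conditionals the experts perturb.
    n_experts
        Panel size (>= 1).
    prior_concentration
        Dirichlet concentration mass spread over the true prior
        proportions; 200 (default) gives clinician-plausible spread
        (roughly +/- a few points on mid-sized priors), higher values a
        tighter panel.
    conditional_noise_sd
        Standard deviation of the log-scale multiplicative noise on
        conditionals; 0.3 (default) spans roughly x/÷ 1.35 per expert,
        comparable to the disagreement seen between real elicitors.
    seed
        Mandatory seed; output is a pure function of the model.
    no_noise
        Exact no-noise limit: every expert reproduces the truth.
    """

    true_belief: BeliefState
    n_experts: int
    prior_concentration: float = 200.0
    conditional_noise_sd: float = 0.3
    seed: int = 0
    no_noise: bool = False

    def __post_init__(self):
        if self.n_experts < 1:
            raise ValueError(f"n_experts must be >= 1, got {self.n_experts}")
        if self.prior_concentration <= 0:
            raise ValueError("prior_concentration must be > 0")
        if self.conditional_noise_sd < 0:
            raise ValueError("conditional_noise_sd must be >= 0")


@dataclass(frozen=True)
class PanelSample:
    """A simulated panel plus bookkeeping about range clamping."""

    elicitations: tuple[ExpertElicitation, ...]
    n_clamped: int
    model: PanelModel = field(repr=False)

    def __iter__(self):
        return iter(self.elicitations)

    def __len__(self) -> int:
        return len(self.elicitations)


def _clamp(values: np.ndarray) -> tuple[np.ndarray, int]:
    clamped = np.clip(values, PROBABILITY_FLOOR, 100.0)
    return clamped, int(np.sum(clamped != values))


def simulate_panel(model: PanelModel) -> PanelSample:
    """Draw a reproducible panel of noisy experts around the true belief."""
    truth = model.true_belief
    dx = list(truth.differential)
    findings = list(truth.findings)
    rng = np.random.default_rng(model.seed)

    elicitations = []
    n_clamped = 0
    alpha = model.prior_concentration * truth.priors / truth.priors.sum()
    for k in range(model.n_experts):
        if model.no_noise:
            priors = truth.priors.copy()
            conds = truth.conditionals.copy()
        else:
            priors = 100.0 * rng.dirichlet(alpha)
            # unit-mean log-normal multiplier (mean-centred on the linear
            # scale, since the panel is pooled by arithmetic mean)
            sd = model.conditional_noise_sd
            noise = rng.normal(-0.5 * sd**2, sd, size=truth.conditionals.shape)
            conds = truth.conditionals * np.exp(noise)
        priors, c1 = _clamp(priors)
        conds, c2 = _clamp(conds)
        n_clamped += c1 + c2
        elicitations.append(
            ExpertElicitation(
                expert_id=f"sim-expert-{k + 1}",
                priors={d: float(priors[i]) for i, d in enumerate(dx)},
                conditionals={
                    d: {f: float(conds[i, j]) for j, f in enumerate(findings)}
                    for i, d in enumerate(dx)
                },
            )
        )
    return PanelSample(tuple(elicitations), n_clamped, model)


@dataclass(frozen=True)
class CaseSample:
    """One simulated patient workup and its posterior scoring."""

    true_diagnosis: str
    matched: tuple[bool, ...]  # per finding, in finding-set order
    result: PosteriorResult
    true_rank: int  # 1 = ranked most probable

    @property
    def correct_top(self) -> bool:
        return self.true_rank == 1


def _case_from_matches(
    belief: BeliefState, true_diagnosis: str, matched: np.ndarray
) -> CaseSample:
    # likelihood of the realized evidence: c if the finding matched,
    # 100 - c otherwise, floored at the elicitation floor
    effective = np.where(matched, belief.conditionals, 100.0 - belief.conditionals)
    effective = np.maximum(effective, PROBABILITY_FLOOR)
    scored = BeliefState(
        belief.differential,
        belief.findings,
        belief.priors,
        effective,
        provenance=belief.provenance,
    )
    result = posterior(scored)
    ranking = result.ranking()
    rank = ranking.index(
        belief.differential.diagnoses[belief.differential.index(true_diagnosis)]
    ) + 1
    return CaseSample(true_diagnosis, tuple(bool(m) for m in matched), result, rank)


def simulate_case(
    true_diagnosis: str,
    belief: BeliefState,
    seed: int | np.random.Generator,
) -> CaseSample:
    """Simulate one patient with a known true diagnosis.

    Each finding in the belief's finding set independently "matches" the
    case picture with the true diagnosis's conditional probability for
    that finding.  The returned sample records the realized match
    pattern, the posterior over the differential given that evidence,
    and where the true diagnosis landed in the posterior ranking.
    """
    i = belief.differential.index(true_diagnosis)  # raises UnknownLabelError
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_match = belief.conditionals[i] / 100.0
    matched = rng.random(len(belief.findings)) < p_match
    return _case_from_matches(belief, belief.differential.diagnoses[i], matched)


def simulate_cases(
    belief: BeliefState,
    n_cases: int,
    seed: int,
    true_diagnoses: Sequence[str] | None = None,
) -> list[CaseSample]:
    """Simulate a cohort of patients.

    True diagnoses are drawn from the belief's renormalized priors
    unless given explicitly, so the cohort's diagnosis mix reflects the
    assumed prevalences.  A single seed drives the whole cohort.
    """
    rng = np.random.default_rng(seed)
    dx = belief.differential.diagnoses
    if true_diagnoses is None:
        probs = belief.priors / belief.priors.sum()
        draws = rng.choice(len(dx), size=n_cases, p=probs)
        true_diagnoses = [dx[i] for i in draws]
    elif len(true_diagnoses) != n_cases:
        raise ValueError("true_diagnoses length must equal n_cases")
    else:
        for d in true_diagnoses:
            belief.differential.index(d)
    return [simulate_case(d, belief, rng) for d in true_diagnoses]
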
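"""Posterior probabilities over a differential-diagnosis set.

The update is the product form of Bayes' theorem under conditional
independence of findings given the diagnosis (the naive-Bayes
assumption): for diagnosis *i* and observed findings *F*,

    score_i     = prior_i * prod_{f in F} conditional_{i,f}
    posterior_i = 100 * score_i / sum_j score_j

with everything on the percent scale.  Only ratios of scores matter, so
the percent scale is purely cosmetic; scaling any single finding's
conditional column by a constant leaves the posterior unchanged.

Products are accumulated in log space.  On the percent scale a raw
product over five findings already reaches ~1e9 and longer chains grow
geometrically, so the sum-of-logs form is used internally and the raw
product (wanted for table display) is exponentiated on demand.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elicitation import BeliefState, DifferentialSet, FindingSet
from .errors import PanelMismatchError

__all__ = ["PosteriorResult", "Trajectory", "posterior", "trajectory", "chain"]


@dataclass(frozen=True)
class PosteriorResult:
    """Normalized posterior over a differential set.

    Stores the unnormalized evidence in log space (``log_score``);
    ``posterior`` and ``score`` are derived views.  ``findings_used``
    records exactly which findings were conditioned on, and
    ``provenance`` carries the belief's provenance for audit trails.
    """

    differential: DifferentialSet
    findings_used: tuple[str, ...]
    log_score: np.ndarray
    provenance: str = "single-expert"

    @property
    def posterior(self) -> np.ndarray:
        """Posterior percents, summing to 100 (softmax of the log scores)."""
        shifted = np.exp(self.log_score - self.log_score.max())
        return 100.0 * shifted / shifted.sum()

    @property
    def score(self) -> np.ndarray:
        """Raw prior-times-conditionals product on the percent scale.

        This is the "product" column of a worked posterior table; it can
        overflow float range for very long finding chains, in which case
        the normalized ``posterior`` remains exact but ``score`` returns
        inf.
        """
        with np.errstate(over="ignore"):
            return np.exp(self.log_score)

    def __getitem__(self, diagnosis: str) -> float:
        return float(self.posterior[self.differential.index(diagnosis)])

    def ranking(self) -> list[str]:
        """Diagnosis labels from most to least probable (stable for ties)."""
        order = np.argsort(-self.posterior, kind="stable")
        return [self.differential.diagnoses[i] for i in order]

    def top(self) -> str:
        return self.ranking()[0]

    def as_series(self) -> pd.Series:
        return pd.Series(self.posterior, index=list(self.differential), name="posterior_pct")


@dataclass(frozen=True)
class Trajectory:
    """Posteriors after each cumulative prefix of an evidence sequence.

    ``entries[0]`` is the renormalized prior (no evidence);
    ``entries[k]`` conditions on the first *k* findings; the final entry
    equals the posterior over the full sequence.
    """

    entries: tuple[PosteriorResult, ...]
    sequence: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, k: int) -> PosteriorResult:
        return self.entries[k]

    @property
    def final(self) -> PosteriorResult:
        return self.entries[-1]

    def as_frame(self) -> pd.DataFrame:
        """Rows = evidence steps ("prior", then each finding), columns = diagnoses."""
        index = ["prior"] + [f"+ {f}" for f in self.sequence]
        data = [e.posterior for e in self.entries]
        return pd.DataFrame(data, index=index, columns=list(self.entries[0].differential))


def _finding_indices(belief: BeliefState, findings_used) -> list[int]:
    if findings_used is None:
        return list(range(len(belief.findings)))
    return [belief.findings.index(f) for f in findings_used]


def posterior(belief: BeliefState, findings_used: Sequence[str] | None = None) -> PosteriorResult:
    """Compute the normalized posterior for a belief state.

    Parameters
    ----------
    belief
        Priors plus conditional matrix (percent scale, all positive —
        enforced by :class:`~bayesdca.elicitation.BeliefState` itself).
    findings_used
        Which findings to condition on.  ``None`` (default) uses every
        finding in the belief's finding set; an empty sequence yields the
        renormalized priors.  Labels not in the belief's finding set
        raise :class:`~bayesdca.errors.UnknownLabelError`.
    """
    idx = _finding_indices(belief, findings_used)
    log_score = np.log(belief.priors) + np.log(belief.conditionals[:, idx]).sum(axis=1)
    used = tuple(belief.findings.findings[i] for i in idx)
    return PosteriorResult(belief.differential, used, log_score, provenance=belief.provenance)


def trajectory(belief: BeliefState, sequence: Sequence[str] | None = None) -> Trajectory:
    """Iteratively update the posterior as findings accumulate one at a time.

    ``sequence`` defaults to the belief's declared finding order (the
    diagnostic workup order).  Entry *k* of the result conditions on the
    first *k* findings, so the trajectory shows how each new piece of
    evidence moves the differential; the final entry is identical to
    ``posterior(belief, sequence)``.
    """
    if sequence is None:
        sequence = tuple(belief.findings)
    seq = tuple(sequence)
    entries = [posterior(belief, seq[:k]) for k in range(len(seq) + 1)]
    return Trajectory(tuple(entries), seq)


def chain(
    first: PosteriorResult,
    conditionals: Mapping[str, Mapping[str, float]] | np.ndarray,
    findings: FindingSet | Sequence[str] | None = None,
    findings_used: Sequence[str] | None = None,
) -> PosteriorResult:
    """Use a posterior as the prior for a later evidence stage.

    When the reference time point moves (say, from pre-surgical workup
    to post-surgical course), the first stage's posterior becomes the
    second stage's prior.  The *unrounded* posterior percents are carried
    forward — rounding before chaining visibly distorts small
    probabilities.  Chaining is associative: chaining stage-2 findings
    onto a stage-1 posterior equals a single update over the union of
    findings from the original belief.

    Parameters
    ----------
    first
        Stage-1 posterior; its diagnoses define the differential.
    conditionals
        Stage-2 conditional probabilities, either a nested mapping
        ``{diagnosis: {finding: pct}}`` or an array of shape
        ``(n_diagnoses, n_findings)`` in differential/finding order.
    findings
        Stage-2 finding labels.  Required when ``conditionals`` is an
        array; inferred (and checked for consistency) from the mapping
        otherwise.
    findings_used
        Optional subset of stage-2 findings to condition on.
    """
    differential = first.differential
    if isinstance(conditionals, Mapping):
        for dx in differential:
            if dx not in conditionals:
                raise PanelMismatchError(
                    f"stage-2 conditionals are missing diagnosis {dx!r}"
                )
        if findings is None:
            first_row = conditionals[next(iter(differential))]
            findings = FindingSet(tuple(first_row))
        elif not isinstance(findings, FindingSet):
            findings = FindingSet(tuple(findings))
        matrix = np.array(
            [[float(conditionals[dx][f]) for f in findings] for dx in differential]
        )
    else:
        if findings is None:
            raise ValueError("findings labels are required with an array of conditionals")
        if not isinstance(findings, FindingSet):
            findings = FindingSet(tuple(findings))
        matrix = np.asarray(conditionals, dtype=float)

    stage2 = BeliefState(
        differential,
        findings,
        first.posterior,  # unrounded carry-forward
        matrix,
        provenance="chained-posterior",
    )
    result = posterior(stage2, findings_used)
    return PosteriorResult(
        differential,
        first.findings_used + result.findings_used,
        result.log_score,
        provenance="chained-posterior",
    )
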
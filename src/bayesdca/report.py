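"""Human- and machine-readable renderings of an analysis.

The report mirrors the worked-table style of a published decision
analysis: a posterior table per evidence stage (prior, per-finding
conditionals, raw product, posterior), an ASCII decision tree with the
expected value at each choice node, the treatment-threshold statement,
and optional trajectory / sensitivity-sweep plots.  Everything the text
report states is also available as DataFrames (``tables``) and a JSON
document, so reports are auditable and diffable.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .caseio import CaseBundle, Stage
from .decision import DecisionResult, expected_values, sensitivity_sweep
from .elicitation import BeliefState
from .inference import PosteriorResult, Trajectory, posterior

logger = logging.getLogger(__name__)

__all__ = [
    "Report",
    "posterior_table",
    "decision_tree_text",
    "render_report",
    "plot_trajectory",
    "plot_sweep",
]


def _fmt_pct(x: float) -> str:
    """Display convention for posterior percents: whole percents, except
    sub-0.5% values which keep enough decimals not to print as 0."""
    if x >= 0.5:
        return f"{x:.0f}"
    if x >= 0.05:
        return f"{x:.1f}"
    return f"{x:.2f}"


def posterior_table(belief: BeliefState, result: PosteriorResult) -> pd.DataFrame:
    """Worked posterior table: prior, conditionals used, product, posterior.

    Reproduces the layout of a printed Bayesian-workup table.  The
    product column is the raw percent-scale prior x conditionals score
    (recovered from the log-space representation).
    """
    used = [f for f in belief.findings if f in result.findings_used]
    data = {"prior_pct": belief.priors}
    for f in used:
        data[f"P({f} | dx) %"] = belief.conditionals[:, belief.findings.index(f)]
    data["product"] = result.score
    data["posterior_pct"] = result.posterior
    frame = pd.DataFrame(data, index=list(belief.differential))
    frame.index.name = "diagnosis"
    return frame


def _table_text(frame: pd.DataFrame) -> str:
    shown = frame.copy()
    shown["product"] = [f"{v:,.0f}" for v in shown["product"]]
    shown["posterior_pct"] = [_fmt_pct(v) for v in shown["posterior_pct"]]
    return shown.to_string(float_format=lambda v: f"{v:g}")


def decision_tree_text(
    decision: DecisionResult,
    disease: str,
    treat_label: str = "treat",
    no_treat_label: str = "no treat",
) -> str:
    """ASCII two-choice decision tree with expected values at the chance nodes."""
    u = decision.utilities
    p = decision.p_disease
    lines = [
        f"decision: {treat_label} vs {no_treat_label}   (P[{disease}] = {p:.1f}%)",
        "",
        f"[{treat_label}] EV = {decision.ev_treat:.1f}"
        + ("   <-- optimal" if decision.optimal == "treat" else ""),
        f" |-- {disease} ({p:.1f}%)".ljust(46) + f"utility {u.treated_disease:g}",
        f" `-- no {disease} ({100 - p:.1f}%)".ljust(46) + f"utility {u.treated_no_disease:g}",
        "",
        f"[{no_treat_label}] EV = {decision.ev_no_treat:.1f}"
        + ("   <-- optimal" if decision.optimal == "no-treat" else ""),
        f" |-- {disease} ({p:.1f}%)".ljust(46) + f"utility {u.untreated_disease:g}",
        f" `-- no {disease} ({100 - p:.1f}%)".ljust(46) + f"utility {u.untreated_no_disease:g}",
    ]
    if decision.optimal == "indifferent":
        lines.append("")
        lines.append("the two choices have equal expected value (indifferent)")
    return "\n".join(lines)


@dataclass
class Report:
    """A rendered analysis: text, tables, and a JSON-serializable summary."""

    case_name: str
    text: str
    tables: dict[str, pd.DataFrame]
    summary: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary, **kwargs)

    def save(self, directory: str | Path, stem: str = "report") -> list[Path]:
        """Write the text report, each table as CSV, and the JSON summary."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = [directory / f"{stem}.txt", directory / f"{stem}.json"]
        written[0].write_text(self.text)
        written[1].write_text(self.to_json(indent=2))
        for name, frame in self.tables.items():
            p = directory / f"{stem}_{name}.csv"
            frame.to_csv(p)
            written.append(p)
        return written


def render_report(
    bundle: CaseBundle,
    findings_used: Sequence[str] | None = None,
    stages: Sequence[int | str] | None = None,
) -> Report:
    """Run the full analysis for a case and render it.

    By default every stage is used in order, chaining posteriors across
    stages, and the decision is evaluated at the *first* stage's
    posterior (the decision point of the workup).  ``findings_used``
    restricts the first stage to a subset of its findings — the device
    for counterfactual what-did-the-clinician-actually-condition-on
    analyses; later stages are then dropped.
    """
    stage_list: list[Stage] = (
        [bundle.stage(s) for s in stages] if stages is not None else list(bundle.stages)
    )
    belief = bundle.belief(stage_list[0].name)
    logger.info(
        "rendering report for %r: provenance=%s, stages=%s, findings_used=%s",
        bundle.name, bundle.priors_provenance,
        [s.name for s in stage_list], findings_used,
    )

    parts: list[str] = [f"case: {bundle.name}"]
    if bundle.description:
        parts.append(bundle.description.strip())
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"case": bundle.name, "stages": []}

    first = posterior(belief, findings_used)
    tables[f"stage1_{stage_list[0].name}"] = posterior_table(belief, first)
    used = list(first.findings_used)
    parts += [
        "",
        f"stage '{stage_list[0].name}' "
        + (f"(findings: {', '.join(used)})" if used else "(no findings: priors only)"),
        _table_text(tables[f"stage1_{stage_list[0].name}"]),
    ]
    summary["stages"].append(
        {
            "name": stage_list[0].name,
            "findings_used": used,
            "posterior_pct": {dx: first[dx] for dx in bundle.differential},
        }
    )

    previous = first
    if findings_used is None:
        for k, s in enumerate(stage_list[1:], start=2):
            # the previous stage's unrounded posterior becomes this stage's prior
            chained_belief = BeliefState(
                bundle.differential,
                s.findings,
                previous.posterior,
                s.conditionals,
                provenance="chained-posterior",
            )
            stage_result = posterior(chained_belief)
            tables[f"stage{k}_{s.name}"] = posterior_table(chained_belief, stage_result)
            parts += [
                "",
                f"stage '{s.name}' (priors = previous stage's unrounded posteriors)",
                _table_text(tables[f"stage{k}_{s.name}"]),
            ]
            summary["stages"].append(
                {
                    "name": s.name,
                    "findings_used": list(s.findings),
                    "posterior_pct": {dx: stage_result[dx] for dx in bundle.differential},
                }
            )
            previous = stage_result

    if bundle.utilities is not None and bundle.disease is not None:
        decision = expected_values(first[bundle.disease], bundle.utilities)
        sweep = sensitivity_sweep(bundle.utilities, step=1.0)
        tree = decision_tree_text(
            decision, bundle.disease, bundle.treat_label, bundle.no_treat_label
        )
        verdict = {
            "treat": bundle.treat_label,
            "no-treat": bundle.no_treat_label,
            "indifferent": "indifferent",
        }[decision.optimal]
        parts += ["", tree, ""]
        if decision.threshold is not None:
            relation = ">" if decision.p_disease > decision.threshold else (
                "<" if decision.p_disease < decision.threshold else "="
            )
            parts.append(
                f"treatment threshold: {decision.threshold:.0f}% — "
                f"P[{bundle.disease}] = {decision.p_disease:.0f}% {relation} threshold "
                f"=> verdict: {verdict}"
            )
        else:
            parts.append(f"no treatment threshold ({sweep.verdict}); verdict: {verdict}")
        tables["sensitivity_sweep"] = sweep.as_frame()
        summary["decision"] = {
            "disease": bundle.disease,
            "p_disease_pct": decision.p_disease,
            "ev_treat": decision.ev_treat,
            "ev_no_treat": decision.ev_no_treat,
            "optimal": decision.optimal,
            "verdict": verdict,
            "threshold_pct": decision.threshold,
        }

    return Report(bundle.name, "\n".join(parts), tables, summary)


def plot_trajectory(traj: Trajectory, path: str | Path | None = None, ax=None):
    """Line plot of each diagnosis's posterior as evidence accumulates."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = traj.as_frame()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    for dx in frame.columns:
        ax.plot(range(len(frame)), frame[dx], marker="o", label=dx)
    ax.set_xticks(range(len(frame)))
    ax.set_xticklabels(frame.index, rotation=30, ha="right")
    ax.set_ylabel("posterior probability (%)")
    ax.set_xlabel("evidence incorporated")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
    return ax


def plot_sweep(sweep, path: str | Path | None = None, ax=None):
    """Expected value of each choice across disease probability, with the crossing."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    ax.plot(sweep.p_grid, sweep.ev_treat, label="treat")
    ax.plot(sweep.p_grid, sweep.ev_no_treat, label="no treat")
    if sweep.crossing is not None:
        ax.axvline(sweep.crossing, color="grey", linestyle="--",
                   label=f"threshold {sweep.crossing:.1f}%")
    ax.set_xlabel("disease probability (%)")
    ax.set_ylabel("expected value (utility)")
    ax.legend()
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
    return ax
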
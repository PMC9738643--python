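"""Reading and writing case bundles and elicitation tables.

Two file surfaces, both plain text and spreadsheet-friendly:

* **Case file** (YAML): the whole decision problem in one document —
  differential set, one or more evidence stages with their conditional
  tables, composite or per-expert probabilities, outcome utilities, and
  optional printed reference values for provenance.  This is the
  fill-in-the-blank template form of the analysis.
* **Elicitation CSV**: one expert's numbers as a single table with
  header ``diagnosis,prior,<finding1>,<finding2>,...``; a panel is a
  directory of such files or a long-format CSV
  ``expert,diagnosis,field,value`` (``field`` is ``prior`` or a finding
  label).

Loading validates everything it can and fails with cell-level messages:
:class:`~bayesdca.errors.CaseFileError` for unparseable files,
:class:`~bayesdca.errors.CaseSchemaError` for structural problems
(naming the missing (diagnosis, finding) pair), and
:class:`~bayesdca.errors.CaseValidationError` for values outside the
elicitable range.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decision import OutcomeUtilities
from .elicitation import (
    BeliefState,
    DifferentialSet,
    ExpertElicitation,
    FindingSet,
    aggregate_experts,
    validate_elicitation,
)
from .errors import CaseFileError, CaseSchemaError, CaseValidationError, UnknownLabelError

logger = logging.getLogger(__name__)

#: Percent values are serialized at one decimal place by default — the
#: finest precision elicited tables are printed at.
DEFAULT_DECIMALS = 1


@dataclass(frozen=True)
class Stage:
    """One evidence stage: a finding set and its conditional table."""

    name: str
    findings: FindingSet
    conditionals: np.ndarray  # (n_diagnoses, n_findings), percent

    def conditional_mapping(self, differential: DifferentialSet) -> dict[str, dict[str, float]]:
        return {
            dx: {f: float(self.conditionals[i, j]) for j, f in enumerate(self.findings)}
            for i, dx in enumerate(differential)
        }


@dataclass(frozen=True)
class CaseBundle:
    """A complete, validated decision-analysis case.

    ``priors`` are composite percent priors over ``differential``;
    ``stages`` hold per-stage conditional tables in workup order;
    ``utilities`` are the composite outcome utilities (with the
    per-rater breakdown in ``utilities_experts`` when available);
    ``reference`` optionally carries published values at printed
    precision for provenance and integrity checks.
    """

    name: str
    differential: DifferentialSet
    priors: np.ndarray
    stages: tuple[Stage, ...]
    utilities: OutcomeUtilities | None = None
    utilities_experts: tuple[OutcomeUtilities, ...] = ()
    panel: tuple[ExpertElicitation, ...] = ()
    disease: str | None = None
    treat_label: str = "treat"
    no_treat_label: str = "no treat"
    priors_provenance: str = "composite"
    description: str = ""
    metadata: dict = field(default_factory=dict)
    reference: dict = field(default_factory=dict)

    def stage(self, key: int | str = 0) -> Stage:
        if isinstance(key, int):
            return self.stages[key]
        for s in self.stages:
            if s.name == key:
                return s
        raise UnknownLabelError(
            f"no stage named {key!r}; stages are {[s.name for s in self.stages]}"
        )

    def belief(self, stage: int | str = 0) -> BeliefState:
        """Belief state for one stage: the case priors plus that stage's conditionals."""
        s = self.stage(stage)
        logger.info(
            "building %s belief for stage %r (findings: %s)",
            self.priors_provenance, s.name, ", ".join(s.findings),
        )
        return BeliefState(
            self.differential,
            s.findings,
            self.priors,
            s.conditionals,
            provenance=self.priors_provenance,
        )


# --------------------------------------------------------------------------
# case files


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise CaseSchemaError(f"case file is missing {key!r} in {where}")
    return mapping[key]


def _utilities_from(block: Mapping, where: str) -> OutcomeUtilities:
    kwargs = {}
    for name in ("treated_disease", "treated_no_disease", "untreated_disease"):
        kwargs[name] = float(_require(block, name, where))
    if "untreated_no_disease" in block:
        kwargs["untreated_no_disease"] = float(block["untreated_no_disease"])
    try:
        return OutcomeUtilities(**kwargs)
    except ValueError as exc:
        raise CaseValidationError(f"{where}: {exc}") from exc


def _conditionals_matrix(
    block: Mapping, differential: DifferentialSet, findings: FindingSet, where: str
) -> np.ndarray:
    matrix = np.empty((len(differential), len(findings)))
    for i, dx in enumerate(differential):
        if dx not in block:
            raise CaseSchemaError(f"{where}: no conditional row for diagnosis {dx!r}")
        row = block[dx]
        for j, f in enumerate(findings):
            if not isinstance(row, Mapping) or f not in row:
                raise CaseSchemaError(
                    f"{where}: missing conditional cell ({dx!r}, {f!r})"
                )
            matrix[i, j] = float(row[f])
    return matrix


def load_case(path: str | Path, clamp: bool = False) -> CaseBundle:
    """Load and fully validate a YAML case file.

    With ``clamp=True``, panel values below the 1% floor are clamped up
    to it (logged) instead of failing validation.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise CaseFileError(f"cannot read case file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise CaseFileError(f"cannot parse case file {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise CaseSchemaError(f"case file {path} must be a mapping at top level")
    return case_from_dict(doc, clamp=clamp)


def case_from_dict(doc: Mapping, clamp: bool = False) -> CaseBundle:
    """Build a :class:`CaseBundle` from an already-parsed case document."""
    try:
        differential = DifferentialSet(_require(doc, "diagnoses", "top level"))
    except ValueError as exc:
        raise CaseSchemaError(str(exc)) from exc

    stages = []
    for k, block in enumerate(_require(doc, "stages", "top level")):
        where = f"stages[{k}]"
        name = str(block.get("name", f"stage-{k + 1}"))
        try:
            findings = FindingSet(_require(block, "findings", where))
        except ValueError as exc:
            raise CaseSchemaError(f"{where}: {exc}") from exc
        matrix = _conditionals_matrix(
            _require(block, "conditionals", where), differential, findings, where
        )
        stages.append(Stage(name, findings, matrix))
    if not stages:
        raise CaseSchemaError("case file defines no evidence stages")

    panel: tuple[ExpertElicitation, ...] = ()
    if "experts" in doc and doc["experts"]:
        panel = tuple(
            ExpertElicitation(
                expert_id=str(_require(e, "id", f"experts[{k}]")),
                priors=dict(_require(e, "priors", f"experts[{k}]")),
                conditionals={
                    dx: dict(row)
                    for dx, row in _require(e, "conditionals", f"experts[{k}]").items()
                },
            )
            for k, e in enumerate(doc["experts"])
        )
        problems = [
            p
            for e in panel
            for p in validate_elicitation(e, differential, stages[0].findings)
            if p.severity == "error"
        ]
        if problems and not clamp:
            raise CaseValidationError(
                "expert panel failed validation:\n" + "\n".join(map(str, problems))
            )

    if "priors" in doc:
        pblock = doc["priors"]
        values = pblock.get("values", pblock) if isinstance(pblock, Mapping) else None
        if not isinstance(values, Mapping):
            raise CaseSchemaError("'priors' must map diagnoses to percent values")
        missing = [dx for dx in differential if dx not in values]
        if missing:
            raise CaseSchemaError(f"priors are missing diagnoses {missing}")
        priors = np.array([float(values[dx]) for dx in differential])
        provenance = (
            str(pblock.get("provenance", "composite")) if isinstance(pblock, Mapping) else "composite"
        )
    elif panel:
        composite = aggregate_experts(panel, differential, stages[0].findings, clamp=clamp)
        priors, provenance = composite.priors, "composite"
    else:
        raise CaseSchemaError("case file needs either 'priors' or an 'experts' panel")
    if np.any(priors <= 0):
        bad = [dx for dx, v in zip(differential, priors) if v <= 0]
        raise CaseValidationError(
            f"priors for {bad} are not strictly positive; a zero prior pins the "
            "posterior at zero — use the 1% floor instead"
        )

    utilities = None
    utilities_experts: tuple[OutcomeUtilities, ...] = ()
    disease = None
    treat_label, no_treat_label = "treat", "no treat"
    if "decision" in doc:
        dec = doc["decision"]
        disease = dec.get("disease")
        if disease is not None:
            differential.index(str(disease))  # must name a known diagnosis
        treat_label = str(dec.get("treat_label", treat_label))
        no_treat_label = str(dec.get("no_treat_label", no_treat_label))
        ublock = _require(dec, "utilities", "decision")
        if "experts" in ublock:
            utilities_experts = tuple(
                _utilities_from(u, f"decision.utilities.experts[{k}]")
                for k, u in enumerate(ublock["experts"])
            )
        if "composite" in ublock:
            utilities = _utilities_from(ublock["composite"], "decision.utilities.composite")
        elif utilities_experts:
            utilities = OutcomeUtilities.mean(utilities_experts)
        else:
            raise CaseSchemaError(
                "decision.utilities needs a 'composite' block or an 'experts' list"
            )

    return CaseBundle(
        name=str(doc.get("name", "unnamed-case")),
        differential=differential,
        priors=priors,
        stages=tuple(stages),
        utilities=utilities,
        utilities_experts=utilities_experts,
        panel=panel,
        disease=str(disease) if disease is not None else None,
        treat_label=treat_label,
        no_treat_label=no_treat_label,
        priors_provenance=provenance,
        description=str(doc.get("description", "")),
        metadata=dict(doc.get("metadata", {})),
        reference=dict(doc.get("reference", {})),
    )


def _round(x: float, decimals: int | None) -> float:
    return float(x) if decimals is None else round(float(x), decimals)


def case_to_dict(bundle: CaseBundle, decimals: int | None = DEFAULT_DECIMALS) -> dict:
    """Serialize a case bundle back to the case-file document structure."""
    doc: dict = {
        "name": bundle.name,
        "description": bundle.description,
        "diagnoses": list(bundle.differential),
        "priors": {
            "provenance": bundle.priors_provenance,
            "values": {
                dx: _round(v, decimals) for dx, v in zip(bundle.differential, bundle.priors)
            },
        },
        "stages": [
            {
                "name": s.name,
                "findings": list(s.findings),
                "conditionals": {
                    dx: {
                        f: _round(s.conditionals[i, j], decimals)
                        for j, f in enumerate(s.findings)
                    }
                    for i, dx in enumerate(bundle.differential)
                },
            }
            for s in bundle.stages
        ],
    }
    if bundle.panel:
        doc["experts"] = [
            {
                "id": e.expert_id,
                "priors": {dx: _round(v, decimals) for dx, v in e.priors.items()},
                "conditionals": {
                    dx: {f: _round(v, decimals) for f, v in row.items()}
                    for dx, row in e.conditionals.items()
                },
            }
            for e in bundle.panel
        ]
    if bundle.utilities is not None:
        ublock: dict = {
            "composite": {
                "treated_disease": _round(bundle.utilities.treated_disease, decimals),
                "treated_no_disease": _round(bundle.utilities.treated_no_disease, decimals),
                "untreated_disease": _round(bundle.utilities.untreated_disease, decimals),
                "untreated_no_disease": _round(bundle.utilities.untreated_no_disease, decimals),
            }
        }
        if bundle.utilities_experts:
            ublock["experts"] = [
                {
                    "treated_disease": _round(u.treated_disease, decimals),
                    "treated_no_disease": _round(u.treated_no_disease, decimals),
                    "untreated_disease": _round(u.untreated_disease, decimals),
                    "untreated_no_disease": _round(u.untreated_no_disease, decimals),
                }
                for u in bundle.utilities_experts
            ]
        doc["decision"] = {
            "disease": bundle.disease,
            "treat_label": bundle.treat_label,
            "no_treat_label": bundle.no_treat_label,
            "utilities": ublock,
        }
    if bundle.metadata:
        doc["metadata"] = dict(bundle.metadata)
    if bundle.reference:
        doc["reference"] = dict(bundle.reference)
    return doc


def save_case(bundle: CaseBundle, path: str | Path, decimals: int | None = DEFAULT_DECIMALS) -> None:
    """Write a case bundle to YAML (percent values at ``decimals`` places)."""
    with open(path, "w") as fh:
        yaml.safe_dump(case_to_dict(bundle, decimals), fh, sort_keys=False, allow_unicode=True)


# --------------------------------------------------------------------------
# elicitation CSVs


def write_expert_csv(
    elicitation: ExpertElicitation,
    differential: DifferentialSet,
    findings: FindingSet,
    path: str | Path,
    decimals: int | None = DEFAULT_DECIMALS,
) -> None:
    """Write one expert's table as ``diagnosis,prior,<finding...>`` CSV."""
    rows = []
    for dx in differential:
        row = {"diagnosis": dx, "prior": _round(elicitation.priors[dx], decimals)}
        for f in findings:
            row[f] = _round(elicitation.conditionals[dx][f], decimals)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_expert_csv(path: str | Path, expert_id: str | None = None) -> ExpertElicitation:
    """Read one expert's ``diagnosis,prior,<finding...>`` CSV.

    The expert id defaults to the file's stem.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CaseFileError(f"cannot read elicitation CSV {path}: {exc}") from exc
    for col in ("diagnosis", "prior"):
        if col not in frame.columns:
            raise CaseSchemaError(f"{path}: elicitation CSV needs a {col!r} column")
    finding_cols = [c for c in frame.columns if c not in ("diagnosis", "prior")]
    priors = {}
    conditionals = {}
    for _, row in frame.iterrows():
        dx = str(row["diagnosis"])
        priors[dx] = float(row["prior"])
        conditionals[dx] = {f: float(row[f]) for f in finding_cols}
    return ExpertElicitation(expert_id or path.stem, priors, conditionals)


def write_panel_csvs(
    panel: Sequence[ExpertElicitation],
    differential: DifferentialSet,
    findings: FindingSet,
    directory: str | Path,
    decimals: int | None = DEFAULT_DECIMALS,
) -> list[Path]:
    """Write each panel member to ``<directory>/<expert_id>.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for e in panel:
        p = directory / f"{e.expert_id}.csv"
        write_expert_csv(e, differential, findings, p, decimals)
        paths.append(p)
    return paths


def read_panel(path: str | Path) -> list[ExpertElicitation]:
    """Read a panel: a directory of per-expert CSVs, or one long-format CSV.

    The long format has columns ``expert,diagnosis,field,value`` where
    ``field`` is ``prior`` or a finding label.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise CaseFileError(f"panel directory {path} contains no .csv files")
        return [read_expert_csv(p) for p in files]

    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CaseFileError(f"cannot read panel CSV {path}: {exc}") from exc
    required = {"expert", "diagnosis", "field", "value"}
    if not required.issubset(frame.columns):
        raise CaseSchemaError(
            f"{path}: long-format panel CSV needs columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    panel = []
    for expert_id, group in frame.groupby("expert", sort=False):
        priors: dict[str, float] = {}
        conditionals: dict[str, dict[str, float]] = {}
        for _, row in group.iterrows():
            dx = str(row["diagnosis"])
            if str(row["field"]) == "prior":
                priors[dx] = float(row["value"])
            else:
                conditionals.setdefault(dx, {})[str(row["field"])] = float(row["value"])
        panel.append(ExpertElicitation(str(expert_id), priors, conditionals))
    return panel
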
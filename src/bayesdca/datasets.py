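"""Bundled example cases."""

from __future__ import annotations

from importlib.resources import files

from .caseio import CaseBundle, load_case

__all__ = ["ferret_case", "ferret_case_path"]


def ferret_case_path() -> str:
    """Filesystem path of the bundled ferret case file."""
    return str(files("bayesdca.data") / "ferret_gi_foreign_body.yaml")


def ferret_case() -> CaseBundle:
    """The retrospective ferret gastrointestinal-foreign-body case.

    A ~1-year-old ferret with lethargy, anorexia and diarrhea, worked up
    for a suspected GI foreign body and taken to exploratory laparotomy.
    The bundle carries the composite three-expert priors and
    conditionals for the five pre-surgical findings, the three
    post-surgical findings, the clinical team's outcome utilities, and
    the published values at printed precision under ``reference``.
    """
    return load_case(ferret_case_path())
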
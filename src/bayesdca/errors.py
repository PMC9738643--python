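"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`BayesDCAError`, so callers can catch one type at an application
boundary (the CLI does exactly that).
"""


class BayesDCAError(Exception):
    """Base class for all package-specific errors."""


class PanelMismatchError(BayesDCAError):
    """Expert elicitations in a panel do not cover the same diagnosis or
    finding labels; the message names the mismatched labels."""


class ZeroProbabilityError(BayesDCAError):
    """A prior or conditional probability of zero was supplied.

    A zero anywhere in the product form forces that diagnosis's posterior
    to zero no matter what later evidence says, which is almost never the
    elicitor's intent.  Zeros are therefore rejected rather than
    propagated; pass ``floor=True`` where offered to substitute the 1%
    elicitation floor instead.
    """


class DominanceError(BayesDCAError):
    """No treatment threshold exists because one choice dominates.

    Raised when benefit (treated disease minus untreated disease) or harm
    (untreated no-disease minus treated no-disease) is not strictly
    positive: the expected-value lines never cross inside (0, 100).
    """


class UnknownLabelError(BayesDCAError, KeyError):
    """A diagnosis or finding label is not part of the relevant set."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return BayesDCAError.__str__(self)


class CaseFileError(BayesDCAError):
    """A case or elicitation file could not be parsed at all."""


class CaseSchemaError(BayesDCAError):
    """A case file parsed but violates the expected structure; the message
    names the missing or malformed element (down to the
    (diagnosis, finding) cell where applicable)."""


class CaseValidationError(BayesDCAError):
    """A structurally valid case file contains values that fail
    elicitation validation (floor/range violations)."""
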
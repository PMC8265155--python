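"""Exception hierarchy shared across the package.

Errors split into configuration/usage problems (``ConfigError``) and
data-dependent conditions that make a single computation impossible
(``NotTestableError`` and friends). Scans catch the latter per gene/pair
and continue; CLI entry points map the former to exit code 2.
"""


class MultisepError(Exception):
    """Base class for all package errors."""


class ConfigError(MultisepError):
    """Invalid configuration, missing inputs, or schema violations."""


class DuplicateIdentifierError(ConfigError):
    """A matrix or table contains a repeated cell-line or gene identifier."""


class EmptyIntersectionError(ConfigError):
    """No cell line is shared by all loaded data sources."""


class DegenerateGeneError(MultisepError):
    """Expression values are constant (or near-constant) for a gene."""


class InsufficientDataError(MultisepError):
    """Too few finite observations to fit the requested mixture."""


class TissueTooSmallError(MultisepError):
    """A tissue subset holds fewer cell lines than the configured minimum."""

    def __init__(self, tissue: str, n: int, minimum: int):
        self.tissue = tissue
        self.n = n
        self.minimum = minimum
        super().__init__(
            f"tissue {tissue!r} has {n} cell lines; at least {minimum} required"
        )


class NotTestableError(MultisepError):
    """A dependency test's preconditions are not met for this pair."""


class NotPredictableError(MultisepError):
    """A baseline method cannot emit a score for this gene or pair."""


class EmptyGoldStandardError(MultisepError):
    """No gold-standard positive survives intersection with predictions."""
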
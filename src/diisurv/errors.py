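"""Exception hierarchy for diisurv.

All package-raised errors derive from :class:`DiisurvError` so callers can
catch pipeline failures without touching unrelated exceptions.
"""


class DiisurvError(Exception):
    """Base class for all diisurv errors."""


class SchemaError(DiisurvError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(DiisurvError):
    """A value violates a domain invariant (e.g. non-positive reference SD)."""


class UsageError(DiisurvError):
    """Objects were combined inconsistently (e.g. per-day profile vs per-1000 kcal database)."""


class DomainError(DiisurvError):
    """A numeric argument is outside the mathematical domain of an operation."""


class FoodLookupError(DiisurvError):
    """Food identifiers could not be resolved in the composition table."""

    def __init__(self, identifiers):
        self.identifiers = sorted(set(identifiers))
        super().__init__(f"unresolvable food identifiers: {', '.join(map(str, self.identifiers))}")


class MissingDataError(DiisurvError):
    """Required per-subject data are absent (e.g. zero recall days)."""


class FitError(DiisurvError):
    """A survival model could not be fitted (no events, separation, non-convergence)."""
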
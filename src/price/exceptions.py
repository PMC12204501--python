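"""Exception hierarchy for the PRICE diagnostic-tree toolkit."""


class PriceError(Exception):
    """Base class for all errors raised by this package."""


class TreeFormatError(PriceError):
    """A tree document violates the JSON tree format (schema, duplicate ids, ...)."""


class InvalidTreeError(PriceError):
    """An operation that requires a valid tree was given an invalid one.

    Carries the list of :class:`~price.tree_model.Violation` records that
    ``validate_tree`` produced.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"[{v.code}] {v.node_id}: {v.message}" for v in self.violations)
        super().__init__(f"tree failed validation: {lines}")


class UndefinedPredictiveValueError(PriceError):
    """A predictive value is undefined because its denominator is zero."""


class UnsupportedResultError(PriceError):
    """A result value outside {positive, negative} reached the utility model."""


class NonPositiveEffectivenessError(PriceError):
    """Effective cost requested for a pathway with expected effectiveness <= 0."""


class DelegationError(PriceError):
    """The AI-delegation transform was applied to an unsuitable node or subtree."""


class NonMonotoneObjectiveError(PriceError):
    """The effective-cost objective is not monotone in AI precision on the scan grid."""


class TruncationError(PriceError):
    """Rejection sampling under a truncation bound exceeded the resample cap."""
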
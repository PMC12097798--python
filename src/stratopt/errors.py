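"""Exception hierarchy shared across stratopt modules."""


class StratoptError(Exception):
    """Base class for all stratopt errors."""


class DomainError(StratoptError):
    """A cell or point lies outside a density's support."""


class ConfigurationError(StratoptError):
    """Invalid or inconsistent specification (families, parameters, shapes)."""


class UndefinedMomentError(StratoptError):
    """Moment requested for a zero-mass cell."""


class InputError(StratoptError):
    """Malformed user input (length mismatches, non-positive costs, ...)."""


class InfeasibleError(StratoptError):
    """The requested design cannot be satisfied (L > grid, total < strata, ...)."""


class SingularFitError(StratoptError):
    """Rank-deficient design matrix in the superpopulation fit."""


class BudgetExceededError(StratoptError):
    """Combinatorial enumeration would exceed the stated budget."""
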
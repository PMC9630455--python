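"""Exception hierarchy shared across the package."""


class SlideUQError(Exception):
    """Base class for all package-specific errors."""


class InvalidEnsembleError(SlideUQError):
    """Ensemble violates its structural invariants (e.g. fewer than 2 passes)."""


class DomainError(SlideUQError):
    """A numeric value lies outside its permitted domain."""


class IntegrityError(SlideUQError):
    """Identifiers are inconsistent (duplicates, mixed slides, ...)."""


class EmptyInputError(SlideUQError):
    """An operation received an empty collection it cannot act on."""


class ShapeError(SlideUQError):
    """Parallel sequences have mismatched lengths."""


class StateError(SlideUQError):
    """An object is missing a field required by the requested operation."""


class ConfigError(SlideUQError):
    """A configuration field is invalid; the message names the field."""


class InsufficientDataError(SlideUQError):
    """Too few slides per class to honour the requested fold layout."""


class DegenerateLabelsError(SlideUQError):
    """A metric requiring both classes received single-class labels."""


class ContractError(SlideUQError):
    """A predictor-contract call was malformed (unknown tiles, unfit model)."""


class SchemaError(SlideUQError):
    """A tabular file is missing a required column; the message names it."""


class FormatError(SlideUQError):
    """A file's contents violate the expected layout (e.g. pass indices)."""
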
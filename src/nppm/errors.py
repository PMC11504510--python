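"""Exception and warning types shared across the package."""


class NPPMError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NPPMError):
    """A product table is missing mandatory columns/keys or has unknown ones."""


class ProductValidationError(NPPMError):
    """A product row violates a domain invariant.

    Carries enough context (product_id, field) to locate the offending row.
    """

    def __init__(self, message: str, product_id: str | None = None, field: str | None = None):
        super().__init__(message)
        self.product_id = product_id
        self.field = field


class RulesetError(NPPMError):
    """A ruleset config is malformed or references an unknown subcategory."""


class GenerationError(NPPMError):
    """Synthetic-data constraints are mutually inconsistent under the ruleset."""


class InsufficientInputWarning(UserWarning):
    """A check was applicable but the product lacked the inputs to evaluate it."""


class VacuousResultWarning(UserWarning):
    """A rollup was computed over an empty set of applicable checks."""
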
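"""Exception hierarchy shared across the package."""


class OrdqualError(Exception):
    """Base class for all ordqual errors."""


class SchemaError(OrdqualError):
    """A required column is missing or the column mapping is malformed."""


class ValidationError(OrdqualError):
    """Input data violate a domain invariant (negative mass, duplicated group, ...)."""


class ScaleMismatchError(OrdqualError):
    """Two profiles were compared across different quality scales."""


class DegenerateWeightsError(OrdqualError):
    """The lottery normalizer is zero: one provider holds all registrations."""
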
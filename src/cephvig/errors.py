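"""Exception types shared across the package."""


class CephvigError(Exception):
    """Base class for package errors."""


class SchemaError(CephvigError):
    """A line-listing file does not match the documented column schema."""


class ValidationError(CephvigError):
    """Input records violate a dataset invariant (e.g. conflicting demographics)."""


class InfeasibleConfigError(CephvigError):
    """A simulation configuration cannot be realised exactly."""
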
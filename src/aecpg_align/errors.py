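"""Exception hierarchy shared by all modules."""


class AECPGError(Exception):
    """Base class for all package errors."""


class SchemaError(AECPGError):
    """A table is missing required columns or is structurally unreadable."""


class ValidationError(AECPGError):
    """A value violates the scoring/weighting alphabet or a matrix invariant."""


class CatalogMismatchError(AECPGError):
    """Two objects do not share the same public-good catalog."""


class UndefinedAgreementError(AECPGError):
    """Potential agreement is zero, so the agreement percentage is undefined."""
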
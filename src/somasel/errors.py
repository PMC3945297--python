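"""Exception types shared across the package."""


class SomaselError(Exception):
    """Base class for package errors."""


class ValidationError(SomaselError, ValueError):
    """An input violated a structural precondition (bad CDS, bad schema...)."""


class SchemeMismatchError(SomaselError, ValueError):
    """A functionality table was used with the wrong scheme."""


class ClassificationError(SomaselError, ValueError):
    """A substitution record could not be classified against its gene model."""
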
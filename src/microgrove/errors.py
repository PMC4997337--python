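"""Exception hierarchy shared across the pipeline."""


class MicrogroveError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MicrogroveError):
    """A file violates its declared dialect (bad counts, missing columns...)."""


class InvariantError(MicrogroveError):
    """An in-memory object violates a structural invariant."""


class UntestableError(MicrogroveError):
    """A statistical test cannot be run on the given data (constant factor,
    all-zero response, too few observations)."""


class AliasingError(MicrogroveError):
    """Perfectly collinear model terms."""
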
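"""Exception hierarchy."""


class GelrsmError(Exception):
    """Base class for all package-specific errors."""


class InputError(GelrsmError, ValueError):
    """A caller-supplied value violates a precondition."""


class ModelIntegrityError(GelrsmError):
    """A model object is internally inconsistent (e.g. NaN coefficient)."""


class FitError(GelrsmError):
    """A regression or nonlinear fit cannot be carried out or did not converge."""
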
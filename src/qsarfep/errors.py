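"""Exception types shared across the package."""


class ParameterError(ValueError):
    """Invalid user-supplied parameter or specification."""


class ParseError(ValueError):
    """Malformed input file or record."""


class DegenerateGeometryError(ValueError):
    """Geometric input without a well-defined solution (e.g. collinear points)."""


class ColumnMismatchError(ValueError):
    """Descriptor columns of a block do not match those a model was fitted on."""


class InsufficientOverlapError(RuntimeError):
    """Forward/reverse work distributions overlap too little for a BAR solution."""
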
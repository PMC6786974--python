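"""Exception types shared across the toolkit."""


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(ValueError):
    """Input data carry too little information for the operation (all missing,
    constant, zero scale, ...)."""


class AlignmentError(ValueError):
    """Sample sets of jointly used tables do not line up."""
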
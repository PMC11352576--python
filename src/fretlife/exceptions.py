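"""Exception hierarchy used across the package."""


class FormatError(ValueError):
    """A track table or config file does not conform to the expected layout."""


class ValidationError(ValueError):
    """A field value violates a data-model invariant (reports the offending row)."""


class EstimationError(RuntimeError):
    """Maximum-likelihood estimation cannot produce a finite, well-defined result."""


class GenerationError(RuntimeError):
    """The simulator could not collect the requested number of tracks."""


class StudyError(RuntimeError):
    """A replicated simulation study produced no usable experiments."""
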
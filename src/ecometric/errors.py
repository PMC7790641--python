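"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data or configuration violates a documented contract.

    Messages always name the offending field, species, point or site so that
    failures in a long pipeline run are traceable to a row of input.
    """
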
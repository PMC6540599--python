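class SchemaError(ValueError):
    """A tabular input file or in-memory table violates the expected schema."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but statistically degenerate (e.g. zero mean)."""
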
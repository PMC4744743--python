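"""Exception types shared across the package."""


class DataFormatError(Exception):
    """An input file could not be parsed or violates a format precondition."""


class PedigreeError(Exception):
    """The pedigree is inconsistent with the requested analysis."""
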
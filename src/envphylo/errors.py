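"""Exception hierarchy."""


class EnvPhyloError(Exception):
    """Base class for all package errors."""


class ValidationError(EnvPhyloError, ValueError):
    """Invalid input data or parameters."""


class ParseError(EnvPhyloError, ValueError):
    """Malformed input file (FASTA, Newick, PHYLIP, ...)."""
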
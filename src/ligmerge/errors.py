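"""Exception hierarchy."""


class LigMergeError(Exception):
    """Base class for all errors raised by this package."""


class EmptyModelError(LigMergeError):
    """A molecule (or PDB file) contains no usable heavy atoms."""


class PDBFormatError(LigMergeError):
    """A PDB record could not be parsed."""


class ConfigurationError(LigMergeError):
    """Invalid configuration: unknown element, bad CLI arguments, etc."""


class NoMCSFoundError(LigMergeError):
    """No common substructure of the requested minimum size exists."""


class StructureError(LigMergeError):
    """Inconsistent molecular structure (e.g. a substituent fragment with
    no bond into the common substructure)."""
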
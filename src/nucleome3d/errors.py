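"""Exception hierarchy shared across the package."""


class Nucleome3DError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(Nucleome3DError, ValueError):
    """An argument or input record violates a documented invariant."""


class GenomicRangeError(Nucleome3DError, ValueError):
    """A genomic coordinate or range falls outside the model."""


class StoreError(Nucleome3DError):
    """Base class for model-store I/O failures."""


class StoreVersionError(StoreError):
    """The on-disk store format version is not supported."""


class StoreDecodeError(StoreError):
    """A payload file could not be decompressed or parsed."""


class PdbOverflowError(Nucleome3DError, ValueError):
    """Too many atoms for fixed-column PDB serial numbers."""


class SceneRangeError(Nucleome3DError, ValueError):
    """A requested scene range exceeds the configured cap."""
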
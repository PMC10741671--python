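"""Exception types shared across the package."""


class KindredScanError(Exception):
    """Base class for all package errors."""


class GenealogyError(KindredScanError):
    """Invalid genealogy structure (cycles, missing parents, sex conflicts)."""


class UnknownIndividualError(KindredScanError):
    """An operation referenced an individual id absent from the genealogy."""


class RecordError(KindredScanError):
    """A registry / death / assay record is inconsistent with the genealogy."""


class VcfError(KindredScanError):
    """Malformed or unsupported VCF content."""


class ConfigError(KindredScanError):
    """Invalid simulation or pipeline configuration."""
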
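"""Exception hierarchy for the haplomarker pipeline."""


class HaplomarkerError(Exception):
    """Base class for all pipeline errors."""


class GffError(HaplomarkerError):
    """Gene-model ingestion failed (missing CDS, bad phase, ...)."""


class VcfFormatError(HaplomarkerError):
    """Variant matrix ingestion failed."""


class CoordinateError(HaplomarkerError):
    """Invalid start-codon-relative or genomic coordinate."""


class RegionError(HaplomarkerError):
    """Gene-region extraction or variant placement problem."""


class ClassificationError(HaplomarkerError):
    """Haplotype classification cannot proceed."""


class DesignError(HaplomarkerError):
    """No admissible marker/primer design exists."""


class GenotypingError(HaplomarkerError):
    """In-silico genotyping failed (e.g. non-specific marker)."""


class ConfigError(HaplomarkerError):
    """Infeasible synthetic-panel configuration."""
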
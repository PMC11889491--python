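"""Exception hierarchy for cohort validation and analysis stages."""


class SexomeError(Exception):
    """Base class for all package errors."""


class CohortFileError(SexomeError):
    """An input file is missing or unreadable."""


class DuplicateIdError(SexomeError):
    """Duplicate ASV or sample identifiers in an input table."""


class CrossReferenceError(SexomeError):
    """Counts, taxonomy, metadata or sequences do not cover each other."""


class NegativeCountError(SexomeError):
    """A read count is negative."""


class NonIntegerCountError(SexomeError):
    """A read count is not integer-valued."""


class EmptySampleError(SexomeError):
    """A sample column sums to zero where positive reads are required."""


class UnknownRankError(SexomeError):
    """Requested taxonomic rank is not stored in the taxonomy table."""


class InvalidMetadataError(SexomeError):
    """A sample record violates the specimen/control field contract."""


class NoControlSamplesError(SexomeError):
    """Contaminant identification requires at least one negative control."""


class MissingTimepointError(SexomeError):
    """A participant lacks a before or after specimen."""


class MalformedCoupleError(SexomeError):
    """A couple does not have exactly 2 sexes x 2 timepoints of specimens."""


class SimulationError(SexomeError):
    """Invalid simulation configuration."""


class PipelineStageError(SexomeError):
    """A pipeline stage aborted; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
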
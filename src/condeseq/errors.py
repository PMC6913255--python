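"""Exception hierarchy.

Every error raised on bad user input derives from :class:`CondeseqError` so a
CLI or pipeline driver can catch one type and report an actionable message.
"""


class CondeseqError(Exception):
    """Base class for all condeseq errors."""


class SchemaError(CondeseqError):
    """A required column or field is missing from an input table."""


class DesignError(CondeseqError):
    """The experimental design is invalid (groups, pairing, replicates)."""


class AlignmentError(CondeseqError):
    """Gene identifier sets disagree between inputs."""


class DataError(CondeseqError):
    """Counts are malformed (negative, non-integer, duplicated IDs)."""


class NormalizationError(CondeseqError):
    """Scale/size factors cannot be computed for the given matrix."""


class EstimationError(CondeseqError):
    """A statistical estimate (dispersion, NB parameters) cannot be formed."""


class EngineError(CondeseqError):
    """A DE engine cannot run on the given design."""


class MergeError(CondeseqError):
    """Engine results cannot be merged into a consensus table."""


class ConfigError(CondeseqError):
    """A simulation or run configuration is invalid."""
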
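"""Exception hierarchy for bcrmrd."""


class BcrmrdError(Exception):
    """Base class for all bcrmrd errors."""


class FormatError(BcrmrdError):
    """A sequence file could not be parsed or classified."""


class SchemaError(BcrmrdError):
    """A tabular file is missing mandatory columns or holds invalid values."""


class EmptyRepertoireError(BcrmrdError):
    """No reads survived filtering / an empty repertoire was supplied."""


class InsufficientDataError(BcrmrdError):
    """Too few observations for the requested statistic."""


class AnnotationError(BcrmrdError):
    """A sequence could not be assigned V and J segments above the score floor."""


class SimulationError(BcrmrdError):
    """Simulator parameters are infeasible (e.g. rejection sampling exhausted)."""
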
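"""Exception hierarchy for the episig pipeline."""


class EpisigError(Exception):
    """Base class for all episig errors."""


class ConfigurationError(EpisigError, ValueError):
    """Invalid configuration (dimensions, ranges, unknown keys)."""


class DomainError(EpisigError, ValueError):
    """A value outside its mathematical domain (e.g. beta not in (0,1))."""


class EmptyCohortError(EpisigError):
    """Sample-level QC removed every sample."""


class EmptySignatureError(EpisigError):
    """Site selection produced an empty episignature; downstream must handle."""


class PipelineError(EpisigError):
    """A multi-stage run aborted; the message names the failing stage."""
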
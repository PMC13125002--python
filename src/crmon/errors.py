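"""Exception hierarchy for the crmon pipeline."""


class CRMonError(Exception):
    """Base class for all crmon-specific errors."""


class ConfigurationError(CRMonError, ValueError):
    """Invalid simulator or pipeline configuration (non-positive rates, durations...)."""


class ProtocolError(CRMonError, ValueError):
    """Inconsistent LBNP protocol (endpoint in baseline, zero endpoint pressure...)."""


class FormatError(CRMonError, ValueError):
    """Malformed input file (missing header, non-monotone timestamps...)."""


class DialectError(CRMonError, ValueError):
    """Sampling rate inconsistent with the declared CSV dialect."""


class EmptyRecordError(CRMonError, ValueError):
    """An operation produced or received a waveform with no samples."""


class ParameterError(CRMonError, ValueError):
    """Out-of-range operation parameter (non-positive target rate, stride < 1...)."""


class ContractError(CRMonError, ValueError):
    """Violation of an inter-module data contract (wrong window length, value range)."""


class EvaluationError(CRMonError, ValueError):
    """Evaluation cannot proceed (empty overlap, no valid windows...)."""
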
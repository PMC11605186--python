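"""Package exception hierarchy."""


class EpiCrossNetError(Exception):
    """Base class for package errors."""


class ParameterError(EpiCrossNetError, ValueError):
    """Invalid generator or model parameters."""


class SchemaError(EpiCrossNetError, KeyError):
    """Feature name not resolvable against the feature schema."""


class SelectionError(EpiCrossNetError, ValueError):
    """Site-selection produced an empty or ill-posed labeled set."""


class SamplingError(EpiCrossNetError, ValueError):
    """Balanced sampling impossible (negative pool too small)."""


class AnnotationError(EpiCrossNetError, ValueError):
    """A site could not be mapped onto the transcript model."""


class EvaluationError(EpiCrossNetError, ValueError):
    """Metric undefined for the given labels (e.g. single-class)."""


class TrainingError(EpiCrossNetError, ValueError):
    """Training preconditions violated (e.g. single-class split)."""


class ParseError(EpiCrossNetError, ValueError):
    """Malformed record in an on-disk artifact."""
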
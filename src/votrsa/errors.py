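"""Domain-specific exceptions raised across the pipeline."""


class VotrsaError(Exception):
    """Base class for all pipeline errors."""


class UnsupportedConditionError(VotrsaError):
    """An operation was asked to run on a stimulus condition it is not defined for
    (e.g. a logo-grapheme RDM for stroke combinations)."""


class InvalidStimulusError(VotrsaError):
    """A stimulus violates its invariants (empty unit set, bad counts)."""


class InvalidRDMError(VotrsaError):
    """A dissimilarity matrix is asymmetric, has a nonzero diagonal, or is out of
    range for its kind."""


class LookupError_(VotrsaError):
    """An id was not found in a table (embeddings, manifests)."""


class DegenerateVectorError(VotrsaError):
    """A zero-norm embedding vector makes cosine dissimilarity undefined."""


class SingularDesignError(VotrsaError):
    """The design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class TimingError(VotrsaError):
    """An event falls outside the acquired scan window."""


class ContrastSpecError(VotrsaError):
    """A contrast references unknown columns or is all-zero."""


class IncompleteDesignError(VotrsaError):
    """A repeated-measures table has missing subject x condition cells."""


class DegenerateConditionError(VotrsaError):
    """Trial exclusion removed every trial of a condition for a retained subject."""


class UndefinedCorrelationError(VotrsaError):
    """A correlation is undefined (constant input)."""


class FormatError(VotrsaError):
    """A file could not be parsed as the expected format."""


class ConfigurationError(VotrsaError):
    """Inconsistent or impossible configuration values."""
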
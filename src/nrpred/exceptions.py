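"""Exception hierarchy.

Everything user-facing derives from :class:`NrpredError`; the CLI maps these
to exit code 1 and anything else to exit code 2.
"""


class NrpredError(Exception):
    """Base class for all validation and domain errors raised by nrpred."""


class ZeroVarianceScale(NrpredError):
    """A property scale whose 20 values are all equal cannot be standardized."""


class EmptySequence(NrpredError):
    """Sequence is empty after whitespace removal."""


class TooManyAmbiguous(NrpredError):
    """More than 10% of residues are non-canonical; the input is untrustworthy."""


class AmbiguousResidue(NrpredError):
    """A non-canonical residue was encountered in strict sanitization mode."""


class LagTooLarge(NrpredError):
    """Requested lag g is >= sequence length; the covariance sum is empty."""


class SameProperty(NrpredError):
    """Cross-covariance requested with i1 == i2; use auto-covariance instead."""


class SequenceTooShort(NrpredError):
    """Sequence length L <= max lag; not every feature component is defined."""


class MalformedFasta(NrpredError):
    """FASTA stream violates the dialect (reported with a line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownLabel(NrpredError):
    """Label manifest contains a label outside the closed vocabulary."""


class DuplicateId(NrpredError):
    """Label manifest repeats a sequence id."""


class MissingSequence(NrpredError):
    """Manifest references sequence ids absent from the FASTA input."""


class BatchTooLarge(NrpredError):
    """More query sequences than the 500-sequence batch cap."""


class TooFewSamples(NrpredError):
    """A class has too few members for the requested cross-validation."""


class EmptyEvaluation(NrpredError):
    """An evaluation report over zero samples is undefined."""


class ModelMismatch(NrpredError):
    """A persisted model archive does not match the running encoder config."""
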
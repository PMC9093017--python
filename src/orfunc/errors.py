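"""Exception hierarchy shared across the pipeline."""


class OrfuncError(Exception):
    """Base class for all orfunc-specific errors."""


class AlignmentFormatError(OrfuncError):
    """Alignment file is malformed or violates alignment invariants."""


class ResponseFormatError(OrfuncError):
    """Response-matrix file is malformed (bad header, duplicate labels, non-numeric cells)."""


class UndefinedDistanceError(OrfuncError):
    """Two receptors share no odorant with non-missing responses."""


class InsufficientDataError(OrfuncError):
    """Too few receptors (or training rows) for the requested computation."""


class RankingError(OrfuncError):
    """No alignment column is eligible for scoring."""
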
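"""Exception hierarchy.

``ValueError`` is used for plain invalid-argument conditions; the classes
here mark analysis-level failures a pipeline may want to catch separately.
"""


class FicollNMRError(Exception):
    """Base class for analysis-level failures."""


class CalibrationError(FicollNMRError):
    """No reference feature above the noise floor in the search window."""


class NormalizationError(FicollNMRError):
    """Total-area normalization impossible (non-positive row sum)."""


class PairingError(FicollNMRError):
    """Paired analysis requested on a subject lacking a pre/post pair."""

    def __init__(self, subject_id: str, message: str | None = None):
        self.subject_id = subject_id
        super().__init__(message or f"subject {subject_id!r} is not a complete pre/post pair")


class DegenerateAnalysisError(FicollNMRError):
    """Analysis ran but produced no usable result (e.g. all-zero differences)."""
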
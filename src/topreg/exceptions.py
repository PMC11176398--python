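"""Exception hierarchy for topreg."""


class TopregError(Exception):
    """Base class for all topreg errors."""


class ConfigurationError(TopregError):
    """A required column, key or option is missing or invalid."""


class EmptyDatasetError(TopregError):
    """No records survived cleaning."""


class SmilesParseError(TopregError):
    """A SMILES string could not be parsed."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class SingularFitError(TopregError):
    """The regression design is rank deficient.

    ``anchors`` names the offending (collinear) anchor positions when they
    could be identified.
    """

    def __init__(self, message: str, anchors=()):
        self.anchors = tuple(anchors)
        super().__init__(message)


class TooFewAnchorsError(TopregError):
    """Fewer than two anchor points were requested."""


class CannotSplitError(TopregError):
    """A scaffold split is impossible (e.g. a single scaffold)."""
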
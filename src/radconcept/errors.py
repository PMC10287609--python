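"""Exception hierarchy shared across the package."""


class RadconceptError(Exception):
    """Base class for all package-specific errors."""


class LexiconFormatError(RadconceptError):
    """A mapping file is structurally invalid (e.g. a required column is missing)."""


class LexiconValidationError(RadconceptError):
    """A mapping-file row violates a lexicon invariant (e.g. malformed CUI)."""


class SynonymConflictError(RadconceptError):
    """The same surface phrase is claimed by two different concept entries."""

    def __init__(self, phrase: str, entry_a: str, entry_b: str):
        self.phrase = phrase
        self.entry_a = entry_a
        self.entry_b = entry_b
        super().__init__(
            f"surface phrase {phrase!r} is claimed by both {entry_a!r} and {entry_b!r}"
        )


class UnknownLabelError(RadconceptError):
    """A preferred label was referenced that does not exist in the lexicon."""


class CorpusFormatError(RadconceptError):
    """A report repository file is missing required columns."""


class PipelineOrderError(RadconceptError):
    """A stage received input that skipped a mandatory upstream stage."""


class StratificationError(RadconceptError):
    """A class is too small to populate every fold."""


class ModelStateError(RadconceptError):
    """An operation requires a trained/refit model that is not available."""


class ParameterError(RadconceptError):
    """An invalid configuration or operation parameter."""
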
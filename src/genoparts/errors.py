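"""Exception hierarchy for genoparts."""


class GenopartsError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(GenopartsError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class FrameError(GenopartsError):
    """Coding sequence length is not divisible by three."""


class PrematureStopError(GenopartsError):
    """Internal stop codon encountered during translation."""

    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        self.codon = codon
        super().__init__(f"internal stop codon {codon!r} at codon index {codon_index}")


class MissingReferenceError(GenopartsError):
    """A referenced contig or record is absent from the supplied genome."""


class ConsistencyError(GenopartsError):
    """Coordinates do not agree between related records (mapping/locus/ORF)."""


class StructuralError(GenopartsError):
    """A domain object violates a structural constraint (unknown part type etc.)."""


class DomesticationError(GenopartsError):
    """No admissible substitution removes a restriction site."""


class IntegrityError(GenopartsError):
    """Registry referential-integrity violation (dangling or duplicate reference)."""


class UsageError(GenopartsError):
    """An operation was invoked with inapplicable options."""


class UndefinedStatisticError(GenopartsError):
    """Statistic requested on an empty input."""


class GenerationError(GenopartsError):
    """Synthetic-dataset generation failed (infeasible parameters)."""
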
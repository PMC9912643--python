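"""Exception hierarchy for hlaase."""


class HlaaseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HlaaseError, ValueError):
    """Malformed input record (FASTA header, TSV row, ...)."""


class AlleleLookupError(HlaaseError, KeyError):
    """A genotype allele could not be resolved in the allele database."""

    def __init__(self, name: str, near_matches=()):
        self.name = name
        self.near_matches = tuple(near_matches)
        hint = f"; near matches: {', '.join(self.near_matches)}" if near_matches else ""
        super().__init__(f"allele {name!r} not found in database{hint}")

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class AmbiguousAlleleError(HlaaseError, ValueError):
    """A partial-resolution allele name matches more than one database entry."""

    def __init__(self, name: str, matches):
        self.name = name
        self.matches = tuple(matches)
        super().__init__(
            f"allele {name!r} is ambiguous: matches {', '.join(self.matches)}"
        )


class ParameterError(HlaaseError, ValueError):
    """An argument is outside its valid domain (k too large, rho <= 0, ...)."""


class PipelineError(HlaaseError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
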
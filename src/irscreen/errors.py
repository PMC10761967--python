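"""Exception hierarchy shared across the package."""


class IrscreenError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(IrscreenError, ValueError):
    """A FASTA file violated the expected header or residue conventions."""


class MissingOrthologError(IrscreenError, LookupError):
    """No sequence is available for a required (gene, species) combination."""

    def __init__(self, gene: str, species) -> None:
        self.gene = gene
        self.species = tuple(species) if not isinstance(species, str) else (species,)
        sp = ", ".join(self.species)
        super().__init__(f"no ortholog for gene {gene!r} in species: {sp}")


class UndefinedRatioError(IrscreenError, ZeroDivisionError):
    """An identity ratio is undefined because its denominator is zero."""


class DegenerateProportionsError(IrscreenError, ValueError):
    """Pooled proportion is 0 or 1: the z statistic has zero variance."""
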
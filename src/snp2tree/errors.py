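"""Exception hierarchy for the pipeline.

Every stage raises a subclass of Snp2TreeError so the CLI can attribute a
failure to its stage and exit with an actionable message.
"""


class Snp2TreeError(Exception):
    """Base class for all package errors."""


class FormatError(Snp2TreeError):
    """Input file violates its declared format."""


class FormatDetectionError(Snp2TreeError):
    """No known genotype format matched the file content."""


class EmptyInputError(Snp2TreeError):
    """A genotype file parsed to zero usable records."""


class EmptyAfterFilterError(Snp2TreeError):
    """Site filtering removed every site."""


class EmptyAfterPruneError(Snp2TreeError):
    """LD pruning removed every site."""


class UndefinedMAFError(Snp2TreeError):
    """Minor allele frequency requested at a site with no non-missing calls."""


class CacheError(Snp2TreeError):
    """Genotype cache is incompatible or corrupt."""


class NewickParseError(Snp2TreeError):
    """Malformed Newick input.

    Carries the character offset at which parsing failed.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class LikelihoodError(Snp2TreeError):
    """Non-finite likelihood or a tree/alignment mismatch."""
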
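"""Exception hierarchy for hla_popgen."""


class HlaPopgenError(Exception):
    """Base class for all package errors."""


class AlleleFormatError(HlaPopgenError):
    """An allele string does not parse under the supported grammars."""


class UnmappedAlleleError(HlaPopgenError):
    """A B14/B15/B40 full-resolution allele has no serological split assignment."""


class MalformedRecordError(HlaPopgenError):
    """A genotype table row violates the record contract."""


class InconsistentInputError(HlaPopgenError):
    """Two inputs that must agree (e.g. haplotypes vs. allele frequencies) do not."""


class DegenerateTestError(HlaPopgenError):
    """A statistical test was requested on data that leave it no degrees of freedom."""


class InfiniteDistanceError(HlaPopgenError):
    """Two populations share no alleles at any locus; genetic identity is zero."""


class FixtureChecksumError(HlaPopgenError):
    """A packaged reference table does not match its recorded checksum."""


class PipelineStageError(HlaPopgenError):
    """A pipeline stage failed; carries the stage name and input context."""

    def __init__(self, stage: str, context: str, cause: Exception):
        self.stage = stage
        self.context = context
        self.cause = cause
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")
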
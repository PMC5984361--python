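"""Exception hierarchy for the SSB-dN/dS pipeline."""


class SsbDndsError(Exception):
    """Base class for all package errors."""


# --- reference ---------------------------------------------------------------
class InvalidBase(SsbDndsError):
    """A nucleotide outside {A, C, G, T} was supplied."""


class InvalidSubstitution(SsbDndsError):
    """Reference and alternate alleles are identical."""


class ContextUnavailable(SsbDndsError):
    """A trinucleotide-context classification was requested at a position
    whose 5' or 3' neighbor is unknown."""


class EmptyTranscript(SsbDndsError):
    """A transcript with an empty coding sequence."""


class InvalidTranscript(SsbDndsError):
    """A CDS violating the transcript-model invariants (length not a
    multiple of 3, non-ACGT characters, internal stop codon)."""


# --- mutations ---------------------------------------------------------------
class DialectError(SsbDndsError):
    """The mutation table lacks a required column."""


class OutOfBounds(SsbDndsError):
    """A CDS position beyond the transcript length."""


class ReferenceMismatch(SsbDndsError):
    """The stated reference allele disagrees with the CDS."""


class MissingSpectrum(SsbDndsError):
    """A gene present in the cohort has no site spectrum."""


# --- selection ---------------------------------------------------------------
class EmptySpectrum(SsbDndsError):
    """A site spectrum with zero total sites."""


class NoMutations(SsbDndsError):
    """An operation that requires at least one mutation received none."""


class SystemMismatch(SsbDndsError):
    """Substitution-class systems of two objects disagree."""


class DegenerateSites(SsbDndsError):
    """Corrected non-synonymous or synonymous site total is zero."""


# --- regions -----------------------------------------------------------------
class EmptyRegion(SsbDndsError):
    """A region mask covering no position."""


class UnknownProtein(SsbDndsError):
    """An epitope interval names a protein absent from the transcriptome."""


class Degenerate(SsbDndsError):
    """A permutation test in which no interval has an eligible placement."""


# --- simulate / config -------------------------------------------------------
class ConfigError(SsbDndsError):
    """An infeasible or inconsistent configuration value."""
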
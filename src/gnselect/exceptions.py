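"""Domain-specific error types raised across gnselect modules."""


class GnselectError(Exception):
    """Base class for all gnselect errors."""


class FormatError(GnselectError):
    """An input file could not be parsed; the message names the offending record."""


class DuplicateSiteError(FormatError):
    """Two variant records share the same (chrom, pos)."""


class DuplicateLocusError(FormatError):
    """Two loci share the same locus_id."""


class UndefinedFrequencyError(GnselectError):
    """Allele frequency requested at a site where every call is missing."""


class MonomorphicSiteError(GnselectError):
    """LD requested for a site pair where a site is monomorphic after pairwise deletion."""


class LabelConflictError(GnselectError):
    """Loci merged into one neighborhood carry conflicting group labels."""


class DegenerateVarianceError(GnselectError):
    """Two-sample t-test with zero pooled variance and unequal means."""


class InsufficientDataError(GnselectError):
    """Too few observations for the requested smoother or test."""


class FrameError(GnselectError):
    """Coding sequence length is not a multiple of three."""


class AlignmentError(GnselectError):
    """Paired sequences are not a valid pre-aligned pair."""


class InvalidCdsError(GnselectError):
    """Coding sequence contains an internal stop codon after cleaning."""


class ConvergenceError(GnselectError):
    """Likelihood optimisation failed to converge after multistart."""


class EmptyPolymorphismError(GnselectError):
    """No polymorphic sites remain after frequency filtering."""


class CorrectionUndefinedError(GnselectError):
    """Weakly-deleterious correction undefined (no common synonymous polymorphisms)."""


class SimulationError(GnselectError):
    """A simulator could not satisfy its sampling contract."""
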
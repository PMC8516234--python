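"""Exception hierarchy for identilab."""


class IdentilabError(Exception):
    """Base class for all identilab errors."""


class ModelError(IdentilabError):
    """Invalid model definition (undeclared/duplicate symbols, bad schema)."""


class UnknownModelError(ModelError):
    """Requested registry model does not exist."""


class SIMEligibilityError(IdentilabError):
    """Model outputs are not a subset of the state variables."""


class UnsupportedTermError(IdentilabError):
    """An additive term cannot be scaled in closed form.

    The scaling-invariance construction is only defined for monomial terms
    (and univariate functions of invariant monomials); anything else is a
    hard error rather than a silent approximation.
    """


class DegenerateSampleError(IdentilabError):
    """All randomized evaluation points were degenerate; try another seed."""


class ReductionError(IdentilabError):
    """Scaling-symmetry model reduction is not possible as requested."""


class InternalInconsistencyError(IdentilabError):
    """Two independent classification routes disagreed (bug trap)."""
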
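"""Exception hierarchy.

All package errors derive from :class:`PhyloExprError` so callers can catch
one base class; subclasses also derive from ``ValueError`` to behave sanely
in generic code.
"""


class PhyloExprError(Exception):
    """Base class for all phyloexpr errors."""


class ParseError(PhyloExprError, ValueError):
    """A file or string could not be parsed (malformed header, bad Newick...)."""


class ValidationError(PhyloExprError, ValueError):
    """Input data violates a documented invariant (negative expression,
    duplicate sample labels, zero-variance column...)."""


class TreeError(PhyloExprError, ValueError):
    """A phylogeny is structurally unusable (missing branch lengths,
    unknown node label, taxon mismatch)."""


class UndefinedDistanceError(PhyloExprError, ValueError):
    """An expression distance is undefined for the given correlation
    (r <= 0 for the constant-optimum estimator, r <= pi for the
    variable-optimum estimator): divergence beyond the resolvable range."""
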
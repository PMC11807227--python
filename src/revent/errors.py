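"""Exception hierarchy.

Every rejected input raises a distinct, named error so that callers (and the
CLI) can report exactly which invariant was violated.
"""


class ReventError(Exception):
    """Base class for all errors raised by this package."""


# -- molecular-graph construction -------------------------------------------

class GraphConstructionError(ReventError):
    """An input could not be turned into a valid molecular graph."""


class EmptyInputError(GraphConstructionError):
    """The edge list / matrix contained no edges."""


class SelfLoopError(GraphConstructionError):
    """An edge joins a vertex to itself."""


class DuplicateEdgeError(GraphConstructionError):
    """The same unordered vertex pair appears twice."""


class DisconnectedGraphError(GraphConstructionError):
    """The resulting graph is not a single connected component."""


class AdjacencyMatrixError(GraphConstructionError):
    """The adjacency matrix is not symmetric, hollow and 0/1."""


class SmilesError(GraphConstructionError):
    """A SMILES string could not be parsed into a molecular graph."""


class MultiFragmentError(SmilesError):
    """The SMILES encodes more than one connected fragment."""


class SmilesAdapterUnavailableError(SmilesError):
    """RDKit is not installed; SMILES input is an optional extra."""


# -- edge weights and indices ------------------------------------------------

class WeightDomainError(ReventError):
    """An edge-weight function is undefined on the given reverse-degree pair
    (e.g. the augmented-Zagreb weight on a (1,1) class)."""


class ContextRequiredError(ReventError):
    """A context-dependent weight (Balaban) was evaluated without (p, q)."""


class UnknownWeightError(ReventError):
    """The weight name is not in the registry."""


# -- entropy ------------------------------------------------------------------

class EntropyDomainError(ReventError):
    """Weights are negative, or the normalizer vanishes."""


# -- parameterized families ---------------------------------------------------

class PartitionError(ReventError):
    """Invalid edge partition or parameterized-partition specification."""


class ParameterRangeError(PartitionError):
    """The repeat parameter s lies below s_min, or a count evaluates negative."""


# -- QSPR ---------------------------------------------------------------------

class RegressionError(ReventError):
    """Invalid regression specification or data."""


class AlignmentError(RegressionError):
    """Descriptor and property tables do not share row labels."""


class EquationUnavailableError(RegressionError):
    """The fitted model has no linear equation form (nonlinear-kernel SVR)."""
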
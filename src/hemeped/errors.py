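"""Exception hierarchy for pedigree validation and analysis."""


class PedigreeError(Exception):
    """Base class for all hemeped errors."""


class ValidationError(PedigreeError):
    """A pedigree violates a structural or phenotypic invariant."""


class CycleError(ValidationError):
    """The parent graph contains a cycle (someone is their own ancestor)."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"parent graph contains a cycle: {' -> '.join(map(str, self.cycle))}")


class RelationError(PedigreeError):
    """A requested relation (e.g. ancestor) does not hold between two members."""


class AmbiguousLineageError(RelationError):
    """An ancestor is reachable through both the father and the mother.

    Arises only in consanguineous (loop-containing) pedigrees.  Callers that
    tabulate lineage-specific counts should emit one pair per first parental
    edge; the error carries both lineages for that purpose.
    """

    def __init__(self, pc_id, ancestor_id):
        self.pc_id = pc_id
        self.ancestor_id = ancestor_id
        self.lineages = ("PA", "MA")
        super().__init__(
            f"{ancestor_id} is an ancestor of {pc_id} through both the father "
            f"and the mother (consanguinity loop)"
        )


class AnalysisError(PedigreeError):
    """A statistical procedure received degenerate input (empty stratum, zero expectation...)."""
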
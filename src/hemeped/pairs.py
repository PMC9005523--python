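"""Proband/affected-relative pairs, parental lineage, and the vertical pair table.

Every affected pedigree member is taken in turn as *proband crude* (Pc).  Its
*affected relatives* (ARs) are the affected members lying 1..``max_generations``
generations before it, reachable along a path with at most
``max_healthy_intermediates`` unaffected members strictly between the two.
Direct ancestors give *vertical* pairs (parent-offspring, grandparent-
grandchild, ...); relatives reached up-then-down through a common ancestor
(uncles, great-aunts, ...) are *oblique* and are excluded from the reported
pair table.  Lineage is paternal (PA) if the first ancestral step from Pc
passes through the father, maternal (MA) if through the mother.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .diagnoses import DiagnosisCode
from .errors import AmbiguousLineageError, AnalysisError, RelationError
from .pedigree import Pedigree, Sex
from .rounding import round_half_up

PA, MA = "PA", "MA"
VERTICAL, OBLIQUE = "vertical", "oblique"


@dataclass(frozen=True)
class PcArPair:
    """One proband-crude / affected-relative relation."""

    pc_id: str
    ar_id: str
    lineage: str                 # PA | MA
    generation_gap: int          # 1 = parent generation, 2 = grandparent, ...
    relation_class: str          # vertical | oblique
    healthy_intermediates: int
    pc_diagnosis: DiagnosisCode
    ar_diagnosis: DiagnosisCode
    pc_sex: Sex
    ar_sex: Sex
    ambiguous: bool = False      # consanguinity loop: AR reachable via both parents


def classify_lineage(p: Pedigree, pc_id: str, ancestor_id: str) -> str:
    """PA/MA affiliation of a strict ancestor of ``pc_id``.

    Raises :class:`RelationError` if not an ancestor, and
    :class:`AmbiguousLineageError` if the ancestor is reachable through both
    parents (consanguinity loop) — callers tabulating counts should then emit
    one pair per first parental edge.
    """
    father = p.father_of(pc_id)
    mother = p.mother_of(pc_id)
    via_pa = father is not None and (
        father.id == ancestor_id or ancestor_id in p.ancestors(father.id))
    via_ma = mother is not None and (
        mother.id == ancestor_id or ancestor_id in p.ancestors(mother.id))
    if via_pa and via_ma:
        raise AmbiguousLineageError(pc_id, ancestor_id)
    if via_pa:
        return PA
    if via_ma:
        return MA
    raise RelationError(f"{ancestor_id!r} is not an ancestor of {pc_id!r}")


def _relative_paths(p: Pedigree, pc_id: str, max_generations: int):
    """All simple up-then-down paths from pc to earlier-generation relatives.

    Yields (node_id, path) for every node reached at elevation >= 1 (at least
    one generation before pc), ascending at most ``max_generations`` steps
    before optionally descending.  ``path`` includes both endpoints.
    """
    # stack entries: (node, ups, downs, descending, path)
    stack = [(pc_id, 0, 0, False, (pc_id,))]
    while stack:
        node, ups, downs, descending, path = stack.pop()
        elevation = ups - downs
        if node != pc_id and elevation >= 1:
            yield node, path, elevation, not descending
        if not descending and ups < max_generations:
            for parent in p.parents_of(node):
                if parent.id not in path:
                    stack.append((parent.id, ups + 1, downs, False, path + (parent.id,)))
        if ups >= 1 and elevation > 1:  # descending below elevation 1 is pointless
            for child in p.children_of(node):
                if child.id not in path:
                    stack.append((child.id, ups, downs + 1, True, path + (child.id,)))


def enumerate_pc_ar(p: Pedigree, max_generations: int = 5,
                    max_healthy_intermediates: int = 5) -> list[PcArPair]:
    """All Pc-AR pairs of the pedigree under the generation and health caps.

    One individual may appear as AR to many Pcs, so the pair count exceeds the
    patient count in deep pedigrees.  In consanguinity loops where an AR is
    reachable through both of Pc's parents, one pair is emitted per first
    parental edge (one PA, one MA), both flagged ``ambiguous``.
    """
    pairs: list[PcArPair] = []
    for pc in p.affected:
        # best cap-satisfying path per (ar, first-edge):
        # prefer vertical, then short, then few healthy intermediates
        best: dict[tuple[str, str], tuple] = {}
        father = p.father_of(pc.id)
        mother = p.mother_of(pc.id)
        for ar_id, path, elevation, vertical in _relative_paths(p, pc.id, max_generations):
            if not p[ar_id].affected:
                continue
            first = path[1]
            if father is not None and first == father.id:
                lineage = PA
            elif mother is not None and first == mother.id:
                lineage = MA
            else:  # single known parent whose record is outside the pedigree
                continue
            healthy = sum(1 for mid in path[1:-1] if not p[mid].affected)
            if healthy > max_healthy_intermediates or elevation > max_generations:
                continue
            key = (ar_id, lineage)
            cand = (0 if vertical else 1, len(path) - 1, healthy, elevation)
            if key not in best or cand < best[key]:
                best[key] = cand
        # ambiguity mirrors classify_lineage: true ancestor through BOTH parents
        fa_anc = ({father.id} | p.ancestors(father.id)) if father else set()
        mo_anc = ({mother.id} | p.ancestors(mother.id)) if mother else set()
        for (ar_id, lineage), (obl, plen, healthy, gap) in sorted(
                best.items(), key=lambda kv: (kv[0][0], kv[0][1])):
            ar = p[ar_id]
            pairs.append(PcArPair(
                pc_id=pc.id, ar_id=ar_id, lineage=lineage,
                generation_gap=gap,
                relation_class=VERTICAL if obl == 0 else OBLIQUE,
                healthy_intermediates=healthy,
                pc_diagnosis=pc.diagnosis, ar_diagnosis=ar.diagnosis,
                pc_sex=pc.sex, ar_sex=ar.sex,
                ambiguous=(ar_id in fa_anc and ar_id in mo_anc),
            ))
    return pairs


def sibling_concordance_pairs(p: Pedigree) -> list[tuple[str, str]]:
    """Horizontal pairs: unordered pairs of affected full siblings.

    Computed for completeness; never part of the vertical pair table.
    """
    out = []
    for sib in p.sibships():
        aff = [m.id for m in sib.members if m.affected]
        out.extend((a, b) for i, a in enumerate(aff) for b in aff[i + 1:])
    return out


# ---------------------------------------------------------------------------
@dataclass
class PairTable:
    """Vertical pairs cross-tabulated by diagnosis class, lineage and sex.

    The *parent side* of a pair is the AR (the earlier-generation member) and
    the *offspring side* is the Pc; ``table`` counts offspring-side members by
    sex within each (parent CLL/nonCLL, offspring CLL/nonCLL, lineage) cell.
    """

    pairs: list[PcArPair]
    table: pd.DataFrame = field(init=False)

    def __post_init__(self):
        rows = [{
            "parent_class": "CLL" if pr.ar_diagnosis.is_cll else "nonCLL",
            "offspring_class": "CLL" if pr.pc_diagnosis.is_cll else "nonCLL",
            "lineage": pr.lineage,
            "offspring_sex": pr.pc_sex.value,
            "parent_sex": pr.ar_sex.value,
            "generation_gap": pr.generation_gap,
        } for pr in self.pairs]
        cols = ["parent_class", "offspring_class", "lineage",
                "offspring_sex", "parent_sex", "generation_gap"]
        self.table = pd.DataFrame(rows, columns=cols)

    def __len__(self) -> int:
        return len(self.pairs)

    def lineage_counts(self) -> dict[str, int]:
        c = self.table["lineage"].value_counts().to_dict()
        return {PA: int(c.get(PA, 0)), MA: int(c.get(MA, 0))}

    def offspring_sex_counts(self, parent_class: str, offspring_class: str,
                             lineage: str) -> tuple[int, int, int]:
        """(total, male, female) offspring-side counts of one stratum."""
        sub = self.table[(self.table.parent_class == parent_class)
                         & (self.table.offspring_class == offspring_class)
                         & (self.table.lineage == lineage)]
        male = int((sub.offspring_sex == "male").sum())
        female = int((sub.offspring_sex == "female").sum())
        return len(sub), male, female

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "pc_id": pr.pc_id, "ar_id": pr.ar_id, "lineage": pr.lineage,
            "generation_gap": pr.generation_gap,
            "healthy_intermediates": pr.healthy_intermediates,
            "relation_class": pr.relation_class,
            "pc_dx": pr.pc_diagnosis.label, "ar_dx": pr.ar_diagnosis.label,
        } for pr in self.pairs])


def extract_vertical_pairs(pairs: Iterable[PcArPair], max_gap: int = 2) -> PairTable:
    """Keep strictly vertical pairs with generation gap <= ``max_gap``.

    Oblique combinations (uncle/aunt-nephew and the like) are dropped, matching
    the reported parent-offspring and grandparent-grandchild rows.
    """
    kept = [pr for pr in pairs
            if pr.relation_class == VERTICAL and pr.generation_gap <= max_gap]
    return PairTable(kept)


def pair_percentages(t: PairTable) -> pd.DataFrame:
    """Percent male/female of offspring-side members per stratum and lineage.

    Percentages are rounded half-up to integers as in the reported tables;
    empty strata yield NaN (undefined), never 0.
    """
    if len(t) == 0:
        raise AnalysisError("empty pair table")
    rows = []
    for parent_class in ("CLL", "nonCLL"):
        for offspring_class in ("CLL", "nonCLL"):
            for lineage in (PA, MA):
                total, male, female = t.offspring_sex_counts(
                    parent_class, offspring_class, lineage)
                rows.append({
                    "parent_class": parent_class,
                    "offspring_class": offspring_class,
                    "lineage": lineage,
                    "n": total,
                    "pct_male": round_half_up(100 * male / total) if total else float("nan"),
                    "pct_female": round_half_up(100 * female / total) if total else float("nan"),
                })
    return pd.DataFrame(rows).set_index(["parent_class", "offspring_class", "lineage"])


def lineage_annotation(pairs: Iterable[PcArPair]) -> dict[str, set[str]]:
    """For each Pc, the set of lineages through which it has any vertical AR."""
    out: dict[str, set[str]] = {}
    for pr in pairs:
        if pr.relation_class == VERTICAL:
            out.setdefault(pr.pc_id, set()).add(pr.lineage)
    return out
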
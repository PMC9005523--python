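"""Pedigree data model: individuals, validated parent graphs, sibships.

A :class:`Pedigree` is a collection of :class:`Individual` records whose
father/mother references form an acyclic graph.  Members without any parent
reference inside the pedigree are founders.  A *sibship* is the set of full
siblings (same father AND same mother), ordered by birth rank.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional

import networkx as nx

from .diagnoses import DiagnosisCode
from .errors import CycleError, ValidationError

logger = logging.getLogger(__name__)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class KindredMode(str, enum.Enum):
    NUCLEAR = "nuclear"   # continental multi-family material
    ENDEMIC = "endemic"   # one deep consanguineous family


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``birth_order`` is the 1-based rank within the full sibship, ascending by
    birth.  ``affected`` individuals must carry a diagnosis; unaffected ones
    must not.
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.MALE
    birth_order: Optional[int] = None
    birth_year: Optional[int] = None
    affected: bool = False
    diagnosis: Optional[DiagnosisCode] = None
    onset_age: Optional[float] = None

    def __post_init__(self):
        if self.affected and self.diagnosis is None:
            raise ValidationError(f"affected individual {self.id!r} has no diagnosis")
        if not self.affected and self.diagnosis is not None:
            raise ValidationError(f"unaffected individual {self.id!r} carries a diagnosis")
        if self.birth_order is not None and self.birth_order < 1:
            raise ValidationError(f"individual {self.id!r}: birth_order must be >= 1")
        if self.onset_age is not None and self.onset_age < 0:
            raise ValidationError(f"individual {self.id!r}: negative onset_age")


@dataclass(frozen=True)
class Sibship:
    """Full siblings (same father and mother), ordered by birth rank."""

    father_id: Optional[str]
    mother_id: Optional[str]
    members: tuple[Individual, ...]  # ascending birth_order

    @property
    def size(self) -> int:
        return len(self.members)

    def affected_ranks(self, predicate=None) -> list[int]:
        """Birth ranks (1..size by position) of affected members.

        Ranks are positional within the sibship so that sibships with sparse
        stored birth orders still rank 1..s.  ``predicate`` optionally narrows
        which affected members count (e.g. male CLL only).
        """
        pred = predicate if predicate is not None else (lambda ind: True)
        return [i + 1 for i, ind in enumerate(self.members) if ind.affected and pred(ind)]


class Pedigree:
    """Validated collection of individuals forming an acyclic parent graph."""

    def __init__(self, members: Iterable[Individual], family_id: str = "F1",
                 kindred_mode: KindredMode = KindredMode.NUCLEAR):
        members = list(members)
        self.family_id = family_id
        self.kindred_mode = KindredMode(kindred_mode)
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self._members:
                raise ValidationError(f"duplicate id: {ind.id!r}")
            self._members[ind.id] = ind
        self._graph = nx.DiGraph()  # edge child -> parent
        self._graph.add_nodes_from(self._members)
        for ind in members:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in self._members:
                    self._graph.add_edge(ind.id, pid)
        self._validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._members

    def __getitem__(self, member_id: str) -> Individual:
        return self._members[member_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return (self.family_id == other.family_id
                and self.kindred_mode == other.kindred_mode
                and self._members == other._members)

    @property
    def members(self) -> list[Individual]:
        return list(self._members.values())

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self if m.affected]

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = [u for u, _ in nx.find_cycle(self._graph)]
            raise CycleError(cycle)
        for ind in self:
            if ind.father_id is not None and ind.father_id in self._members:
                father = self._members[ind.father_id]
                if father.sex is not Sex.MALE:
                    raise ValidationError(
                        f"father {father.id!r} of {ind.id!r} is not male")
            if ind.mother_id is not None and ind.mother_id in self._members:
                mother = self._members[ind.mother_id]
                if mother.sex is not Sex.FEMALE:
                    raise ValidationError(
                        f"mother {mother.id!r} of {ind.id!r} is not female")
        missing = [m.id for m in self if m.affected and m.diagnosis is None]
        if missing:  # unreachable given Individual's own check; defense in depth
            raise ValidationError(f"affected without diagnosis: {missing}")
        for sib in self.sibships():
            orders = [m.birth_order for m in sib.members]
            if any(o is None for o in orders):
                continue  # ranks may be derived later from birth_year
            if sorted(orders) != list(range(1, sib.size + 1)):
                raise ValidationError(
                    "birth orders within full sibship "
                    f"({sib.father_id!r}, {sib.mother_id!r}) are {sorted(orders)}, "
                    f"expected 1..{sib.size}")

    # -- traversal ----------------------------------------------------------
    def father_of(self, member_id: str) -> Optional[Individual]:
        fid = self._members[member_id].father_id
        return self._members.get(fid) if fid is not None else None

    def mother_of(self, member_id: str) -> Optional[Individual]:
        mid = self._members[member_id].mother_id
        return self._members.get(mid) if mid is not None else None

    def parents_of(self, member_id: str) -> list[Individual]:
        return [p for p in (self.father_of(member_id), self.mother_of(member_id))
                if p is not None]

    def children_of(self, member_id: str) -> list[Individual]:
        return [self._members[c] for c in self._graph.predecessors(member_id)]

    def is_founder(self, member_id: str) -> bool:
        return not self.parents_of(member_id)

    def ancestors(self, member_id: str, max_generations: int | None = None) -> set[str]:
        """Ids of strict ancestors, optionally within a generation cap."""
        out: set[str] = set()
        frontier = [member_id]
        gen = 0
        while frontier and (max_generations is None or gen < max_generations):
            gen += 1
            nxt = []
            for mid in frontier:
                for p in self.parents_of(mid):
                    if p.id not in out:
                        out.add(p.id)
                        nxt.append(p.id)
            frontier = nxt
        return out

    def depth(self, member_id: str) -> int:
        """Generation stratum: longest parent-path from any founder down to the member."""
        return self._depths()[member_id]

    def _depths(self) -> dict[str, int]:
        if not hasattr(self, "_depth_cache"):
            depths: dict[str, int] = {}
            for mid in nx.topological_sort(self._graph.reverse(copy=False)):
                parents = [p.id for p in self.parents_of(mid)]
                depths[mid] = 0 if not parents else 1 + max(depths[p] for p in parents)
            self._depth_cache = depths
        return self._depth_cache

    # -- sibships -----------------------------------------------------------
    def sibships(self) -> list[Sibship]:
        """Partition of the non-founders into full sibships.

        Members are ordered by stored birth_order; where absent, by birth
        year then id (ties broken lexicographically).
        """
        groups: dict[tuple, list[Individual]] = {}
        for ind in self:
            if ind.father_id is None and ind.mother_id is None:
                continue
            groups.setdefault((ind.father_id, ind.mother_id), []).append(ind)
        out = []
        for (fid, mid), inds in groups.items():
            inds.sort(key=lambda i: (i.birth_order if i.birth_order is not None else 10 ** 9,
                                     i.birth_year if i.birth_year is not None else 10 ** 9,
                                     str(i.id)))
            out.append(Sibship(father_id=fid, mother_id=mid, members=tuple(inds)))
        out.sort(key=lambda s: (str(s.father_id), str(s.mother_id)))
        return out

    def with_derived_birth_orders(self) -> "Pedigree":
        """Fill missing birth orders from birth years (ties broken by id).

        Used by the readers; logs a warning whenever a rank had to be derived.
        """
        updates: dict[str, int] = {}
        for sib in self.sibships():
            if any(m.birth_order is not None for m in sib.members):
                continue  # stored ranks win; mixed sibships are left alone
            if not any(m.birth_year is not None for m in sib.members):
                continue  # nothing to derive from

            ordered = sorted(sib.members,
                             key=lambda i: (i.birth_year if i.birth_year is not None else 10 ** 9,
                                            str(i.id)))
            logger.warning(
                "deriving birth order for sibship (%s, %s) from birth years; "
                "ties broken by id", sib.father_id, sib.mother_id)
            for rank, m in enumerate(ordered, start=1):
                updates[m.id] = rank
        if not updates:
            return self
        new_members = [replace(m, birth_order=updates.get(m.id, m.birth_order))
                       for m in self]
        return Pedigree(new_members, family_id=self.family_id,
                        kindred_mode=self.kindred_mode)
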
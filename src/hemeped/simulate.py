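"""Synthetic pedigree generation under a sex-of-parent-dependent model.

The generator reproduces the statistical structure the analyses assume
without claiming genetic realism: susceptibility is carried by a two-state
carrier process (carrier / non-carrier) transmitted from parent to child with
probabilities that may depend on the sex of the parent and the child, rather
than by explicit allele-level imprinting — pair statistics constrain only
these transmission weights.  Carriers become affected with a penetrance that
may be enhanced multiplicatively (on the odds scale) per birth rank for a
configurable scope, by default male offspring of paternal carrier lines with
CLL — the single positive birth-order finding the analyses target.
Anticipation enters as a fixed onset-age decrement per generation, with
seed-stable normal noise around the configured median.

``maternal_drive`` shifts segregation toward maternal lines: in nuclear mode
it is the probability that the founder carrier of a family is the mother (so
the maternal fraction of affected vertical pairs equals the drive in
expectation); in endemic mode it tilts every per-child transmission by
``2*drive`` through mothers and ``2*(1-drive)`` through fathers.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .diagnoses import DiagnosisCode
from .fixtures import TABLE1
from .pedigree import Individual, KindredMode, Pedigree, Sex

AFFECTED, SILENT, NONCARRIER = "affected-susceptible", "silent-carrier", "non-carrier"


@dataclass
class TransmissionModel:
    """Carrier transmission and penetrance weights.

    ``transmit_prob`` maps (parent_sex, child_sex) to the per-child
    probability that a carrier parent passes the susceptibility on;
    ``penetrance`` is the probability that a carrier is affected (scalar, or
    a map from (sex, diagnosis group) to probability).
    """

    transmit_prob: dict = field(default_factory=lambda: {
        (ps, cs): 0.5 for ps in Sex for cs in Sex})
    penetrance: object = 0.6

    def transmit(self, parent_sex: Sex, child_sex: Sex) -> float:
        return float(self.transmit_prob[(parent_sex, child_sex)])

    def pen(self, sex: Sex, group) -> float:
        if isinstance(self.penetrance, dict):
            return float(self.penetrance[(sex, group)])
        return float(self.penetrance)

    def validate(self):
        for v in self.transmit_prob.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("transmission probability outside [0, 1]")
        pens = (self.penetrance.values() if isinstance(self.penetrance, dict)
                else [self.penetrance])
        for v in pens:
            if not 0.0 <= v <= 1.0:
                raise ValueError("penetrance outside [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the familial material the analyses describe: 112 nuclear
    families, mean sibship size (parity) 2.7, maternal drive 0.64 (the
    observed maternal pair fraction), and a null birth-order/anticipation
    setting (``birth_order_enhancement=1``, ``anticipation_delta=0``) since
    the source material quantifies neither effect size.
    """

    mode: KindredMode = KindredMode.NUCLEAR
    seed: int = 0
    n_families: int = 112            # nuclear mode
    n_generations: int = 5           # endemic mode
    n_founder_couples: int = 4       # endemic mode
    parity: float = 2.7              # sibship size = 1 + Poisson(parity - 1)
    diagnosis_mixture: Optional[dict] = None  # {label: (total, male, female)}
    maternal_drive: float = 0.64
    birth_order_enhancement: float = 1.0      # beta >= 1, odds multiplier per rank
    boe_scope: tuple = (Sex.MALE, "PA", "CLL")
    anticipation_delta: float = 0.0           # onset decrement per generation, years
    onset_median: float = 67.0
    onset_spread: float = 8.0                 # sd of normal onset noise, years
    transmission: TransmissionModel = field(default_factory=TransmissionModel)
    loop_rate: float = 0.25          # endemic cousin-marriage probability
    min_affected_per_family: int = 2  # nuclear ascertainment

    def validate(self):
        self.mode = KindredMode(self.mode)
        if not 0.0 <= self.maternal_drive <= 1.0:
            raise ValueError("maternal_drive must be in [0, 1]")
        if self.birth_order_enhancement < 1.0:
            raise ValueError("birth_order_enhancement must be >= 1")
        if self.parity < 1.0:
            raise ValueError("parity must be >= 1")
        if self.mode is KindredMode.NUCLEAR and self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.mode is KindredMode.ENDEMIC and self.n_generations < 2:
            raise ValueError("endemic mode needs >= 2 generations")
        mixture = self.resolved_mixture()
        if not mixture or all(t == 0 for t, _, _ in mixture.values()):
            raise ValueError("empty diagnosis mixture")
        self.transmission.validate()

    def resolved_mixture(self) -> dict:
        if self.diagnosis_mixture is not None:
            return self.diagnosis_mixture
        material = "continental" if self.mode is KindredMode.NUCLEAR else "faroese"
        out = {}
        for group in ("LPD", "MPD", "OTHER"):
            out.update(TABLE1[material][group])
        return out


@dataclass
class SimulationResult:
    """Pedigree plus the generator's ground truth."""

    pedigree: Pedigree
    carrier_state: dict         # id -> affected-susceptible | silent-carrier | non-carrier
    true_lineage: dict          # id -> {"PA"} / {"MA"}: side of the inherited susceptibility
    families: list              # nuclear: member-id lists per family
    mean_cases_per_family: float
    n_families_attempted: int


class _Mixture:
    def __init__(self, mixture: dict, rng):
        self.rng = rng
        self.labels = sorted(mixture)
        m = np.array([mixture[k][1] for k in self.labels], dtype=float)
        f = np.array([mixture[k][2] for k in self.labels], dtype=float)
        self.p = {Sex.MALE: m / m.sum() if m.sum() else None,
                  Sex.FEMALE: f / f.sum() if f.sum() else None}

    def draw(self, sex: Sex) -> DiagnosisCode:
        p = self.p[sex]
        if p is None:  # no case of this sex in the mixture: fall back to totals
            p = (self.p[Sex.MALE] if self.p[Sex.MALE] is not None
                 else self.p[Sex.FEMALE])
        label = self.labels[int(self.rng.choice(len(self.labels), p=p))]
        return DiagnosisCode.from_label(label)


def _apply_boe(pen: float, beta: float, rank: int) -> float:
    if beta == 1.0 or rank == 1 or pen in (0.0, 1.0):
        return pen
    odds = pen / (1.0 - pen) * beta ** (rank - 1)
    return odds / (1.0 + odds)


def generate_pedigree(cfg: SimulationConfig) -> SimulationResult:
    """Generate a pedigree with ground-truth carrier and lineage annotations.

    Reproducible: the same config (including seed) yields an identical
    result.  Nuclear mode emits independent two-generation families each
    ascertained to contain at least ``min_affected_per_family`` affected
    members; endemic mode grows one connected multi-generation pedigree with
    preferential within-pedigree partner choice creating consanguinity loops.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.mode is KindredMode.NUCLEAR:
        return _generate_nuclear(cfg, rng)
    return _generate_endemic(cfg, rng)


def _sibship_size(cfg, rng) -> int:
    return 1 + int(rng.poisson(cfg.parity - 1.0))


def _onset(cfg, rng, depth: int) -> float:
    raw = cfg.onset_median - depth * cfg.anticipation_delta \
        + rng.normal(0.0, cfg.onset_spread)
    return float(max(raw, 1.0))


def _generate_nuclear(cfg: SimulationConfig, rng) -> SimulationResult:
    mixture = _Mixture(cfg.resolved_mixture(), rng)
    tm = cfg.transmission
    members: list[Individual] = []
    carrier_state: dict[str, str] = {}
    true_lineage: dict[str, set] = {}
    families: list[list[str]] = []
    attempts = 0
    n_cases = 0
    fam = 0
    while fam < cfg.n_families:
        attempts += 1
        carrier_is_mother = bool(rng.random() < cfg.maternal_drive)
        lineage = "MA" if carrier_is_mother else "PA"
        carrier_sex = Sex.FEMALE if carrier_is_mother else Sex.MALE
        fid = f"f{fam:05d}"
        fam_members: list[Individual] = []
        fam_state: dict[str, str] = {}
        fam_lineage: dict[str, set] = {}

        def build_parent(pid, sex):
            is_carrier = sex is carrier_sex
            affected = False
            dx = onset = None
            if is_carrier:
                dx_cand = mixture.draw(sex)
                if rng.random() < tm.pen(sex, dx_cand.lineage_group):
                    affected, dx = True, dx_cand
                    onset = _onset(cfg, rng, 0)
            fam_state[pid] = (AFFECTED if affected else SILENT) if is_carrier else NONCARRIER
            fam_members.append(Individual(
                id=pid, sex=sex, affected=affected, diagnosis=dx,
                onset_age=onset, birth_year=1900))
            return is_carrier

        father_id, mother_id = f"{fid}-p1", f"{fid}-p2"
        build_parent(father_id, Sex.MALE)
        build_parent(mother_id, Sex.FEMALE)
        size = _sibship_size(cfg, rng)
        for rank in range(1, size + 1):
            cid = f"{fid}-c{rank}"
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            is_carrier = bool(rng.random() < tm.transmit(carrier_sex, sex))
            affected = False
            dx = onset = None
            if is_carrier:
                fam_lineage[cid] = {lineage}
                dx_cand = mixture.draw(sex)
                pen = tm.pen(sex, dx_cand.lineage_group)
                if (sex, lineage, dx_cand.label) == cfg.boe_scope:
                    pen = _apply_boe(pen, cfg.birth_order_enhancement, rank)
                if rng.random() < pen:
                    affected, dx = True, dx_cand
                    onset = _onset(cfg, rng, 1)
            fam_state[cid] = (AFFECTED if affected else SILENT) if is_carrier else NONCARRIER
            fam_members.append(Individual(
                id=cid, father_id=father_id, mother_id=mother_id, sex=sex,
                birth_order=rank, birth_year=1930 + rank,
                affected=affected, diagnosis=dx, onset_age=onset))
        n_aff = sum(m.affected for m in fam_members)
        if n_aff < cfg.min_affected_per_family:
            continue  # ascertainment: families enter the material via >= 2 cases
        members.extend(fam_members)
        carrier_state.update(fam_state)
        true_lineage.update(fam_lineage)
        families.append([m.id for m in fam_members])
        n_cases += n_aff
        fam += 1
    ped = Pedigree(members, family_id="sim-nuclear", kindred_mode=KindredMode.NUCLEAR)
    return SimulationResult(ped, carrier_state, true_lineage, families,
                            n_cases / cfg.n_families, attempts)


def _generate_endemic(cfg: SimulationConfig, rng) -> SimulationResult:
    mixture = _Mixture(cfg.resolved_mixture(), rng)
    tm = cfg.transmission
    drive = cfg.maternal_drive
    members: dict[str, Individual] = {}
    carrier_state: dict[str, str] = {}
    true_lineage: dict[str, set] = {}
    counter = itertools.count()

    def tilted(parent_sex: Sex, child_sex: Sex) -> float:
        base = tm.transmit(parent_sex, child_sex)
        tilt = 2.0 * drive if parent_sex is Sex.FEMALE else 2.0 * (1.0 - drive)
        return float(min(1.0, max(0.0, base * tilt)))

    def make(sex, depth, father=None, mother=None, rank=None, carrier=False,
             lineage: Optional[set] = None) -> str:
        mid = f"e{next(counter):05d}"
        affected = False
        dx = onset = None
        if carrier:
            dx_cand = mixture.draw(sex)
            pen = tm.pen(sex, dx_cand.lineage_group)
            if rank is not None and lineage and cfg.boe_scope[1] in lineage \
                    and (sex, dx_cand.label) == (cfg.boe_scope[0], cfg.boe_scope[2]):
                pen = _apply_boe(pen, cfg.birth_order_enhancement, rank)
            if rng.random() < pen:
                affected, dx = True, dx_cand
                onset = _onset(cfg, rng, depth)
        members[mid] = Individual(
            id=mid, father_id=father, mother_id=mother, sex=sex,
            birth_order=rank, birth_year=1880 + 25 * depth + (rank or 0),
            affected=affected, diagnosis=dx, onset_age=onset)
        carrier_state[mid] = (AFFECTED if affected else SILENT) if carrier else NONCARRIER
        if lineage:
            true_lineage[mid] = set(lineage)
        return mid

    couples: list[tuple[str, str]] = []
    for k in range(cfg.n_founder_couples):
        # one carrier per founder couple, alternating sex, so the endemic
        # susceptibility enters through several deep lines as in an old isolate
        husband = make(Sex.MALE, 0, carrier=(k % 2 == 0))
        wife = make(Sex.FEMALE, 0, carrier=(k % 2 == 1))
        couples.append((husband, wife))
    for depth in range(1, cfg.n_generations):
        children: list[str] = []
        for father, mother in couples:
            size = _sibship_size(cfg, rng)
            for rank in range(1, size + 1):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                carrier = False
                lineage: set = set()
                for parent, side in ((members[father], "PA"), (members[mother], "MA")):
                    if carrier_state[parent.id] != NONCARRIER \
                            and rng.random() < tilted(parent.sex, sex):
                        carrier = True
                        lineage.add(side)
                children.append(make(sex, depth, father=father, mother=mother,
                                     rank=rank, carrier=carrier,
                                     lineage=lineage or None))
        if depth == cfg.n_generations - 1:
            break
        couples = _marry(children, members, cfg, rng, make, depth)
    ped = Pedigree(members.values(), family_id="sim-endemic",
                   kindred_mode=KindredMode.ENDEMIC)
    n_aff = len(ped.affected)
    return SimulationResult(ped, carrier_state, true_lineage, [list(members)],
                            float(n_aff), 1)


def _marry(children, members, cfg, rng, make, depth):
    males = [c for c in children if members[c].sex is Sex.MALE]
    females = [c for c in children if members[c].sex is Sex.FEMALE]
    rng.shuffle(males)
    rng.shuffle(females)
    taken: set[str] = set()
    couples = []
    for m in males:
        mate = None
        if rng.random() < cfg.loop_rate:  # preferential within-pedigree choice
            for f in females:
                if f in taken:
                    continue
                if (members[m].father_id, members[m].mother_id) != \
                        (members[f].father_id, members[f].mother_id):
                    mate = f
                    break
        if mate is None:
            mate = make(Sex.FEMALE, depth)  # in-migrating founder spouse
        taken.add(mate)
        couples.append((m, mate))
    for f in females:
        if f not in taken:
            couples.append((make(Sex.MALE, depth), f))
    return couples
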
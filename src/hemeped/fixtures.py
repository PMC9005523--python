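"""Reference count tables and the synthetic fixture pedigrees built from them.

The underlying registry pedigrees of the familial-MBD study material are not
publicly deposited, so the package carries the *printed* summary counts —
diagnosis prevalences for the continental (Norwegian/Danish, 112 nuclear
families) and the Faroese (one deep endemic family) materials, the vertical
pair table, and the observed-vs-expected co/contravariation rows — as
structured data, and builds synthetic pedigrees that realize those counts
exactly.  Every pedigree returned here is synthetic: member ids, family
structure and onset offsets are constructed, only the marginal counts and
medians are real.
"""
from __future__ import annotations

from typing import Iterator

from .diagnoses import DiagnosisCode
from .pedigree import Individual, KindredMode, Pedigree, Sex

#: AR pool related to proband HL in the endemic material: 121 AR LPD (68 m, 53 f).
AR_POOL_HL_LPD = (121, 68, 53)

#: Diagnosis counts {material: {group: {label: (total, males, females)}}}.
TABLE1 = {
    "continental": {
        "LPD": {
            "CLL": (181, 98, 83), "ALL": (4, 2, 2), "other-leukemia": (14, 7, 7),
            "MM": (10, 6, 4), "MGUS": (2, 1, 1), "HL": (11, 8, 3),
            "DLBCL": (16, 9, 7), "FL": (19, 13, 6), "other-lymphoma": (19, 11, 8),
        },
        "MPD": {"AML": (9, 6, 3), "CML": (3, 1, 2), "other-MPD": (12, 6, 6)},
        "OTHER": {"L-NOS": (1, 1, 0)},
        "onset_median": {"LPD": 67.0, "MPD": 63.0, "OTHER": 67.0},
        "n_families": 112,
    },
    "faroese": {
        "LPD": {
            "CLL": (50, 29, 21), "ALL": (16, 10, 6), "other-leukemia": (5, 3, 2),
            "MM": (50, 31, 19), "HL": (19, 12, 7), "DLBCL": (34, 21, 13),
            "FL": (14, 9, 5), "other-lymphoma": (31, 16, 15),
        },
        "MPD": {"AML": (44, 28, 16), "CML": (14, 9, 5), "other-MPD": (29, 15, 14)},
        "OTHER": {"L-NOS": (7, 2, 5), "MH": (2, 0, 2)},
        "onset_median": {"LPD": 61.0, "MPD": 54.0, "OTHER": 61.0},
        "n_families": 1,
    },
}

#: Vertical pair rows: (parent_class, offspring_class, lineage, level,
#: parent-side (total, m, f), offspring-side (total, m, f)).
#: parent_class describes the AR (earlier generation), offspring_class the Pc.
TABLE2 = [
    ("CLL", "CLL", "PA", "child", (16, 16, 0), (16, 11, 5)),
    ("CLL", "CLL", "MA", "child", (26, 0, 26), (26, 11, 15)),
    ("CLL", "CLL", "PA", "grandchild", (1, 1, 0), (1, 1, 0)),
    ("CLL", "CLL", "MA", "grandchild", (13, 7, 6), (13, 8, 5)),
    ("CLL", "nonCLL", "PA", "child", (7, 7, 0), (7, 2, 5)),
    ("CLL", "nonCLL", "MA", "child", (11, 0, 11), (11, 5, 6)),
    ("CLL", "nonCLL", "MA", "grandchild", (6, 2, 4), (6, 2, 4)),
    ("nonCLL", "CLL", "PA", "child", (9, 9, 0), (9, 3, 6)),
    ("nonCLL", "CLL", "MA", "child", (9, 0, 9), (9, 5, 4)),
    ("nonCLL", "CLL", "PA", "grandchild", (8, 8, 0), (8, 4, 4)),
    ("nonCLL", "CLL", "MA", "grandchild", (7, 4, 3), (7, 5, 2)),
    ("nonCLL", "nonCLL", "PA", "child", (6, 6, 0), (6, 4, 2)),
    ("nonCLL", "nonCLL", "MA", "child", (5, 0, 5), (5, 3, 2)),
    ("nonCLL", "nonCLL", "PA", "grandchild", (3, 3, 0), (3, 3, 0)),
    ("nonCLL", "nonCLL", "MA", "grandchild", (11, 5, 6), (11, 2, 9)),
]

#: Observed-vs-expected rows of the endemic material:
#: (pc_label, pc_icd10_as_printed, ar_label, OBS (t, m, f), EXP (t, m, f),
#:  printed_call, printed_significance).  The DLBCL proband code is printed
#: C88.3 in the source table although C83.3 elsewhere; kept verbatim.
TABLE3 = [
    ("HL", "C81", "HL", (17, 10, 7), (11, 7, 4), "covariation", "P < 0.05"),
    ("FL", "C82", "MM", (22, 14, 8), (15, 9, 6), "covariation", "P < 0.05"),
    ("DLBCL", "C88.3", "DLBCL", (37, 14, 23), (28, 17, 11), "covariation", "P < 0.001"),
    ("DLBCL", "C88.3", "CLL", (33, 11, 22), (41, 24, 17), "contravariation", "P < 0.01"),
    ("NHL-NOS", "C85.9", "HL", (19, 12, 7), (12, 8, 4), "covariation", "P < 0.01"),
    ("MM", "C90", "FL", (27, 15, 12), (20, 13, 7), "covariation", "P < 0.05"),
    ("MM", "C90", "MM", (88, 50, 38), (71, 44, 27), "covariation", "P < 0.01"),
    ("MM", "C90", "CLL", (58, 40, 18), (71, 41, 30), "contravariation", "P < .05"),
    ("MM", "C90", "ALL", (27, 11, 16), (23, 14, 9), "covariation", "P < 0.05"),
    ("MM", "C90", "CML", (33, 18, 15), (22, 14, 8), "covariation", "P < 0.01"),
    ("MM", "C90", "MF", (29, 16, 13), (12, 6, 6), "covariation", "P < 0.001"),
    ("AML", "C92.0", "AML", (78, 45, 33), (60, 38, 22), "covariation", "P < 0.01"),
    ("AML", "C92.0", "DLBCL", (47, 25, 22), (33, 20, 13), "covariation", "P < 0.01"),
    ("AML", "C92.0", "CLL", (28, 17, 11), (48, 28, 20), "contravariation", "P < 0.001"),
    ("AML", "C92.0", "MM", (73, 41, 32), (48, 30, 18), "covariation", "P < 0.05"),
    ("CML", "C92.1", "AML", (37, 22, 15), (27, 17, 10), "covariation", "P < 0.05"),
]


def fixture_tables() -> dict:
    """The printed reference tables as structured data."""
    return {"table1": TABLE1, "table2": list(TABLE2), "table3": list(TABLE3),
            "ar_pool_hl_lpd": AR_POOL_HL_LPD}


# ---------------------------------------------------------------------------
def _symmetric_offsets(n: int) -> list[float]:
    """n offsets, symmetric about 0 so the median is preserved exactly."""
    out = []
    for i in range(n // 2):
        step = 1 + i % 15
        out.extend([step, -step])
    if n % 2:
        out.append(0.0)
    return [float(x) for x in out]


def _case_specs(material: str) -> list[tuple[str, Sex, str]]:
    """Flat, deterministic list of (label, sex, group) for every printed case."""
    specs = []
    t1 = TABLE1[material]
    for group in ("LPD", "MPD", "OTHER"):
        for label, (total, male, female) in t1[group].items():
            specs.extend([(label, Sex.MALE, group)] * male)
            specs.extend([(label, Sex.FEMALE, group)] * female)
            assert male + female == total
    return specs


def _onsets_by_group(material: str, specs) -> Iterator[float]:
    t1 = TABLE1[material]
    per_group: dict[str, list[float]] = {}
    for group in ("LPD", "MPD", "OTHER"):
        n = sum(1 for s in specs if s[2] == group)
        med = t1["onset_median"][group]
        per_group[group] = [med + d for d in _symmetric_offsets(n)]
    for label, sex, group in specs:
        yield per_group[group].pop()


def continental_pedigree() -> Pedigree:
    """Synthetic 112-family nuclear material realizing the continental counts.

    301 affected children distributed over 112 families (77 of three cases,
    35 of two — 2.69 cases per family) under unaffected founder couples;
    diagnosis-by-sex counts and the group onset medians match the printed
    table exactly.  Structure and ids are synthetic.
    """
    specs = _case_specs("continental")
    onsets = list(_onsets_by_group("continental", specs))
    assert len(specs) == 301
    # interleave groups so each family mixes diagnoses deterministically
    order = sorted(range(len(specs)), key=lambda i: (i % 112, i))
    members: list[Individual] = []
    sizes = [3] * 77 + [2] * 35
    cursor = 0
    for fam, size in enumerate(sizes):
        fid = f"c{fam:03d}"
        members.append(Individual(id=f"{fid}-f", sex=Sex.MALE))
        members.append(Individual(id=f"{fid}-m", sex=Sex.FEMALE))
        for rank in range(1, size + 1):
            idx = order[cursor]
            label, sex, _ = specs[idx]
            members.append(Individual(
                id=f"{fid}-c{rank}", father_id=f"{fid}-f", mother_id=f"{fid}-m",
                sex=sex, birth_order=rank, affected=True,
                diagnosis=DiagnosisCode.from_label(label),
                onset_age=onsets[idx]))
            cursor += 1
    assert cursor == 301
    return Pedigree(members, family_id="continental", kindred_mode=KindredMode.NUCLEAR)


def faroese_pedigree() -> Pedigree:
    """Synthetic deep endemic pedigree realizing the Faroese counts.

    Six generations descending from one founder couple (three children per
    couple, in-marrying spouses, one deliberate cousin marriage creating a
    consanguinity loop); the 315 printed cases (219 LPD, 87 MPD, 9 other) are
    assigned to members round-robin across generations so affected relatives
    are separated by healthy connectors.  Diagnosis-by-sex counts and group
    onset medians match the printed table exactly; everything else is
    synthetic.
    """
    members: dict[str, Individual] = {}

    def add(ind: Individual):
        members[ind.id] = ind

    add(Individual(id="g0-1", sex=Sex.MALE))
    add(Individual(id="g0-2", sex=Sex.FEMALE))
    couples = [("g0-1", "g0-2")]
    generation_of: dict[str, int] = {"g0-1": 0, "g0-2": 0}
    n_children = 3
    for g in range(1, 6):
        new_couples = []
        child_idx = 0
        kids_this_gen: list[str] = []
        for (fid, mid) in couples:
            for rank in range(1, n_children + 1):
                sex = Sex.MALE if rank % 2 == 1 else Sex.FEMALE
                cid = f"g{g}-{child_idx:04d}"
                add(Individual(id=cid, father_id=fid, mother_id=mid, sex=sex,
                               birth_order=rank))
                generation_of[cid] = g
                kids_this_gen.append(cid)
                child_idx += 1
        if g == 5:
            break
        # one cousin marriage per generation from g>=2 creates loops;
        # everyone else marries an in-migrating founder spouse
        married: set[str] = set()
        if g >= 2:
            males = [k for k in kids_this_gen if members[k].sex is Sex.MALE]
            females = [k for k in kids_this_gen if members[k].sex is Sex.FEMALE]
            for a in males:
                mate = next((b for b in females
                             if b not in married
                             and members[a].father_id != members[b].father_id), None)
                if mate is not None:
                    new_couples.append((a, mate))
                    married.update((a, mate))
                    break
        for k in kids_this_gen:
            if k in married:
                continue
            ind = members[k]
            spouse_id = f"s{g}-{k}"
            spouse_sex = Sex.FEMALE if ind.sex is Sex.MALE else Sex.MALE
            add(Individual(id=spouse_id, sex=spouse_sex))
            generation_of[spouse_id] = g
            couple = (k, spouse_id) if ind.sex is Sex.MALE else (spouse_id, k)
            new_couples.append(couple)
        couples = new_couples

    # assign the 315 printed cases round-robin across generations
    specs = _case_specs("faroese")
    onsets = list(_onsets_by_group("faroese", specs))
    assert len(specs) == 315
    by_sex_gen: dict[Sex, dict[int, list[str]]] = {Sex.MALE: {}, Sex.FEMALE: {}}
    for mid, ind in members.items():
        by_sex_gen[ind.sex].setdefault(generation_of[mid], []).append(mid)
    for sex in by_sex_gen:
        for g in by_sex_gen[sex]:
            by_sex_gen[sex][g].sort()
    gen_cycle = {Sex.MALE: 0, Sex.FEMALE: 0}
    final: dict[str, Individual] = dict(members)
    for idx, (label, sex, group) in enumerate(specs):
        pools = by_sex_gen[sex]
        gens = sorted(g for g in pools if pools[g])
        if not gens:
            raise RuntimeError("fixture construction ran out of members")
        g = gens[gen_cycle[sex] % len(gens)]
        gen_cycle[sex] += 1
        mid = pools[g].pop(0)
        ind = members[mid]
        final[mid] = Individual(
            id=ind.id, father_id=ind.father_id, mother_id=ind.mother_id,
            sex=ind.sex, birth_order=ind.birth_order, affected=True,
            diagnosis=DiagnosisCode.from_label(label), onset_age=onsets[idx])
    return Pedigree(final.values(), family_id="faroese",
                    kindred_mode=KindredMode.ENDEMIC)


def table2_pedigree() -> Pedigree:
    """Synthetic pedigree whose vertical pairs reproduce the pair table.

    Each printed pair becomes an independent small family: an affected child
    (the Pc) with an affected parent (gap 1) or an affected grandparent with
    an unaffected intermediate parent (gap 2), on the paternal or maternal
    side as tabulated.  CLL-class members carry CLL, nonCLL-class members MM.
    """
    members: list[Individual] = []
    dx = {"CLL": DiagnosisCode.from_label("CLL"),
          "nonCLL": DiagnosisCode.from_label("MM")}

    def expand(counts) -> list[Sex]:
        _, male, female = counts
        return [Sex.MALE] * male + [Sex.FEMALE] * female

    unit = 0
    for parent_class, offspring_class, lineage, level, pcounts, ocounts in TABLE2:
        parent_sexes = expand(pcounts)
        offspring_sexes = expand(ocounts)
        assert len(parent_sexes) == len(offspring_sexes)
        for anc_sex, child_sex in zip(parent_sexes, offspring_sexes):
            fid = f"t2-{unit:04d}"
            unit += 1
            father, mother = f"{fid}-f", f"{fid}-m"
            pc = f"{fid}-pc"
            if level == "child":
                aff_parent = father if lineage == "PA" else mother
                want = Sex.MALE if lineage == "PA" else Sex.FEMALE
                assert anc_sex is want, "printed parent sexes follow the lineage"
                members.append(Individual(
                    id=father, sex=Sex.MALE, affected=(aff_parent == father),
                    diagnosis=dx[parent_class] if aff_parent == father else None))
                members.append(Individual(
                    id=mother, sex=Sex.FEMALE, affected=(aff_parent == mother),
                    diagnosis=dx[parent_class] if aff_parent == mother else None))
            else:  # grandchild row: affected grandparent on the given side
                gpf, gpm = f"{fid}-gf", f"{fid}-gm"
                aff_gp = gpf if anc_sex is Sex.MALE else gpm
                members.append(Individual(
                    id=gpf, sex=Sex.MALE, affected=(aff_gp == gpf),
                    diagnosis=dx[parent_class] if aff_gp == gpf else None))
                members.append(Individual(
                    id=gpm, sex=Sex.FEMALE, affected=(aff_gp == gpm),
                    diagnosis=dx[parent_class] if aff_gp == gpm else None))
                if lineage == "PA":
                    members.append(Individual(id=father, sex=Sex.MALE,
                                              father_id=gpf, mother_id=gpm,
                                              birth_order=1))
                    members.append(Individual(id=mother, sex=Sex.FEMALE))
                else:
                    members.append(Individual(id=mother, sex=Sex.FEMALE,
                                              father_id=gpf, mother_id=gpm,
                                              birth_order=1))
                    members.append(Individual(id=father, sex=Sex.MALE))
            members.append(Individual(
                id=pc, father_id=father, mother_id=mother, sex=child_sex,
                birth_order=1, affected=True, diagnosis=dx[offspring_class]))
    return Pedigree(members, family_id="table2", kindred_mode=KindredMode.NUCLEAR)
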
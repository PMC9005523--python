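"""Shared fixtures: hand-built pedigrees and sibship constructors."""
from __future__ import annotations

import pytest

from hemeped.diagnoses import DiagnosisCode
from hemeped.pedigree import Individual, KindredMode, Pedigree, Sex, Sibship

CLL = DiagnosisCode.from_label("CLL")
MM = DiagnosisCode.from_label("MM")
AML = DiagnosisCode.from_label("AML")


def ind(id, father=None, mother=None, sex=Sex.MALE, rank=None, year=None,
        dx=None, onset=None):
    return Individual(id=id, father_id=father, mother_id=mother, sex=sex,
                      birth_order=rank, birth_year=year,
                      affected=dx is not None, diagnosis=dx, onset_age=onset)


def make_sibship(size: int, affected_ranks, dx=CLL, sex=Sex.MALE) -> Sibship:
    """A standalone sibship of ``size`` with the given affected birth ranks."""
    members = tuple(
        ind(f"c{r}", father="f", mother="m", sex=sex, rank=r,
            dx=dx if r in set(affected_ranks) else None,
            onset=60.0 if r in set(affected_ranks) else None)
        for r in range(1, size + 1))
    return Sibship(father_id="f", mother_id="m", members=members)


@pytest.fixture
def trio() -> Pedigree:
    """Father, mother, one affected CLL child."""
    return Pedigree([
        ind("f", sex=Sex.MALE),
        ind("m", sex=Sex.FEMALE),
        ind("c", father="f", mother="m", sex=Sex.MALE, rank=1, dx=CLL, onset=60),
    ])


@pytest.fixture
def three_generations() -> Pedigree:
    """Affected maternal grandfather -> unaffected mother -> affected child."""
    return Pedigree([
        ind("gf", sex=Sex.MALE, dx=MM, onset=70),
        ind("gm", sex=Sex.FEMALE),
        ind("m", father="gf", mother="gm", sex=Sex.FEMALE, rank=1),
        ind("f", sex=Sex.MALE),
        ind("c", father="f", mother="m", sex=Sex.MALE, rank=1, dx=CLL, onset=55),
    ])


@pytest.fixture
def consanguineous() -> Pedigree:
    """First-cousin parents: the affected great-grandparent is an ancestor of
    the proband through both the father and the mother."""
    members = [
        ind("gg-f", sex=Sex.MALE, dx=MM, onset=75),      # shared great-grandfather
        ind("gg-m", sex=Sex.FEMALE),
        # two of their children, heads of the two branches
        ind("u1", father="gg-f", mother="gg-m", sex=Sex.MALE, rank=1),
        ind("u2", father="gg-f", mother="gg-m", sex=Sex.FEMALE, rank=2),
        ind("u1-w", sex=Sex.FEMALE),
        ind("u2-h", sex=Sex.MALE),
        # the cousin couple
        ind("pf", father="u1", mother="u1-w", sex=Sex.MALE, rank=1),
        ind("pm", father="u2-h", mother="u2", sex=Sex.FEMALE, rank=1),
        # proband
        ind("pc", father="pf", mother="pm", sex=Sex.MALE, rank=1, dx=CLL, onset=50),
    ]
    return Pedigree(members, family_id="loop", kindred_mode=KindredMode.ENDEMIC)
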
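"""Pc-AR enumeration, lineage classification, vertical pair extraction."""
import pytest

from hemeped.errors import AmbiguousLineageError, AnalysisError, RelationError
from hemeped.pairs import (MA, PA, classify_lineage, enumerate_pc_ar,
                           extract_vertical_pairs, pair_percentages,
                           sibling_concordance_pairs)
from hemeped.pedigree import KindredMode, Pedigree, Sex
from hemeped.simulate import SimulationConfig, generate_pedigree

from .conftest import AML, CLL, MM, ind


# ---------------------------------------------------------------------------
# lineage classification
# ---------------------------------------------------------------------------
class TestClassifyLineage:
    def test_father_is_pa(self):
        ped = Pedigree([ind("f", dx=CLL, onset=70), ind("m", sex=Sex.FEMALE),
                        ind("c", father="f", mother="m", dx=CLL, onset=50)])
        assert classify_lineage(ped, "c", "f") == PA

    def test_maternal_grandfather_is_ma(self, three_generations):
        assert classify_lineage(three_generations, "c", "gf") == MA

    def test_not_an_ancestor_raises(self, three_generations):
        with pytest.raises(RelationError):
            classify_lineage(three_generations, "gf", "c")

    def test_consanguinity_loop_is_ambiguous(self, consanguineous):
        with pytest.raises(AmbiguousLineageError):
            classify_lineage(consanguineous, "pc", "gg-f")

    def test_loop_yields_one_pair_per_first_edge(self, consanguineous):
        pairs = [p for p in enumerate_pc_ar(consanguineous)
                 if p.pc_id == "pc" and p.ar_id == "gg-f"]
        assert sorted(p.lineage for p in pairs) == [MA, PA]
        assert all(p.ambiguous for p in pairs)
        assert all(p.generation_gap == 3 for p in pairs)


# ---------------------------------------------------------------------------
# enumeration caps
# ---------------------------------------------------------------------------
def vertical_chain(n_links: int, affected_top=True):
    """pc at the bottom of a male chain of ``n_links`` parent steps."""
    members = [ind("g0", dx=MM if affected_top else None,
                   onset=80 if affected_top else None)]
    for k in range(1, n_links + 1):
        dx = CLL if k == n_links else None
        members.append(ind(f"g{k}", father=f"g{k-1}", rank=1, dx=dx,
                           onset=50 if dx else None))
    return Pedigree(members)


class TestEnumerationCaps:
    def test_parent_child_single_pair(self):
        ped = Pedigree([ind("f", dx=CLL, onset=70), ind("m", sex=Sex.FEMALE),
                        ind("c", father="f", mother="m", dx=CLL, onset=50)])
        pairs = enumerate_pc_ar(ped)
        # both affected act as Pc, but only the child has an affected ancestor
        assert len(pairs) == 1
        pr = pairs[0]
        assert (pr.pc_id, pr.ar_id, pr.lineage, pr.generation_gap,
                pr.relation_class) == ("c", "f", PA, 1, "vertical")

    def test_generation_gap_cap(self):
        ped = vertical_chain(6)  # ancestor 6 generations up
        assert enumerate_pc_ar(ped, max_generations=5) == []
        assert len(enumerate_pc_ar(ped, max_generations=6)) == 1

    def test_gap_five_with_four_healthy_included(self):
        ped = vertical_chain(5)
        pairs = enumerate_pc_ar(ped)
        assert len(pairs) == 1
        assert pairs[0].generation_gap == 5
        assert pairs[0].healthy_intermediates == 4

    @pytest.mark.parametrize("extra_affected,expect_pair", [(False, False), (True, True)])
    def test_healthy_intermediate_cap(self, extra_affected, expect_pair):
        """An up-4/down-3 connecting path has six intermediates: all healthy
        exceeds the cap; making one affected (five healthy) admits the pair."""
        q1_dx = AML if extra_affected else None
        members = [
            ind("top"),
            ind("p3", father="top", rank=1), ind("p2", father="p3", rank=1),
            ind("p1", father="p2", rank=1),
            ind("pc", father="p1", rank=1, dx=CLL, onset=50),
            ind("q1", father="top", rank=2, dx=q1_dx,
                onset=70 if extra_affected else None),
            ind("q2", father="q1", rank=1),
            ind("ar", father="q2", rank=1, dx=MM, onset=75),
        ]
        ped = Pedigree(members)
        hit = [p for p in enumerate_pc_ar(ped)
               if p.pc_id == "pc" and p.ar_id == "ar"]
        assert bool(hit) == expect_pair
        if hit:
            assert hit[0].healthy_intermediates == 5
            assert hit[0].relation_class == "oblique"
            assert hit[0].generation_gap == 1

    def test_monotone_in_both_caps(self):
        res = generate_pedigree(SimulationConfig(
            mode=KindredMode.ENDEMIC, seed=11, n_generations=5, parity=3.0))
        ped = res.pedigree

        def keys(gens, healthy):
            return {(p.pc_id, p.ar_id, p.lineage)
                    for p in enumerate_pc_ar(ped, gens, healthy)}

        for gens, healthy in [(2, 1), (3, 2), (4, 3), (5, 5)]:
            assert keys(gens, healthy) <= keys(gens + 1, healthy)
            assert keys(gens, healthy) <= keys(gens, healthy + 1)


# ---------------------------------------------------------------------------
# vertical extraction and percentages
# ---------------------------------------------------------------------------
class TestVerticalExtraction:
    def test_aunt_nephew_pair_is_excluded(self):
        members = [
            ind("gf"), ind("gm", sex=Sex.FEMALE),
            ind("f", father="gf", mother="gm", rank=1),
            ind("aunt", father="gf", mother="gm", sex=Sex.FEMALE, rank=2,
                dx=MM, onset=65),
            ind("m", sex=Sex.FEMALE),
            ind("pc", father="f", mother="m", rank=1, dx=CLL, onset=50),
        ]
        pairs = enumerate_pc_ar(Pedigree(members))
        assert [(p.ar_id, p.relation_class) for p in pairs
                if p.pc_id == "pc"] == [("aunt", "oblique")]
        assert len(extract_vertical_pairs(pairs)) == 0

    def test_grandparent_with_unaffected_parent_is_vertical(self, three_generations):
        table = extract_vertical_pairs(enumerate_pc_ar(three_generations))
        assert len(table) == 1
        pr = table.pairs[0]
        assert (pr.ar_id, pr.lineage, pr.generation_gap,
                pr.healthy_intermediates) == ("gf", MA, 2, 1)

    def test_single_male_pair_percentages(self):
        ped = Pedigree([ind("f", dx=CLL, onset=70), ind("m", sex=Sex.FEMALE),
                        ind("c", father="f", mother="m", dx=CLL, onset=50)])
        pct = pair_percentages(extract_vertical_pairs(enumerate_pc_ar(ped)))
        row = pct.loc[("CLL", "CLL", PA)]
        assert row.pct_male == 100 and row.pct_female == 0
        # empty stratum is undefined, not zero
        assert pct.loc[("CLL", "CLL", MA)].pct_male != pct.loc[("CLL", "CLL", MA)].pct_male

    def test_empty_table_percentage_errors(self):
        with pytest.raises(AnalysisError):
            pair_percentages(extract_vertical_pairs([]))


# ---------------------------------------------------------------------------
# oracles on simulator output
# ---------------------------------------------------------------------------
def brute_force_vertical(ped, max_gap=2, max_healthy=5):
    """Independent double loop over ordered affected pairs testing ancestry."""
    out = set()
    for pc in ped.affected:
        for ar in ped.affected:
            if ar.id == pc.id or ar.id not in ped.ancestors(pc.id, max_gap):
                continue
            # walk every ancestral chain pc -> ar
            def chains(node, path):
                if node == ar.id:
                    yield path
                    return
                for par in ped.parents_of(node):
                    if len(path) <= max_gap:
                        yield from chains(par.id, path + [par.id])
            for chain in chains(pc.id, [pc.id]):
                healthy = sum(1 for x in chain[1:-1] if not ped[x].affected)
                if healthy <= max_healthy:
                    first = chain[1]
                    lin = PA if (ped.father_of(pc.id) and
                                 first == ped.father_of(pc.id).id) else MA
                    out.add((pc.id, ar.id, lin))
    return out


class TestOracles:
    def test_vertical_table_matches_brute_force(self):
        res = generate_pedigree(SimulationConfig(seed=21, n_families=60))
        table = extract_vertical_pairs(enumerate_pc_ar(res.pedigree))
        got = {(p.pc_id, p.ar_id, p.lineage) for p in table.pairs}
        assert got == brute_force_vertical(res.pedigree)

    def test_lineage_matches_classifier(self):
        res = generate_pedigree(SimulationConfig(
            mode=KindredMode.ENDEMIC, seed=5, n_generations=5, parity=3.0))
        pairs = [p for p in enumerate_pc_ar(res.pedigree)
                 if p.relation_class == "vertical"]
        assert pairs, "endemic pedigree should contain vertical pairs"
        for pr in pairs:
            if pr.ambiguous:
                with pytest.raises(AmbiguousLineageError):
                    classify_lineage(res.pedigree, pr.pc_id, pr.ar_id)
            else:
                assert classify_lineage(res.pedigree, pr.pc_id, pr.ar_id) == pr.lineage

    def test_pa_plus_ma_equals_total(self):
        res = generate_pedigree(SimulationConfig(seed=33, n_families=80))
        table = extract_vertical_pairs(enumerate_pc_ar(res.pedigree))
        counts = table.lineage_counts()
        assert counts[PA] + counts[MA] == len(table)

    def test_no_ambiguity_in_nuclear_mode(self):
        res = generate_pedigree(SimulationConfig(seed=8, n_families=100))
        assert not any(p.ambiguous for p in enumerate_pc_ar(res.pedigree))


def test_sibling_concordance_is_horizontal_only():
    ped = Pedigree([ind("f"), ind("m", sex=Sex.FEMALE),
                    ind("a", father="f", mother="m", rank=1, dx=CLL, onset=60),
                    ind("b", father="f", mother="m", rank=2, dx=MM, onset=62)])
    assert sibling_concordance_pairs(ped) == [("a", "b")]
    assert enumerate_pc_ar(ped) == []  # siblings never form Pc-AR pairs
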
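"""Trio inheritance-pattern detection: parental origin, compound
heterozygosity, trans-heterozygous pathway disruption, additive load."""

import itertools

import numpy as np
import pytest

from famburden import (
    Cohort,
    CohortError,
    Consequence,
    Fracture,
    Group,
    Subject,
    TrioPlant,
    TrioRole,
    generate_trio_fixtures,
)
from famburden.pathways import builtin_pathways
from famburden.trios import (
    Trio,
    assign_parental_origin,
    detect_additive_load,
    detect_compound_het,
    detect_trans_het_pathway,
    resolve_trios,
)

from conftest import make_call


def _collagen():
    return next(g for g in builtin_pathways()
                if g.name == "collagen_biosynthesis")


def _trio(child_calls, mother_calls, father_calls):
    child = Subject("C", "F1", Group.CASE, trio_role=TrioRole.CHILD)
    mother = Subject("M", "F1", Group.CASE, trio_role=TrioRole.MOTHER)
    father = Subject("F", "F1", Group.CONTROL, trio_role=TrioRole.FATHER)
    return Trio(child=child, mother=mother, father=father,
                child_calls=child_calls, mother_calls=mother_calls,
                father_calls=father_calls)


def _variant(subject, gene="G", pos=100, **kw):
    return make_call(subject, gene, "1", pos, **kw)


# --------------------------------------------------------- parental origin


def test_origin_maternal_paternal_both_de_novo():
    child_v = _variant("C", pos=100)
    trio = _trio([child_v], [_variant("M", pos=100)], [])
    assert assign_parental_origin(trio, child_v) == "maternal"
    trio = _trio([child_v], [], [_variant("F", pos=100)])
    assert assign_parental_origin(trio, child_v) == "paternal"
    trio = _trio([child_v], [_variant("M", pos=100)],
                 [_variant("F", pos=100)])
    assert assign_parental_origin(trio, child_v) == "both"
    trio = _trio([child_v], [], [])
    assert assign_parental_origin(trio, child_v) == "de_novo"


# -------------------------------------------------------- compound het


def test_compound_het_planted_pattern_detected():
    v1 = _variant("C", pos=100)
    v2 = _variant("C", pos=200, ref="G", alt="T")
    trio = _trio([v1, v2], [_variant("M", pos=100)],
                 [_variant("F", pos=200, ref="G", alt="T")])
    (hit,) = detect_compound_het(trio)
    assert hit.genes == ("G",)
    assert set(hit.origins.values()) == {"maternal", "paternal"}


def test_two_maternal_variants_are_not_compound_het():
    v1 = _variant("C", pos=100)
    v2 = _variant("C", pos=200, ref="G", alt="T")
    trio = _trio([v1, v2],
                 [_variant("M", pos=100),
                  _variant("M", pos=200, ref="G", alt="T")], [])
    assert detect_compound_het(trio) == []


def test_shared_parental_variant_satisfies_neither_side():
    v1 = _variant("C", pos=100)  # in both parents -> ambiguous
    v2 = _variant("C", pos=200, ref="G", alt="T")  # paternal
    trio = _trio([v1, v2],
                 [_variant("M", pos=100)],
                 [_variant("F", pos=100),
                  _variant("F", pos=200, ref="G", alt="T")])
    assert detect_compound_het(trio) == []


def brute_force_compound_het(trio):
    """Oracle: enumerate all child het variant pairs per gene and check
    origins pairwise."""
    genes = set()
    hets = [c for c in trio.child_calls if c.zygosity.value == "het"]
    for v1, v2 in itertools.combinations(hets, 2):
        if v1.gene_symbol != v2.gene_symbol:
            continue
        o1 = assign_parental_origin(trio, v1)
        o2 = assign_parental_origin(trio, v2)
        if {o1, o2} == {"maternal", "paternal"}:
            genes.add(v1.gene_symbol)
    return genes


def test_compound_het_agrees_with_pairwise_enumeration():
    rng = np.random.default_rng(0)
    for fixture in range(15):
        child_calls, mother_calls, father_calls = [], [], []
        for gene in ("G1", "G2", "G3"):
            for pos in rng.choice(np.arange(100, 1000), size=3,
                                  replace=False):
                pos = int(pos)
                where = rng.integers(4)
                v_child = _variant("C", gene, pos)
                if where == 0:  # maternal
                    mother_calls.append(_variant("M", gene, pos))
                    child_calls.append(v_child)
                elif where == 1:  # paternal
                    father_calls.append(_variant("F", gene, pos))
                    child_calls.append(v_child)
                elif where == 2:  # both parents
                    mother_calls.append(_variant("M", gene, pos))
                    father_calls.append(_variant("F", gene, pos))
                    child_calls.append(v_child)
                # where == 3: child does not carry it
        trio = _trio(child_calls, mother_calls, father_calls)
        detected = {h.genes[0] for h in detect_compound_het(trio)}
        assert detected == brute_force_compound_het(trio)


def test_detection_invariant_to_call_order():
    v1 = _variant("C", pos=100)
    v2 = _variant("C", pos=200, ref="G", alt="T")
    m = [_variant("M", pos=100)]
    f = [_variant("F", pos=200, ref="G", alt="T")]
    forward = detect_compound_het(_trio([v1, v2], m, f))
    reverse = detect_compound_het(_trio([v2, v1], m, f))
    assert [h.genes for h in forward] == [h.genes for h in reverse]
    assert [h.variant_keys for h in forward] == \
           [h.variant_keys for h in reverse]


# ------------------------------------------------------ trans-het pathway


def test_trans_het_pathway_planted_pattern_detected():
    va = _variant("C", "COL5A1", 100)
    vb = _variant("C", "PLOD1", 200)
    trio = _trio([va, vb], [_variant("M", "COL5A1", 100)],
                 [_variant("F", "PLOD1", 200)])
    (hit,) = detect_trans_het_pathway(trio, [_collagen()])
    assert set(hit.genes) == {"COL5A1", "PLOD1"}


def test_trans_het_requires_both_parental_sides():
    va = _variant("C", "COL5A1", 100)
    vb = _variant("C", "PLOD1", 200)
    trio = _trio([va, vb],
                 [_variant("M", "COL5A1", 100),
                  _variant("M", "PLOD1", 200)], [])
    assert detect_trans_het_pathway(trio, [_collagen()]) == []


def test_compound_het_only_trio_is_silent_for_trans_het():
    """Two variants in one pathway gene are compound het, not trans-het."""
    v1 = _variant("C", "COL5A1", 100)
    v2 = _variant("C", "COL5A1", 200, ref="G", alt="T")
    trio = _trio([v1, v2], [_variant("M", "COL5A1", 100)],
                 [_variant("F", "COL5A1", 200, ref="G", alt="T")])
    assert detect_compound_het(trio) != []
    assert detect_trans_het_pathway(trio, [_collagen()]) == []


# --------------------------------------------------------- additive load


def test_additive_load_hit_requires_both_sides():
    stop = _variant("C", "G1", 100, consequence=Consequence.STOP_GAIN,
                    gnomad_af=0.05)
    mis = _variant("C", "G2", 200, consequence=Consequence.MISSENSE,
                   gnomad_af=0.05)
    trio = _trio([stop, mis],
                 [_variant("M", "G1", 100,
                           consequence=Consequence.STOP_GAIN,
                           gnomad_af=0.05)],
                 [_variant("F", "G2", 200,
                           consequence=Consequence.MISSENSE,
                           gnomad_af=0.05)])
    hit = detect_additive_load(trio, threshold=12)
    assert hit is not None and hit.load == 15.0
    # same load all maternal: no hit
    trio2 = _trio([stop, mis],
                  [_variant("M", "G1", 100,
                            consequence=Consequence.STOP_GAIN,
                            gnomad_af=0.05),
                   _variant("M", "G2", 200,
                            consequence=Consequence.MISSENSE,
                            gnomad_af=0.05)], [])
    assert detect_additive_load(trio2, threshold=12) is None


def test_additive_load_threshold_is_mandatory():
    trio = _trio([], [], [])
    with pytest.raises(CohortError, match="threshold"):
        detect_additive_load(trio)


def test_additive_load_threshold_sweep_is_monotone():
    plants = [TrioPlant("additive_load", ("GA", "GB"), target_load=20)]
    cohort = generate_trio_fixtures(plants, seed=1, n_trios=4)
    trios = resolve_trios(cohort)
    previous_hits = None
    for threshold in (5, 10, 15, 20, 25, 40):
        hits = {t.child.subject_id
                for t in trios
                if detect_additive_load(t, threshold=threshold) is not None}
        if previous_hits is not None:
            assert hits <= previous_hits
        previous_hits = hits


# ------------------------------------------------------- planted fixtures


def test_planted_patterns_recovered_and_unplanted_trios_clean():
    collagen = _collagen()
    plants = [
        TrioPlant("compound_het", ("COL5A1",)),
        TrioPlant("trans_het_pathway", ("COL5A1", "PLOD1"),
                  gene_set=collagen),
        TrioPlant("additive_load", ("GENEA", "GENEB"), target_load=15),
    ]
    cohort = generate_trio_fixtures(plants, seed=42, n_trios=6)
    trios = resolve_trios(cohort)
    assert len(trios) == 6
    by_child = {t.child.subject_id: t for t in trios}

    hit = detect_compound_het(by_child["TRIO001_C"])
    assert [h.genes for h in hit] == [("COL5A1",)]
    hit = detect_trans_het_pathway(by_child["TRIO002_C"], [collagen])
    assert len(hit) == 1 and set(hit[0].genes) == {"COL5A1", "PLOD1"}
    assert {v for v in hit[0].origins.values()} == {"maternal", "paternal"}
    hit = detect_additive_load(by_child["TRIO003_C"], threshold=15)
    assert hit is not None and hit.load >= 15

    for child in ("TRIO004_C", "TRIO005_C", "TRIO006_C"):
        trio = by_child[child]
        assert detect_compound_het(trio) == []
        assert detect_trans_het_pathway(trio, builtin_pathways()) == []
        assert detect_additive_load(trio, threshold=15) is None


def test_zero_plants_all_detectors_empty():
    cohort = generate_trio_fixtures([], seed=0, n_trios=5)
    for trio in resolve_trios(cohort):
        assert detect_compound_het(trio) == []
        assert detect_trans_het_pathway(trio, builtin_pathways()) == []
        assert detect_additive_load(trio, threshold=10) is None


def test_trio_invariants_enforced():
    child = Subject("C", "F1", Group.CASE, trio_role=TrioRole.CHILD)
    mother = Subject("M", "F2", Group.CASE, trio_role=TrioRole.MOTHER)
    father = Subject("F", "F1", Group.CONTROL, trio_role=TrioRole.FATHER)
    with pytest.raises(CohortError, match="family"):
        Trio(child=child, mother=mother, father=father,
             child_calls=[], mother_calls=[], father_calls=[])
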
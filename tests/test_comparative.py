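"""Tests for architecture distance, trees, ecotypes and parentage."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrarch import comparative as cp
from ssrarch import repeat_core as rc
from ssrarch.genome_scan import Amplicon

from oracles import brute_align

FAM = rc.MotifFamily({"CAG", "CAT", "CAA"})


def A(notation):
    return rc.parse_notation(notation, FAM)


# ---------------------------------------------------------------------------
# align_units
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, thirds",
    [
        ("(CAG)3(CAT)2", "(CAG)3(CAT)2", 0),
        ("(CAG)5", "(CAG)7", 6),  # two unit indels
        ("(CAA)1(CAG)3", "(CAG)4", 1),  # one SNP inside one unit
        ("(CAG)2[CCG](CAG)1", "(CAG)4", 1),
    ],
)
def test_align_units_examples(a, b, thirds):
    res = cp.align_units(A(a), A(b))
    assert res.cost_thirds == thirds
    assert res.distance == pytest.approx(thirds / 3)


def test_single_unit_snp_costs_one_third():
    # a CAA→CAG change inside one unit, as seen between same-length alleles
    assert cp.align_units(A("(CAA)1(CAG)2"), A("(CAG)3")).distance == pytest.approx(1 / 3)


unit_seq = st.lists(
    st.sampled_from(["CAG", "CAT", "CAA", "CCG", "CCA"]), min_size=3, max_size=8
)


def _arch_from_units(units):
    try:
        return rc.decompose("".join(units), FAM)
    except rc.NoRepeatFoundError:
        return None


@settings(max_examples=150, derandomize=True, deadline=None)
@given(unit_seq, unit_seq)
def test_align_units_matches_bruteforce_and_metric_axioms(ua, ub):
    a, b = _arch_from_units(ua), _arch_from_units(ub)
    if a is None or b is None:
        return
    res = cp.align_units(a, b)
    assert res.cost_thirds == brute_align(a.unit_texts(), b.unit_texts())
    # metric axioms (exact, in integer thirds)
    assert res.cost_thirds >= 0
    assert (res.cost_thirds == 0) == (a.unit_texts() == b.unit_texts())
    assert cp.align_units(b, a).cost_thirds == res.cost_thirds


@settings(max_examples=80, derandomize=True, deadline=None)
@given(unit_seq, unit_seq, unit_seq)
def test_align_units_triangle_inequality(ua, ub, uc):
    archs = [_arch_from_units(u) for u in (ua, ub, uc)]
    if any(x is None for x in archs):
        return
    a, b, c = archs
    dab = cp.align_units(a, b).cost_thirds
    dbc = cp.align_units(b, c).cost_thirds
    dac = cp.align_units(a, c).cost_thirds
    assert dac <= dab + dbc


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------


def test_distance_matrix_basic_and_permutation_invariance():
    labelled = [("x", A("(CAG)5")), ("y", A("(CAG)5")), ("z", A("(CAT)3(CAA)4"))]
    dm = cp.distance_matrix(labelled)
    assert dm[("x", "y")] == 0
    assert dm[("x", "z")] > 0
    perm = cp.distance_matrix(labelled[::-1])
    for i in "xyz":
        for j in "xyz":
            assert dm[(i, j)] == perm[(i, j)]


def test_distance_matrix_matches_pairwise_loop():
    labelled = [("a", A("(CAG)4(CAT)2")), ("b", A("(CAG)6")), ("c", A("(CAA)3(CAT)3"))]
    dm = cp.distance_matrix(labelled)
    for la, aa in labelled:
        for lb, ab in labelled:
            assert dm[(la, lb)] == pytest.approx(cp.align_units(aa, ab).distance)


def test_distance_matrix_rejects_duplicate_labels():
    with pytest.raises(ValueError, match="duplicate"):
        cp.distance_matrix([("x", A("(CAG)3")), ("x", A("(CAG)4"))])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _nj_topology_matches(newick: str, expected_newick: str, taxa: list[str]) -> bool:
    tns = dendropy.TaxonNamespace(taxa)
    t1 = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=expected_newick, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2) == 0


def test_nj_three_taxa_closed_form():
    # d(x,y)=3, d(x,z)=4, d(y,z)=5 → leaf branches 1, 2, 3
    dm = cp.DistanceMatrix(
        ("x", "y", "z"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    )
    tree = dendropy.Tree.get(data=cp.nj_tree(dm), schema="newick")
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }
    assert lengths == pytest.approx({"x": 1.0, "y": 2.0, "z": 3.0})


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize(
    "shape",
    [
        "((A:{0},B:{1}):{4},(C:{2},D:{3}):{5});",
        "((A:{0},B:{1}):{5},(C:{2},(D:{3},E:{4}):{6}):{7});",
    ],
)
def test_nj_recovers_additive_tree_topology(shape, seed):
    """On a tree-additive metric, neighbor joining returns the generating
    topology (4- and 5-leaf trees, branch lengths ≥ 0.1)."""
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(0.1, 2.0, size=8)
    newick = shape.format(*lengths)
    taxa = [x for x in "ABCDE" if f"{x}:" in newick]
    src = dendropy.Tree.get(data=newick, schema="newick")
    pdm = src.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in src.taxon_namespace)
    by_label = {t.label: t for t in src.taxon_namespace}
    d = np.array(
        [
            [pdm.patristic_distance(by_label[i], by_label[j]) if i != j else 0.0 for j in labels]
            for i in labels
        ]
    )
    out = cp.nj_tree(cp.DistanceMatrix(tuple(labels), d))
    assert _nj_topology_matches(out, newick, taxa)


def test_nj_requires_three_taxa():
    dm = cp.DistanceMatrix(("x", "y"), np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError):
        cp.nj_tree(dm)


# ---------------------------------------------------------------------------
# ecotype grouping
# ---------------------------------------------------------------------------


def _panel(strain, sizes, notations=None):
    alleles = []
    for k, size in enumerate(sizes):
        arch = A(notations[k]) if notations else None
        alleles.append(("B10", Amplicon(strain, "B10", "N" * size, size, arch)))
    return cp.AllelePanel(strain, tuple(alleles))


TABLE1_SIZES = {
    "U2": (159, 194), "U6": (159, 194), "U10": (159, 194),
    "U12": (159, 194), "U13": (159, 194),
    "U3": (159, 177), "U7": (159, 177), "U9": (159, 177),
    "U4": (171, 191),
    "U5": (159, 196),
}


def test_group_ecotypes_by_size_recovers_four_ecotypes():
    panels = [_panel(s, sz) for s, sz in TABLE1_SIZES.items()]
    groups = cp.group_ecotypes(panels, "by-size")
    assert sorted(len(g.strain_ids) for g in groups) == [1, 1, 3, 5]
    assert len(groups) == 4


def test_group_ecotypes_identical_panels_form_one_group():
    panels = [_panel(s, (100, 120)) for s in ("a", "b", "c")]
    assert len(cp.group_ecotypes(panels, "by-size")) == 1


def test_group_ecotypes_by_architecture_splits_same_length_snp_allele():
    base = ["(CAG)5(CAT)2(CAA)3", "(CAG)8(CAT)3(CAA)2"]
    snp = ["(CAG)5(CAT)2(CAA)3", "(CAG)8(CAT)3(CAA)1(CAG)1"]  # same lengths
    panels = [
        _panel("u2", (130, 139), base),
        _panel("u6", (130, 139), snp),
        _panel("u10", (130, 139), base),
    ]
    assert len(cp.group_ecotypes(panels, "by-size")) == 1
    by_arch = cp.group_ecotypes(panels, "by-architecture")
    assert sorted(tuple(g.strain_ids) for g in by_arch) == [("u10", "u2"), ("u6",)]


# ---------------------------------------------------------------------------
# parent assignment
# ---------------------------------------------------------------------------


def test_assign_parentage_recovers_parents_by_construction():
    p1, p2 = A("(CAG)9(CAT)2(CAA)2"), A("(CAG)4(CAA)1(CAG)2(CAT)3")
    hybrid = cp.AllelePanel(
        "h",
        (
            ("B10", Amplicon("h", "B10", p2.sequence, 3 * p2.n_units, p2)),
            ("B10", Amplicon("h", "B10", p1.sequence, 3 * p1.n_units, p1)),
        ),
    )
    res = cp.assign_parentage(hybrid, [("P1", p1), ("P2", p2)])
    by_allele = {r.allele_id: r for r in res}
    assert by_allele["h:small"].parent_id == "P2"
    assert by_allele["h:large"].parent_id == "P1"
    assert all(r.margin > 0 and r.status == "assigned" for r in res)


def test_assign_parentage_uses_one_to_one_matching():
    # both alleles are nearer P1; the matching still uses each parent once
    p1, p2 = A("(CAG)6"), A("(CAG)6(CAT)6(CAA)6")
    a1, a2 = A("(CAG)5"), A("(CAG)8")
    hybrid = cp.AllelePanel(
        "h",
        (
            ("B10", Amplicon("h", "B10", a1.sequence, 15, a1)),
            ("B10", Amplicon("h", "B10", a2.sequence, 24, a2)),
        ),
    )
    res = cp.assign_parentage(hybrid, [("P1", p1), ("P2", p2)])
    assert {r.parent_id for r in res} == {"P1", "P2"}


def test_assign_parentage_flags_equidistant_parents_ambiguous():
    p1, p2 = A("(CAG)5"), A("(CAG)7")
    allele = A("(CAG)6")
    hybrid = cp.AllelePanel(
        "h", (("B10", Amplicon("h", "B10", allele.sequence, 18, allele)),)
    )
    (res,) = cp.assign_parentage(hybrid, [("P1", p1), ("P2", p2)])
    assert res.status == "ambiguous"
    assert res.margin == pytest.approx(0.0)
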
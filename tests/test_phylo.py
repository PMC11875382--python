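"""Alignment, distance models, neighbor joining, bootstrap, strain grouping."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from fawkit.markers import ReferenceHaplotypeSet
from fawkit.phylo import (
    SATURATION_CAP,
    DistanceMatrix,
    HaplotypeAlignment,
    align_haplotypes,
    assign_strain_group,
    bootstrap_support,
    build_nj_tree,
    compute_distances,
)

# ---------------------------------------------------------------------------
# synthetic sequence helpers
# ---------------------------------------------------------------------------

_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "C", "G": "T", "C": "G", "T": "A"}


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def mutate(seq, positions, table=None, rng=None):
    s = list(seq)
    for p in positions:
        if table is not None:
            s[p] = table[s[p]]
        else:
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


def two_clade_sequences(n_per=8, length=200, n_fixed=30, n_private=2, seed=0):
    """Two clades separated by n_fixed substitutions, n_private per sequence.

    Between-clade divergence (>= n_fixed/length) is >= 5x the within-clade
    divergence (<= 2*n_private/length) for the defaults used here.
    """
    rng = np.random.default_rng(seed)
    anc = random_seq(rng, length)
    fixed = rng.choice(length, size=n_fixed, replace=False)
    clade_b_base = mutate(anc, fixed, table=_TS)
    seqs, strains = {}, {}
    for i in range(n_per):
        pa = rng.choice(length, size=n_private, replace=False)
        seqs[f"cA{i:02d}"] = mutate(anc, pa, rng=rng)
        strains[f"cA{i:02d}"] = "C"
        pb = rng.choice(length, size=n_private, replace=False)
        seqs[f"cB{i:02d}"] = mutate(clade_b_base, pb, rng=rng)
        strains[f"cB{i:02d}"] = "R"
    return seqs, strains


def random_additive_tree(n_taxa, rng):
    """Random binary tree with branch lengths; returns (root, labels)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = round(float(rng.uniform(0.1, 1.0)), 6)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = round(float(rng.uniform(0.1, 1.0)), 6)
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root, [f"t{i}" for i in range(n_taxa)]


def bipartition_set(root):
    taxa = {t.name for t in root.tips()}
    anchor = min(taxa)
    out = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        out.add(side if anchor not in side else frozenset(taxa - side))
    return out


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


class TestAlignHaplotypes:
    def test_identical_sequences_no_gaps(self):
        aln = align_haplotypes({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
        assert all("-" not in r for r in aln.rows)

    def test_three_base_deletion_one_gap_run(self):
        base = "ACGTTGCAACGTGGTTACCA"
        deleted = base[:8] + base[11:]
        aln = align_haplotypes({"full": base, "del": deleted})
        row = aln.rows[aln.labels.index("del")]
        assert row.count("-") == 3
        gap_start = row.index("-")
        assert row[gap_start : gap_start + 3] == "---"

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        base = random_seq(rng, 60)
        seqs = {
            "a": base,
            "b": mutate(base, [5, 10], rng=rng),
            "c": base[:20] + base[23:],
            "d": mutate(base, [40], rng=rng),
        }
        reference = align_haplotypes(seqs)
        for order in itertools.permutations(seqs):
            aln = align_haplotypes({k: seqs[k] for k in order})
            assert aln.labels == reference.labels
            assert aln.rows == reference.rows

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            align_haplotypes({"a": "ACGT"})


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


class TestDistances:
    def test_identical_rows_zero_all_models(self):
        aln = HaplotypeAlignment(["a", "b"], ["ACGTACGT" * 10] * 2)
        for model in ("p", "JC69", "TN93"):
            assert compute_distances(aln, model).matrix[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        a = "A" * 200
        b = "A" * 198 + "CC"
        aln = HaplotypeAlignment(["a", "b"], [a, b])
        assert compute_distances(aln, "p").matrix[0, 1] == pytest.approx(0.01)

    def test_jc69_closed_form_at_p_0_1(self):
        a = "ACGT" * 50
        b = "G" + a[1:181] + mutate(a[181:], range(19), table=_TS)
        # construct exactly 20 differences out of 200
        b = mutate(a, range(0, 200, 10), table=_TS)
        aln = HaplotypeAlignment(["a", "b"], [a, b])
        assert compute_distances(aln, "p").matrix[0, 1] == pytest.approx(0.1)
        assert compute_distances(aln, "JC69").matrix[0, 1] == pytest.approx(
            0.107326, abs=1e-6
        )

    def test_models_match_independent_reference_values(self):
        """Distances agree with R ape::dist.dna on the same pair (frozen oracle)."""
        rng = np.random.default_rng(42)
        a = random_seq(rng, 120)
        b = mutate(a, [5, 20, 40, 60], table=_TS)
        b = mutate(b, [80, 95, 110], table=_TV)
        aln = HaplotypeAlignment(["a", "b"], [a, b])
        assert compute_distances(aln, "p").matrix[0, 1] == pytest.approx(
            0.05833333333, abs=1e-9
        )
        assert compute_distances(aln, "JC69").matrix[0, 1] == pytest.approx(
            0.0607267969, abs=1e-9
        )
        assert compute_distances(aln, "TN93").matrix[0, 1] == pytest.approx(
            0.06089984464, abs=1e-9
        )

    def test_pairwise_deletion_ignores_gap_and_ambiguity_columns(self):
        aln = HaplotypeAlignment(["a", "b"], ["ACGT-RCCCC", "ACGTTTCCCC"])
        # columns 4 (gap) and 5 (R) are deleted; remaining 8 identical
        assert compute_distances(aln, "p").matrix[0, 1] == 0.0

    def test_saturated_pair_capped(self):
        aln = HaplotypeAlignment(["a", "b"], ["A" * 50, "C" * 50])
        with pytest.warns(UserWarning, match="saturated"):
            d = compute_distances(aln, "JC69")
        assert d.matrix[0, 1] == SATURATION_CAP
        assert frozenset(("a", "b")) in d.capped_pairs

    def test_zero_comparable_sites_rejected(self):
        aln = HaplotypeAlignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(ValueError, match="zero comparable"):
            compute_distances(aln, "p")

    @given(st.integers(0, 2**31 - 1))
    def test_model_ordering(self, seed):
        """p <= JC69 and p <= TN93; everything bounded by the saturation cap."""
        rng = np.random.default_rng(seed)
        a = random_seq(rng, 150)
        k = int(rng.integers(0, 40))
        b = mutate(a, rng.choice(150, size=k, replace=False), rng=rng)
        aln = HaplotypeAlignment(["a", "b"], [a, b])
        p = compute_distances(aln, "p").matrix[0, 1]
        jc = compute_distances(aln, "JC69").matrix[0, 1]
        tn = compute_distances(aln, "TN93").matrix[0, 1]
        assert p <= jc + 1e-12 <= SATURATION_CAP + 1e-12
        assert p <= tn + 1e-12 <= SATURATION_CAP + 1e-12


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive path-length matrix
        m = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = build_nj_tree(DistanceMatrix(["A", "B", "C", "D"], m, "p"))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        dists = {t.name: t.length for t in tree.root.tips()}
        assert dists == {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0}

    def test_three_taxa_closed_formulas(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = build_nj_tree(DistanceMatrix(["a", "b", "c"], m, "p"))
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_identical_rows_become_zero_length_siblings(self):
        m = np.array(
            [[0, 0, 5, 6], [0, 0, 5, 6], [5, 5, 0, 3], [6, 6, 3, 0]], float
        )
        tree = build_nj_tree(DistanceMatrix(["a", "b", "c", "d"], m, "p"))
        a = tree.root.find("a")
        b = tree.root.find("b")
        assert a.parent is b.parent
        assert a.length == 0.0 and b.length == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p"))

    @given(st.integers(5, 8), st.integers(0, 2**31 - 1))
    def test_additive_matrix_recovery(self, n_taxa, seed):
        """NJ recovers random additive trees exactly: topology and lengths."""
        rng = np.random.default_rng(seed)
        true_tree, labels = random_additive_tree(n_taxa, rng)
        dm = true_tree.tip_tip_distances(endpoints=labels)
        D = DistanceMatrix(labels, dm.data, "p")
        recovered = build_nj_tree(D)
        assert bipartition_set(recovered.root) == bipartition_set(true_tree)
        rec_dm = recovered.root.tip_tip_distances(endpoints=labels)
        assert np.allclose(rec_dm.data, dm.data, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_topology_agrees_with_skbio_nj(self, seed):
        """Independent cross-check: same topology as scikit-bio's NJ."""
        rng = np.random.default_rng(seed)
        true_tree, labels = random_additive_tree(6, rng)
        data = true_tree.tip_tip_distances(endpoints=labels).data
        ours = build_nj_tree(DistanceMatrix(labels, data, "p"))
        theirs = skbio_nj(SkbioDM(data, ids=labels))
        assert bipartition_set(ours.root) == bipartition_set(theirs)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


class TestBootstrap:
    def test_two_clades_full_support_on_separating_edge(self):
        seqs, _ = two_clade_sequences(n_per=6, seed=5)
        aln = align_haplotypes(seqs)
        tree = bootstrap_support(aln, model="TN93", B=100, seed=1)
        clade_b = frozenset(l for l in seqs if l.startswith("cB"))
        assert tree.supports.get(clade_b) == 100.0

    def test_identical_sequences_star_tree(self):
        aln = HaplotypeAlignment(
            [f"s{i}" for i in range(5)], ["ACGTACGTAC" * 5] * 5
        )
        tree = bootstrap_support(aln, model="p", B=10, seed=0)
        assert tree.supports == {}
        assert len(tree.root.children) == 5  # fully collapsed star

    def test_seed_determinism(self):
        seqs, _ = two_clade_sequences(n_per=4, n_fixed=6, n_private=3, seed=2)
        aln = align_haplotypes(seqs)
        t1 = bootstrap_support(aln, B=30, seed=9)
        t2 = bootstrap_support(aln, B=30, seed=9)
        assert t1.supports == t2.supports

    def test_support_increases_with_divergence(self):
        """More fixed between-clade differences -> higher separating support."""
        sup = []
        for n_fixed in (1, 30):
            seqs, _ = two_clade_sequences(n_per=4, n_fixed=n_fixed,
                                          n_private=3, seed=4)
            aln = align_haplotypes(seqs)
            tree = bootstrap_support(aln, B=50, seed=3)
            clade_b = frozenset(l for l in seqs if l.startswith("cB"))
            sup.append(tree.supports.get(clade_b, 0.0))
        assert sup[0] < sup[1]
        assert all(0 <= s <= 100 for s in sup)

    def test_newick_includes_supports(self):
        seqs, _ = two_clade_sequences(n_per=3, seed=6)
        aln = align_haplotypes(seqs)
        tree = bootstrap_support(aln, B=20, seed=1)
        nwk = tree.to_newick(with_supports=True)
        assert nwk.endswith(";")
        assert ")100:" in nwk or ")100;" in nwk


# ---------------------------------------------------------------------------
# strain assignment
# ---------------------------------------------------------------------------


def _reference_from(seqs, strains, labels):
    return ReferenceHaplotypeSet(
        entries=tuple((l, seqs[l], strains[l]) for l in labels)
    )


class TestStrainAssignment:
    def test_query_identical_to_reference(self):
        seqs, strains = two_clade_sequences(n_per=3, seed=7)
        ref = _reference_from(seqs, strains, sorted(seqs))
        res = assign_strain_group(seqs["cA00"], ref)
        assert res.strain == "C"
        assert res.nearest_C_dist == 0.0

    def test_equidistant_query_unassigned(self):
        ref = ReferenceHaplotypeSet(
            entries=(("c1", "AAAAAAAAAAAAAAAAAAAA", "C"),
                     ("r1", "AAAAAAAAAAAAAAAAAACC", "R"))
        )
        # one mismatch to each reference
        res = assign_strain_group("AAAAAAAAAAAAAAAAAAAC", ref, k=1)
        assert res.strain == "unassigned"
        assert res.nearest_C_dist == pytest.approx(res.nearest_R_dist)

    def test_held_out_clade_queries_all_assigned_correctly(self):
        seqs, strains = two_clade_sequences(n_per=8, seed=8)
        ref_labels = [l for l in sorted(seqs) if l[2:] in
                      ("00", "01", "02", "03")]
        ref = _reference_from(seqs, strains, ref_labels)
        held_out = [l for l in sorted(seqs) if l not in ref_labels]
        for lab in held_out:
            res = assign_strain_group(seqs[lab], ref)
            assert res.strain == strains[lab], lab

    def test_single_strain_reference_rejected(self):
        ref = ReferenceHaplotypeSet(entries=(("c1", "ACGTACGTACGTACGT", "C"),))
        with pytest.raises(ValueError, match="per strain"):
            assign_strain_group("ACGTACGTACGTACGT", ref)
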
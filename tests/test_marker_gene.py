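"""16S identity, taxonomy thresholds, OTU clustering and neighbor joining."""

import io
import itertools

import numpy as np
import pytest

from spectyper import marker_gene as mg
from spectyper import synthetic as syn


def _tip_distances(newick):
    skbio = pytest.importorskip("skbio")
    tree = skbio.TreeNode.read(io.StringIO(newick), convert_underscores=False)
    return tree.tip_tip_distances()


# ---------------------------------------------------------------------------
# Pairwise identity


def test_identical_sequences_identity_100(rng):
    s = syn.simulate_16s([0], rng, length=300)[0]
    assert mg.pairwise_identity(s, s) == pytest.approx(100.0)


def test_two_substitutions_in_100_bases(rng):
    a = syn.simulate_16s([0], rng, length=100)[0]
    b = mg.Seq16S("b", a.sequence[:50] + _flip(a.sequence[50]) +
                  a.sequence[51:99] + _flip(a.sequence[99]))
    assert mg.pairwise_identity(a, b) == pytest.approx(98.0)


def _flip(base):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


def test_identity_is_symmetric(rng):
    a, b = syn.simulate_16s([0, 15], rng, length=500)
    assert mg.pairwise_identity(a, b) == pytest.approx(mg.pairwise_identity(b, a))


def test_reverse_complement_auto_flip(rng):
    from Bio.Seq import Seq

    a = syn.simulate_16s([0], rng, length=400)[0]
    rc = mg.Seq16S("rc", str(Seq(a.sequence).reverse_complement()))
    ident = mg.pairwise_identity(a, rc)
    assert ident == pytest.approx(100.0)
    assert mg.pairwise_identity(a, rc, check_orientation=False) < 60.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        mg.pairwise_identity("ACGT", "")


# ---------------------------------------------------------------------------
# Taxonomy thresholds


def test_classification_levels(rng):
    refs_seqs = syn.simulate_16s([0], rng, length=1000, ids=["Bacillus_refus_T"])
    ref = refs_seqs[0]

    def with_identity(n_subs, name):
        return mg.Seq16S(name, syn._mutate(ref.sequence, n_subs,
                                           np.random.default_rng(5)))

    exact = mg.classify_16s(ref, [ref])
    assert exact.level == "species" and exact.percent_identity == 100.0
    genus = mg.classify_16s(with_identity(40, "q96"), [ref])  # 96.0 %
    assert genus.percent_identity == pytest.approx(96.0)
    assert genus.level == "genus"
    unclassified = mg.classify_16s(with_identity(60, "q94"), [ref])  # 94.0 %
    assert unclassified.percent_identity == pytest.approx(94.0)
    assert unclassified.level == "unclassified"


def test_classification_boundaries(rng):
    ref = syn.simulate_16s([0], rng, length=1000, ids=["ref"])[0]
    q987 = mg.Seq16S("q", syn._mutate(ref.sequence, 13, rng))  # 98.7 %
    assert mg.classify_16s(q987, [ref]).level == "species"
    q95 = mg.Seq16S("q", syn._mutate(ref.sequence, 50, rng))  # 95.0 %
    assert mg.classify_16s(q95, [ref]).level == "unclassified"  # strict > 95


def test_classification_tie_break_lexicographic(rng):
    q = syn.simulate_16s([0], rng, length=400, ids=["q"])[0]
    refs = [mg.Seq16S("zeb", q.sequence), mg.Seq16S("abc", q.sequence)]
    assert mg.classify_16s(q, refs).best_ref_id == "abc"


def test_classify_empty_refs_rejected(rng):
    q = syn.simulate_16s([0], rng, length=100)[0]
    with pytest.raises(ValueError):
        mg.classify_16s(q, [])


# ---------------------------------------------------------------------------
# OTU clustering


def test_identical_sequences_form_one_otu(rng):
    base = syn.simulate_16s([0], rng, length=300)[0]
    seqs = [mg.Seq16S(f"s{i}", base.sequence) for i in range(5)]
    otus = mg.cluster_otus(seqs)
    assert len(otus.clusters) == 1
    assert sorted(otus.clusters[0]) == [f"s{i}" for i in range(5)]


def test_two_otus_from_three_sequences(rng):
    a = syn.simulate_16s([0], rng, length=1000, ids=["A"])[0]
    b = mg.Seq16S("B", syn._mutate(a.sequence, 5, rng))    # 99.5 % to A
    c = mg.Seq16S("C", syn._mutate(a.sequence, 100, rng))  # ~90 % to both
    otus = mg.cluster_otus([a, b, c], similarity=0.99)
    assert sorted(map(sorted, otus.clusters)) == [["A", "B"], ["C"]]


def test_representative_minimizes_total_distance(rng):
    # B sits between A and C, so B minimizes the summed distance
    a = syn.simulate_16s([0], rng, length=1000, ids=["A"])[0]
    b = mg.Seq16S("B", syn._mutate(a.sequence, 4, rng))
    c = mg.Seq16S("C", syn._mutate(b.sequence, 4, rng))
    otus = mg.cluster_otus([a, b, c], similarity=0.98)
    assert len(otus.clusters) == 1
    # oracle: brute force over members
    seqs = {s.id: s for s in (a, b, c)}
    def total(x):
        return sum(100 - mg.pairwise_identity(seqs[x], seqs[y])
                   for y in seqs if y != x)
    best = min(seqs, key=lambda x: (total(x), x))
    assert otus.representatives[0] == best


def test_otu_similarity_extremes(rng):
    a = syn.simulate_16s([0], rng, length=500, ids=["A"])[0]
    b = mg.Seq16S("B", syn._mutate(a.sequence, 25, rng))
    c = mg.Seq16S("C", a.sequence)
    one_per_unique = mg.cluster_otus([a, b, c], similarity=1.0)
    assert len(one_per_unique.clusters) == 2
    single = mg.cluster_otus([a, b, c], similarity=0.0)
    assert len(single.clusters) == 1


# ---------------------------------------------------------------------------
# Neighbor joining


def test_nj_three_taxon_closed_form():
    D = np.array([[0.0, 2.0, 3.0],
                  [2.0, 0.0, 3.0],
                  [3.0, 3.0, 0.0]])
    newick = mg.nj_tree(D, ["A", "B", "C"])
    dm = _tip_distances(newick)
    assert dm["A", "B"] == pytest.approx(2.0)
    assert dm["A", "C"] == pytest.approx(3.0)
    assert dm["B", "C"] == pytest.approx(3.0)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:1)); -> additive distances
    D = np.array([
        [0.0, 3.0, 5.0, 3.0],
        [3.0, 0.0, 6.0, 4.0],
        [5.0, 6.0, 0.0, 4.0],
        [3.0, 4.0, 4.0, 0.0],
    ])
    labels = ["A", "B", "C", "D"]
    dm = _tip_distances(mg.nj_tree(D, labels))
    for i, j in itertools.combinations(range(4), 2):
        assert dm[labels[i], labels[j]] == pytest.approx(D[i, j])


def test_nj_matches_independent_implementation(rng):
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    n = 6
    coords = rng.uniform(0, 1, size=(n, 4))
    D = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    labels = [f"t{i}" for i in range(n)]
    ours = _tip_distances(mg.nj_tree(D, labels))
    ref = skbio_nj(DistanceMatrix(D, labels)).tip_tip_distances()
    for i, j in itertools.combinations(labels, 2):
        assert ours[i, j] == pytest.approx(ref[i, j], abs=1e-9)


def test_nj_zero_matrix_star_tree():
    D = np.zeros((4, 4))
    newick = mg.nj_tree(D, list("ABCD"))
    dm = _tip_distances(newick)
    assert np.allclose(dm.data, 0.0)


def test_nj_rejects_invalid_matrices():
    with pytest.raises(ValueError):
        mg.nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])
    bad = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
    with pytest.raises(ValueError):
        mg.nj_tree(bad, ["A", "B", "C"])


# ---------------------------------------------------------------------------
# FASTA round trip


def test_fasta_round_trip(tmp_path, rng):
    seqs = syn.simulate_16s([0, 3, 10], rng, length=250,
                            ids=["a", "b", "c"])
    path = tmp_path / "seqs.fasta"
    mg.write_fasta(seqs, path)
    back = mg.read_fasta(path)
    assert [(s.id, s.sequence) for s in back] == \
        [(s.id, s.sequence) for s in seqs]
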
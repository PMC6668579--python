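import numpy as np
import pytest
from Bio.Align import substitution_matrices

from helpers import (
    additive_tree_matrix_4taxa,
    additive_tree_matrix_5taxa,
    enumerate_global_alignments_score,
)
from episcope import synthetic as syn
from episcope.errors import InputError
from episcope.sequences import (
    build_residue_map,
    distance_matrix,
    global_align,
    map_residue,
    nj_tree,
    percent_identity,
    protein_mass,
    recompute_score,
)


def test_identical_sequences_align_without_gaps():
    r = global_align("ACDEFGHIKL", "ACDEFGHIKL")
    assert r.n_identical == 10
    assert all(a is not None and b is not None for a, b in r.aligned_columns)
    assert percent_identity(r) == 100.0


def test_single_gap_alignment_matches_enumeration_oracle():
    mat = substitution_matrices.load("BLOSUM62")
    r = global_align("ACDEFG", "ACEFG")
    oracle = enumerate_global_alignments_score("ACDEFG", "ACEFG", mat, 10.0, 0.5)
    assert r.score == pytest.approx(oracle)
    gaps = [(a, b) for a, b in r.aligned_columns if a is None or b is None]
    assert len(gaps) == 1  # one single-residue gap


@pytest.mark.parametrize("seed", range(6))
def test_tiny_alignments_match_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    mat = substitution_matrices.load("BLOSUM62")
    a = "".join(rng.choice(list(syn.AMINO_ACIDS), rng.integers(3, 7)))
    b = "".join(rng.choice(list(syn.AMINO_ACIDS), rng.integers(3, 7)))
    r = global_align(a, b)
    oracle = enumerate_global_alignments_score(a, b, mat, 10.0, 0.5)
    assert r.score == pytest.approx(oracle)
    assert recompute_score(r) == pytest.approx(r.score)


def test_percent_identity_denominators():
    # 5 identities over 10 non-gap columns, constructed by hand
    a, b = "AAAAACCCCC", "AAAAADDDDD"
    r = global_align(a, b)
    assert r.n_identical == 5
    assert percent_identity(r, "aligned_columns_nongap") == 50.0
    assert percent_identity(r, "shorter_seq") == 50.0
    with pytest.raises(InputError):
        percent_identity(r, "bogus")


def test_percent_identity_symmetric():
    seqs, _ = syn.make_sequence_family("(a:0.1,b:0.1);", length=120, seed=3)
    fwd = percent_identity(global_align(seqs["a"], seqs["b"]))
    rev = percent_identity(global_align(seqs["b"], seqs["a"]))
    assert fwd == pytest.approx(rev, abs=1e-9)


def test_x_never_counts_identical():
    r = global_align("AXA", "AXA")
    assert r.n_identical == 2


def test_residue_map_tracks_insertion_offsets(anchor_like_sequence):
    # homolog with 7 extra residues inserted before the catalytic Tyr:
    # anchor position 150 must map to homolog position 157
    anchor = anchor_like_sequence
    homolog = anchor[:130] + "GGSGGSG" + anchor[130:]
    r = global_align(anchor, homolog, ids=("anchor", "homolog"))
    m = build_residue_map(r)
    assert map_residue(m, 150) == 157
    assert map_residue(m, 299) == 306
    assert map_residue(m, 85) == 85
    assert m.anchor_residues[150] == "Y"


def test_residue_map_reports_deletions_as_absent(anchor_like_sequence):
    anchor = anchor_like_sequence
    homolog = anchor[:195] + anchor[205:]  # positions 196-205 deleted
    r = global_align(anchor, homolog)
    m = build_residue_map(r)
    assert map_residue(m, 200) is None
    assert map_residue(m, 150) == 150


def test_protein_mass_known_values():
    assert protein_mass("G") == pytest.approx(75.07, abs=0.01)
    assert protein_mass("GG") == pytest.approx(132.12, abs=0.01)


def test_protein_mass_additivity():
    water = 18.02
    for s1, s2 in [("ACDEF", "GHIKL"), ("WY", "MNPQ")]:
        assert protein_mass(s1 + s2) == pytest.approx(
            protein_mass(s1) + protein_mass(s2) - water, abs=0.02)


def test_distance_matrix_basics():
    seqs = {"a": "ACDEFGHIKL", "b": "ACDEFGHIKL", "c": "ACDEFGHIKW"}
    d, ids = distance_matrix(seqs)
    assert np.allclose(np.diag(d), 0.0)
    assert d[ids.index("a"), ids.index("b")] == 0.0
    assert d[ids.index("a"), ids.index("c")] == pytest.approx(0.1)
    assert np.allclose(d, d.T)


def test_nj_exact_on_additive_4_taxa():
    d, ids, split = additive_tree_matrix_4taxa()
    phy = nj_tree(d, ids)
    assert split in set(phy.clade_leaf_sets()) or \
        frozenset(set(ids) - split) in set(phy.clade_leaf_sets())
    pat, pids = phy.tip_to_tip()
    order = [pids.index(i) for i in ids]
    np.testing.assert_allclose(pat[np.ix_(order, order)], d, atol=1e-9)


def test_nj_exact_on_additive_5_taxa():
    d, ids, splits = additive_tree_matrix_5taxa()
    phy = nj_tree(d, ids)
    found = set(phy.clade_leaf_sets())
    for s in splits:
        assert s in found or frozenset(set(ids) - s) in found
    pat, pids = phy.tip_to_tip()
    order = [pids.index(i) for i in ids]
    np.testing.assert_allclose(pat[np.ix_(order, order)], d, atol=1e-9)


def test_nj_recovers_simulated_topology():
    newick = "((A:0.06,B:0.06):0.05,(C:0.06,D:0.06):0.05,(E:0.06,F:0.06):0.05);"
    seqs, man = syn.make_sequence_family(newick, length=500, seed=17)
    d, ids = distance_matrix(seqs)
    phy = nj_tree(d, ids)
    found = set(phy.clade_leaf_sets())
    for pair in ({"A", "B"}, {"C", "D"}, {"E", "F"}):
        fs = frozenset(pair)
        assert fs in found or frozenset(set(ids) - pair) in found


def test_nj_input_validation():
    d = np.array([[0, 1.0], [1.0, 0]])
    with pytest.raises(InputError):
        nj_tree(d, ["a", "b"])  # too few taxa
    bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
    with pytest.raises(InputError):
        nj_tree(bad, ["a", "b", "c"])  # asymmetric


def test_empty_sequence_rejected():
    with pytest.raises(InputError):
        global_align("", "ACD")
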
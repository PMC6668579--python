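import numpy as np
import pytest

from helpers import bruteforce_rmsd, rmsd_under_random_rotations
from episcope import synthetic as syn
from episcope.errors import (
    ConvergenceError,
    DegenerateGeometryError,
    InsufficientPairsError,
)
from episcope.sequences import AlignmentResult, global_align
from episcope.structure_io import chain_one_letter
from episcope.superposition import (
    PairedCoordinates,
    kabsch_fit,
    pair_calpha_by_alignment,
    rmsd_no_cutoff,
    trimmed_superpose,
)


def test_exact_rigid_copy_has_zero_rmsd():
    p, _ = syn.make_paired_cloud(n=30, noise_sd=0.0, seed=1)
    fit = kabsch_fit(p)
    assert fit.rmsd == pytest.approx(0.0, abs=1e-6)
    assert fit.n_pairs_used == 30 and fit.retained.all()


def test_rotation_is_proper_orthonormal():
    for seed in range(5):
        p, _ = syn.make_paired_cloud(n=20, noise_sd=0.8, seed=seed)
        r = kabsch_fit(p).rotation
        assert np.linalg.norm(r.T @ r - np.eye(3)) < 1e-8
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


def test_square_with_displaced_corner_matches_oracle():
    a = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    b = a.copy()
    b[2, 2] = 1.0  # one corner lifted 1 A out of plane
    fit = kabsch_fit(PairedCoordinates(a, b))
    oracle = bruteforce_rmsd(a, b)
    assert fit.rmsd == pytest.approx(oracle, abs=1e-4)


@pytest.mark.parametrize("seed", range(5))
def test_noisy_cloud_matches_oracle_and_dominates_random_rotations(seed):
    p, _ = syn.make_paired_cloud(n=50, noise_sd=0.5, seed=seed)
    fit = kabsch_fit(p)
    oracle = bruteforce_rmsd(p.coords_a, p.coords_b, seed=seed)
    assert fit.rmsd == pytest.approx(oracle, abs=0.1)
    randoms = rmsd_under_random_rotations(p.coords_a, p.coords_b, n=200, seed=seed)
    assert fit.rmsd <= randoms.min() + 1e-9


def test_rmsd_symmetry():
    p, _ = syn.make_paired_cloud(n=25, noise_sd=0.6, seed=9)
    forward = rmsd_no_cutoff(p)
    backward = rmsd_no_cutoff(PairedCoordinates(p.coords_b, p.coords_a))
    assert forward == pytest.approx(backward, abs=1e-6)


def test_degenerate_inputs():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateGeometryError):
        kabsch_fit(PairedCoordinates(line, line + 1.0))
    with pytest.raises(InsufficientPairsError):
        kabsch_fit(PairedCoordinates(line[:2], line[:2]))


def test_trimming_identity_when_all_within_cutoff():
    p, _ = syn.make_paired_cloud(n=30, noise_sd=0.2, seed=2)
    plain = kabsch_fit(p)
    trimmed = trimmed_superpose(p, cutoff=2.0)
    assert trimmed.n_pairs_used == 30
    assert trimmed.rmsd == pytest.approx(plain.rmsd, abs=1e-9)


def test_trimming_recovers_planted_outliers():
    p, man = syn.make_paired_cloud(n=25, noise_sd=0.2, n_outliers=5,
                                   outlier_shift=5.0, seed=3)
    t = trimmed_superpose(p, cutoff=2.0)
    dropped = set(np.where(~t.retained)[0].tolist())
    assert dropped == set(man["outlier_indices"])
    clean = p.subset(t.retained)
    assert t.rmsd == pytest.approx(kabsch_fit(clean).rmsd, abs=1e-9)
    assert t.rmsd == pytest.approx(
        bruteforce_rmsd(clean.coords_a, clean.coords_b), abs=0.05)


@pytest.mark.parametrize("seed", range(4))
def test_trimmed_rmsd_never_exceeds_untrimmed(seed):
    p, _ = syn.make_paired_cloud(n=40, noise_sd=1.0, n_outliers=6,
                                 outlier_shift=6.0, seed=seed)
    t = trimmed_superpose(p, cutoff=2.0)
    assert t.rmsd <= rmsd_no_cutoff(p) + 1e-12
    assert t.converged
    assert np.all(t.per_pair_dev[t.retained] <= 2.0 + 1e-9)


def test_trimming_collapse_raises():
    rng = np.random.default_rng(0)
    a = rng.uniform(-10, 10, (8, 3))
    b = rng.uniform(-10, 10, (8, 3))  # unrelated clouds: nothing survives 0.01 A
    with pytest.raises(ConvergenceError):
        trimmed_superpose(PairedCoordinates(a, b), cutoff=0.01)


def test_pair_calpha_identity_alignment():
    pep = syn.make_toy_peptide(n_res=8, seed=0)
    seq, _ = chain_one_letter(pep, "A")
    aln = global_align(seq, seq)
    pairs = pair_calpha_by_alignment(pep, pep, aln)
    assert len(pairs) == 8
    assert kabsch_fit(pairs).rmsd == pytest.approx(0.0, abs=1e-9)


def test_pair_calpha_counts_nongap_columns_only():
    pep = syn.make_toy_peptide(n_res=10, seed=0)
    cols = [(i, i) for i in range(4)] + [(4, None), (None, 4)] \
        + [(i, i) for i in range(5, 10)]
    aln = AlignmentResult(("a", "b"), "A" * 10, "A" * 10, cols,
                          n_identical=9, score=0.0)
    pairs = pair_calpha_by_alignment(pep, pep, aln)
    assert len(pairs) == 9  # 10 residues, one gapped column per chain


def test_pair_calpha_respects_planted_correspondence(anchor_like_sequence):
    seqs, _ = syn.make_sequence_family("(x:0.05,y:0.05);", length=40, seed=5)
    # structures that share residue layout; the alignment of two equal-length
    # divergent sequences is the identity mapping here
    pep = syn.make_toy_peptide(n_res=40, seed=0)
    aln = global_align(seqs["x"], seqs["y"])
    pairs = pair_calpha_by_alignment(pep, pep, aln)
    assert len(pairs) == sum(1 for a, b in aln.aligned_columns
                             if a is not None and b is not None)
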
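"""Pairwise global alignment, residue mapping, protein mass, and NJ phylogeny.

Alignment is Needleman-Wunsch with affine gaps (BLOSUM62, open 10 / extend
0.5 by default) via Biopython's PairwiseAligner; identities are reported with
a selectable denominator because published percent-identity figures rarely
state one.  Cross-homolog residue maps are derived from the non-gap aligned
columns so functional positions (catalytic triad, C2/C5 pocket residues) can
be transferred between numbering schemes.  Trees are neighbor joining on
1 - fractional-identity distances, emitted as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils import molecular_weight

from episcope.errors import InputError

DEFAULT_ALIGN_PARAMS = {"matrix": "BLOSUM62", "gap_open": 10.0, "gap_extend": 0.5}


@dataclass
class AlignmentResult:
    """A pairwise global alignment as explicit columns.

    ``aligned_columns`` holds one entry per alignment column:
    (0-based position in A or None, 0-based position in B or None).
    """

    seq_ids: tuple[str, str]
    seq_a: str
    seq_b: str
    aligned_columns: list[tuple[int | None, int | None]]
    n_identical: int
    score: float
    params: dict = field(default_factory=dict)

    @property
    def n_nongap_columns(self) -> int:
        return sum(1 for a, b in self.aligned_columns if a is not None and b is not None)


def global_align(a: str, b: str, params: dict | None = None,
                 ids: tuple[str, str] = ("A", "B")) -> AlignmentResult:
    """Optimal global alignment under affine gap penalties.

    ``params``: matrix id (default BLOSUM62), gap_open and gap_extend as
    positive penalties.  Ties are broken deterministically by taking the
    aligner's first (high-road) traceback.  'X' residues are tolerated but
    never counted as identical.
    """
    if not a or not b:
        raise InputError("sequences must be non-empty")
    p = dict(DEFAULT_ALIGN_PARAMS)
    if params:
        p.update(params)
    a, b = a.upper(), b.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(p["matrix"])
    aligner.open_gap_score = -float(p["gap_open"])
    aligner.extend_gap_score = -float(p["gap_extend"])
    aln = aligner.align(a, b)[0]
    columns = _columns_from_aligned_blocks(aln.aligned, len(a), len(b))
    n_ident = sum(
        1 for ia, ib in columns
        if ia is not None and ib is not None and a[ia] == b[ib] and a[ia] != "X"
    )
    return AlignmentResult(
        seq_ids=ids, seq_a=a, seq_b=b, aligned_columns=columns,
        n_identical=n_ident, score=float(aln.score), params=p,
    )


def _columns_from_aligned_blocks(aligned, len_a: int, len_b: int):
    """Expand Biopython's matched-block representation into full columns.

    Unaligned stretches between blocks are emitted as gap columns, A-side
    first then B-side (a deterministic convention; column order within a
    stretch does not affect scores or identity)."""
    cols: list[tuple[int | None, int | None]] = []
    pa = pb = 0
    blocks_a, blocks_b = aligned
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        while pa < sa:
            cols.append((pa, None)); pa += 1
        while pb < sb:
            cols.append((None, pb)); pb += 1
        for i in range(ea - sa):
            cols.append((sa + i, sb + i))
        pa, pb = ea, eb
    while pa < len_a:
        cols.append((pa, None)); pa += 1
    while pb < len_b:
        cols.append((None, pb)); pb += 1
    return cols


def recompute_score(r: AlignmentResult) -> float:
    """Score of the reported columns under the result's own parameters.

    Used as a consistency check: must equal ``r.score``.  Gap penalty
    convention follows the aligner: the first residue of a gap costs
    ``gap_open``, each further residue ``gap_extend``.
    """
    mat = substitution_matrices.load(r.params["matrix"])
    open_pen, ext_pen = float(r.params["gap_open"]), float(r.params["gap_extend"])
    score = 0.0
    gap_a = gap_b = False
    for ia, ib in r.aligned_columns:
        if ia is not None and ib is not None:
            score += mat[r.seq_a[ia], r.seq_b[ib]]
            gap_a = gap_b = False
        elif ia is None:  # gap in A
            score -= ext_pen if gap_a else open_pen
            gap_a, gap_b = True, False
        else:  # gap in B
            score -= ext_pen if gap_b else open_pen
            gap_b, gap_a = True, False
    return score


def percent_identity(r: AlignmentResult,
                     denominator: str = "aligned_columns_nongap") -> float:
    """100 * identities / denominator.

    denominator: 'aligned_columns_nongap' (columns with both residues
    present, the default), 'shorter_seq', or 'alignment_length'.
    """
    if denominator == "aligned_columns_nongap":
        denom = r.n_nongap_columns
    elif denominator == "shorter_seq":
        denom = min(len(r.seq_a), len(r.seq_b))
    elif denominator == "alignment_length":
        denom = len(r.aligned_columns)
    else:
        raise InputError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return 0.0
    return 100.0 * r.n_identical / denom


@dataclass
class ResidueMap:
    """Anchor-position -> homolog-position lookup from an alignment.

    Positions are in each sequence's own (author) numbering; only non-gap
    aligned columns contribute.
    """

    anchor_id: str
    homolog_id: str
    mapping: dict[int, int]
    anchor_residues: dict[int, str] = field(default_factory=dict)
    homolog_residues: dict[int, str] = field(default_factory=dict)


def build_residue_map(r: AlignmentResult,
                      anchor_numbers: list[int] | None = None,
                      homolog_numbers: list[int] | None = None) -> ResidueMap:
    """Residue correspondence from alignment columns.

    ``anchor_numbers``/``homolog_numbers`` translate 0-based sequence indices
    into author numbering (e.g. from structure residues); default 1-based.
    """
    na = anchor_numbers or list(range(1, len(r.seq_a) + 1))
    nb = homolog_numbers or list(range(1, len(r.seq_b) + 1))
    if len(na) != len(r.seq_a) or len(nb) != len(r.seq_b):
        raise InputError("numbering lists must match sequence lengths")
    mapping, ares, hres = {}, {}, {}
    for ia, ib in r.aligned_columns:
        if ia is None or ib is None:
            continue
        mapping[na[ia]] = nb[ib]
        ares[na[ia]] = r.seq_a[ia]
        hres[nb[ib]] = r.seq_b[ib]
    return ResidueMap(anchor_id=r.seq_ids[0], homolog_id=r.seq_ids[1],
                      mapping=mapping, anchor_residues=ares, homolog_residues=hres)


def map_residue(m: ResidueMap, anchor_pos: int) -> int | None:
    """Homolog position equivalent to an anchor position, or None if gapped."""
    return m.mapping.get(anchor_pos)


def protein_mass(seq: str) -> float:
    """Average-isotopic mass in Da of a peptide (residue masses + one water)."""
    if not seq:
        raise InputError("empty sequence")
    return float(molecular_weight(seq.upper(), seq_type="protein", monoisotopic=False))


def distance_matrix(seqs: dict[str, str], params: dict | None = None,
                    kimura: bool = False) -> tuple[np.ndarray, list[str]]:
    """Pairwise distances d = 1 - fractional identity (optionally
    Kimura-corrected, d = -ln(1 - p - 0.2 p^2)) from global alignments."""
    ids = list(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = global_align(seqs[ids[i]], seqs[ids[j]], params, (ids[i], ids[j]))
            p = 1.0 - r.n_identical / max(r.n_nongap_columns, 1)
            if kimura:
                arg = 1.0 - p - 0.2 * p * p
                p = -np.log(max(arg, 1e-6))
            d[i, j] = d[j, i] = p
    return d, ids


@dataclass
class Phylogeny:
    """Unrooted NJ tree with branch lengths in divergence units."""

    tree: object  # skbio.TreeNode
    leaves: list[str]
    negative_branches_clamped: bool = False

    @property
    def newick(self) -> str:
        return str(self.tree).strip()

    def tip_to_tip(self) -> tuple[np.ndarray, list[str]]:
        """Patristic (path-length) distance matrix over the leaves."""
        dm = self.tree.tip_tip_distances()
        ids = list(dm.ids)
        return np.asarray(dm.data), ids

    def clade_leaf_sets(self) -> list[frozenset]:
        """Leaf bipartitions induced by internal edges (topology fingerprint)."""
        all_leaves = frozenset(self.leaves)
        parts = set()
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_leaves) - 1:
                parts.add(min(side, all_leaves - side, key=sorted))
        return sorted(parts, key=sorted)


def nj_tree(d: np.ndarray, ids: list[str]) -> Phylogeny:
    """Neighbor joining on a symmetric zero-diagonal distance matrix.

    Negative branch-length estimates are clamped to zero (standard practice),
    with the event flagged on the result.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or len(ids) != d.shape[0]:
        raise InputError("distance matrix must be square and match ids")
    if d.shape[0] < 3:
        raise InputError("need >= 3 taxa")
    if np.max(np.abs(d - d.T)) > 1e-8:
        raise InputError("distance matrix is asymmetric beyond tolerance")
    if np.max(np.abs(np.diag(d))) > 1e-12:
        raise InputError("distance matrix diagonal must be zero")
    dm = DistanceMatrix(d, ids)

    def _nj(clamp: bool):
        try:
            return nj(dm, neg_as_zero=clamp)
        except TypeError:  # scikit-bio < 0.6.3
            return nj(dm, disallow_negative_branch_length=clamp)

    raw = _nj(False)
    clamped = any(n.length is not None and n.length < -1e-12 for n in raw.traverse())
    tree = _nj(True) if clamped else raw
    return Phylogeny(tree=tree, leaves=list(ids), negative_branches_clamped=clamped)
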
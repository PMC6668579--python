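"""Seeded generators for every fixture the analysis needs.

Each generator returns the fixture plus a manifest recording the planted
ground truth (realized coordinates, planted distances, true tree ...), so
tests can check results against exact oracles without reaching into the
generator at run time.  All randomness flows through numpy's PCG64
``default_rng``; the same seed reproduces the fixture byte-for-byte.

The toy ternary complex deserves a note: it is an idealized arrangement — a
planar six-ring standing in for the nicotinamide of NAD+, a pyranose-like
ring with C4/O4/C2 substituent atoms, a Tyr-like hydroxyl and an Asn-like
carboxamide — built at prescribed geometry (C4-C4 distance, ring face, swing
rotamer).  Geometry operations read only atom names and coordinates, so the
idealization is harmless while making every expected value exact.
"""

from __future__ import annotations

import io

import numpy as np

from episcope.structure_io import AtomRecord, ResidueRecord, Structure


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _atom(name: str, element: str, coords) -> AtomRecord:
    return AtomRecord(name=name, element=element, coords=np.asarray(coords, float))


def make_toy_peptide(n_res: int = 3, seed: int = 0) -> Structure:
    """A small poly-Ala pseudo-helix (N, CA, C, O, CB per residue).

    CA positions follow an ideal helix (rise 1.5 A, 100 degrees per residue,
    radius 2.3 A), so they are never collinear for n_res >= 3.
    """
    rng = _rng(seed)
    residues = []
    for i in range(n_res):
        ang = np.radians(100.0 * i)
        ca = np.array([1.5 * i, 2.3 * np.cos(ang), 2.3 * np.sin(ang)])
        atoms = [
            _atom("N", "N", ca + [-1.20, 0.60, 0.45]),
            _atom("CA", "C", ca),
            _atom("C", "C", ca + [1.25, 0.55, -0.40]),
            _atom("O", "O", ca + [1.35, 1.75, -0.55]),
            _atom("CB", "C", ca + [-0.30, -1.30, 0.75]),
        ]
        residues.append(ResidueRecord(
            name="ALA", seq_number=i + 1, icode="", chain_id="A", atoms=atoms,
        ))
    del rng  # layout is deterministic; rng reserved for future jitter
    return Structure(id=f"toy_peptide_{n_res}", chains={"A": residues})


def make_rotated_copy(base: Structure, rotation: np.ndarray | None = None,
                      translation: np.ndarray | None = None,
                      noise_sd: float = 0.0, seed: int = 0,
                      ) -> tuple[Structure, dict]:
    """Rigidly transformed (and optionally Gaussian-perturbed) copy of a
    structure, with the realized coordinates recorded in the manifest."""
    rng = _rng(seed)
    rot = rotation if rotation is not None else random_rotation(rng)
    trans = (np.asarray(translation, float) if translation is not None
             else rng.uniform(-20, 20, 3))
    chains = {}
    displacements = []
    for cid, rs in base.chains.items():
        new_rs = []
        for r in rs:
            atoms = []
            for a in r.atoms:
                moved = rot @ a.coords + trans
                noise = rng.normal(0.0, noise_sd, 3) if noise_sd > 0 else np.zeros(3)
                atoms.append(_atom(a.name, a.element, moved + noise))
                displacements.append(noise.tolist())
            new_rs.append(ResidueRecord(
                name=r.name, seq_number=r.seq_number, icode=r.icode,
                chain_id=cid, atoms=atoms, is_het=r.is_het, is_water=r.is_water,
            ))
        chains[cid] = new_rs
    copy = Structure(id=base.id + "_moved", chains=chains)
    manifest = {
        "rotation": rot.tolist(), "translation": trans.tolist(),
        "noise_sd": noise_sd, "seed": seed, "noise": displacements,
    }
    return copy, manifest


def make_paired_cloud(n: int = 50, noise_sd: float = 0.0, n_outliers: int = 0,
                      outlier_shift: float = 5.0, seed: int = 0):
    """Matched coordinate pairs: a random cloud vs its rigid copy plus noise,
    with optional planted outliers displaced by ``outlier_shift`` A.

    Returns (PairedCoordinates, manifest); the manifest carries the realized
    coordinate arrays and outlier indices so an oracle can be exact.
    """
    from episcope.superposition import PairedCoordinates

    rng = _rng(seed)
    a = rng.uniform(-10, 10, (n, 3))
    rot = random_rotation(rng)
    trans = rng.uniform(-15, 15, 3)
    b = a @ rot.T + trans
    if noise_sd > 0:
        b = b + rng.normal(0.0, noise_sd, (n, 3))
    outlier_idx = sorted(rng.choice(n, size=n_outliers, replace=False).tolist()) \
        if n_outliers else []
    for i in outlier_idx:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        b[i] += outlier_shift * direction
    pairs = PairedCoordinates(a, b)
    manifest = {
        "coords_a": a.tolist(), "coords_b": b.tolist(),
        "rotation": rot.tolist(), "translation": trans.tolist(),
        "noise_sd": noise_sd, "outlier_indices": outlier_idx,
        "outlier_shift": outlier_shift, "seed": seed,
    }
    return pairs, manifest


def make_hbond_set(distances: list[float], seed: int = 0):
    """Donor/acceptor atom groups with planted pair distances.

    Pair i sits on its own site 25 A from the others, so each planted
    distance produces at most one contact.  Returns (group_a, group_b,
    manifest).
    """
    rng = _rng(seed)
    group_a, group_b = [], []
    for i, d in enumerate(distances):
        base = np.array([25.0 * i, 0.0, 0.0]) + rng.uniform(-1, 1, 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        group_a.append(_atom("O", "O", base))
        group_b.append(_atom("N", "N", base + d * direction))
    manifest = {"distances": list(map(float, distances)), "seed": seed}
    return group_a, group_b, manifest


def make_toy_complex(c4c4: float = 3.4, face: str = "pro_S",
                     asn_rotamer: str = "in", seed: int = 0,
                     swing_in_dist: float = 3.5, swing_out_dist: float = 9.0,
                     tyr_o4_dist: float = 2.6) -> tuple[Structure, dict]:
    """Minimal ternary-complex geometry with planted measurements.

    Atoms: a planar hexagon het 'NIC' (ring N1,C2..C6) for the nicotinamide,
    a pyranose-like het 'SUG' (ring C1,C2,C3,C4,C5,O5 plus O4 and the C2
    substituent N2), Tyr150 with its OH placed ``tyr_o4_dist`` from O4, and
    Asn200 with the carboxamide centroid at ``swing_in_dist`` (rotamer "in")
    or ``swing_out_dist`` ("out") from N2.  ``face`` puts the sugar C4 on
    the pro-S or pro-R side of the nicotinamide plane.  The whole complex is
    then moved by a random rigid motion so nothing is axis-aligned.
    """
    if face not in ("pro_S", "pro_R"):
        raise ValueError(f"face must be pro_S or pro_R, got {face!r}")
    if asn_rotamer not in ("in", "out"):
        raise ValueError(f"asn_rotamer must be 'in' or 'out', got {asn_rotamer!r}")
    rng = _rng(seed)

    # nicotinamide ring in the z=0 plane, ordered counterclockwise seen from
    # +z, so the Newell normal is +z and (by package convention) +z is pro-S
    ring_names = ["N1", "C2", "C3", "C4", "C5", "C6"]
    nic_atoms = []
    for i, nm in enumerate(ring_names):
        ang = np.radians(60.0 * i)
        nic_atoms.append(_atom(nm, "N" if nm.startswith("N") else "C",
                               [1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0]))
    c4n = nic_atoms[3].coords  # at angle 180 deg

    zsign = 1.0 if face == "pro_S" else -1.0
    c4s = c4n + np.array([0.0, 0.0, zsign * c4c4])

    # sugar ring parallel to the nicotinamide plane, its C4 at the planted point
    sug_center = c4s + np.array([1.45, 0.0, 0.0])
    sug_names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    sug_atoms = []
    for i, nm in enumerate(sug_names):
        ang = np.radians(180.0 + 60.0 * (i - 3))  # index 3 (C4) at angle 180
        sug_atoms.append(_atom(nm, "O" if nm.startswith("O") else "C",
                               sug_center + [1.45 * np.cos(ang), 1.45 * np.sin(ang), 0.0]))
    o4 = c4s + np.array([-1.01, -1.01, 0.0])  # exocyclic O4 on C4
    sug_atoms.append(_atom("O4", "O", o4))
    c2s = sug_atoms[1].coords
    n2 = c2s + 1.45 * (c2s - sug_center) / np.linalg.norm(c2s - sug_center)
    sug_atoms.append(_atom("N2", "N", n2))

    # Tyr150: OH planted at tyr_o4_dist from O4, minimal carbon scaffold behind it
    oh_dir = np.array([-0.55, -0.65, 0.52 * zsign])
    oh_dir /= np.linalg.norm(oh_dir)
    oh = o4 + tyr_o4_dist * oh_dir
    cz = oh + np.array([-1.1, -0.6, 0.3])
    tyr_atoms = [
        _atom("N", "N", cz + [-3.9, -1.4, 0.6]),
        _atom("CA", "C", cz + [-2.9, -1.0, 0.4]),
        _atom("CB", "C", cz + [-2.2, -0.5, 0.2]),
        _atom("CZ", "C", cz),
        _atom("OH", "O", oh),
    ]

    # Asn200: carboxamide centroid planted relative to the sugar N2
    dist = swing_in_dist if asn_rotamer == "in" else swing_out_dist
    pocket_dir = np.array([0.25, 0.88, 0.40 * zsign])
    pocket_dir /= np.linalg.norm(pocket_dir)
    centroid = n2 + dist * pocket_dir
    half = np.array([0.62, -0.15, 0.25])
    od1, nd2 = centroid + half, centroid - half
    cg = centroid + np.array([0.1, -1.25, -0.2])
    cb = cg + np.array([-0.4, -1.40, 0.45])
    ca_ = cb + np.array([-1.1, -0.85, 0.50])
    n_ = ca_ + np.array([-1.30, 0.55, -0.25])
    asn_atoms = [
        _atom("N", "N", n_), _atom("CA", "C", ca_), _atom("CB", "C", cb),
        _atom("CG", "C", cg), _atom("OD1", "O", od1), _atom("ND2", "N", nd2),
    ]

    residues = [
        ResidueRecord("TYR", 150, "", "A", tyr_atoms),
        ResidueRecord("ASN", 200, "", "A", asn_atoms),
        ResidueRecord("NIC", 401, "", "A", nic_atoms, is_het=True),
        ResidueRecord("SUG", 402, "", "A", sug_atoms, is_het=True),
    ]
    s = Structure(id=f"toy_complex_{face}_{asn_rotamer}", chains={"A": residues})
    # random rigid motion: planted distances and face are motion-invariant
    rot = random_rotation(rng)
    trans = rng.uniform(-10, 10, 3)
    for r in s.chains["A"]:
        for a in r.atoms:
            a.coords = rot @ a.coords + trans
    manifest = {
        "c4c4": float(c4c4), "face": face, "asn_rotamer": asn_rotamer,
        "carboxamide_to_pocket": float(dist), "tyr_o4_dist": float(tyr_o4_dist),
        "seed": seed,
    }
    return s, manifest


def make_dimer_spheres(n_atoms_per_protomer: int = 1, separation: float = 3.0,
                       seed: int = 0, element: str = "C",
                       cluster_sd: float = 3.0) -> tuple[Structure, dict]:
    """Two compact atom clusters as mock protomers (chains A and B).

    With one atom per protomer the buried area has a spherical-cap closed
    form; clusters exercise the general case.  Cluster centers sit
    ``separation`` A apart along x.
    """
    rng = _rng(seed)
    chains = {}
    coords_all = {}
    for cid, center in (("A", np.zeros(3)), ("B", np.array([separation, 0.0, 0.0]))):
        if n_atoms_per_protomer == 1:
            pts = center[None, :]
        else:
            pts = center + rng.normal(0.0, cluster_sd, (n_atoms_per_protomer, 3))
        atoms = [_atom(f"C{i + 1}" if n_atoms_per_protomer > 1 else "C",
                       element, p) for i, p in enumerate(pts)]
        chains[cid] = [ResidueRecord("UNK", 1, "", cid, atoms)]
        coords_all[cid] = pts.tolist()
    s = Structure(id=f"dimer_spheres_{n_atoms_per_protomer}_{separation}", chains=chains)
    manifest = {"separation": float(separation), "coords": coords_all,
                "element": element, "seed": seed}
    return s, manifest


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def make_sequence_family(newick: str, length: int = 300, seed: int = 0,
                         ) -> tuple[dict[str, str], dict]:
    """Sequences evolved along a given tree under a uniform replacement model.

    Each branch of length b applies Poisson(b * length) substitutions, each
    at a uniform site and to a uniform different residue, so expected
    per-site divergence matches path length for short branches.  Returns
    (leaf sequences, manifest with the true newick and realized pairwise
    difference fractions).
    """
    from skbio import TreeNode

    rng = _rng(seed)
    tree = TreeNode.read(io.StringIO(newick))
    root_seq = rng.choice(list(AMINO_ACIDS), size=length)
    seqs_at = {id(tree): root_seq}
    leaves: dict[str, str] = {}

    for node in tree.preorder(include_self=True):
        if id(node) not in seqs_at:
            parent_seq = seqs_at[id(node.parent)]
            seq = parent_seq.copy()
            bl = node.length or 0.0
            n_sub = rng.poisson(bl * length)
            for _ in range(n_sub):
                site = rng.integers(length)
                current = seq[site]
                choices = [a for a in AMINO_ACIDS if a != current]
                seq[site] = choices[rng.integers(19)]
            seqs_at[id(node)] = seq
        if node.is_tip():
            leaves[node.name] = "".join(seqs_at[id(node)])

    ids = sorted(leaves)
    diffs = {}
    for i, x in enumerate(ids):
        for y in ids[i + 1:]:
            frac = sum(a != b for a, b in zip(leaves[x], leaves[y])) / length
            diffs[f"{x}|{y}"] = frac
    manifest = {"newick": newick.strip(), "length": length, "seed": seed,
                "pairwise_diff_fraction": diffs}
    return leaves, manifest


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name is not None and line:
                seqs[name] += line
    return seqs
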
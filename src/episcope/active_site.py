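"""Active-site geometry: catalytic C4-C4 distance, H-bonds, salt bridges,
sugar ring face, and the C2-pocket Asn swing conformer.

All criteria are purely geometric, heavy-atom only (the crystal structures
this targets carry no hydrogens):

* hydrogen bond: N/O/S donor-acceptor pair within ``dmax`` (3.5 A default),
  with at least one side a plausible donor by residue chemistry;
* salt bridge: basic side-chain nitrogen (Lys NZ, Arg NE/NH*, His ND1/NE2)
  within ``dmax`` (4.0 A default) of a carboxylate or phosphate oxygen;
* productive hydride-transfer geometry: sugar C4 to nicotinamide C4 within
  [3.0, 3.7] A inclusive;
* ring face: which side of the nicotinamide plane the sugar C4 occupies
  (pro-S side -> "standard" sugar conformation, pro-R -> "flipped");
* Asn swing: whether the C2-pocket Asn carboxamide sits against the sugar C2
  substituent ("swing in") or has rotated away ("swing out").
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from episcope.errors import ClassificationError, InputError, NotFoundError
from episcope.structure_io import AtomRecord, ResidueRecord, Structure, extract_ligand

HBOND_DMAX = 3.5
SALT_DMAX = 4.0
PRODUCTIVE_RANGE = (3.0, 3.7)
SWING_THRESHOLD = 5.0  # A, carboxamide centroid to C2-substituent

#: protein side-chain donor atoms (backbone N is always a donor)
_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("TRP", "NE1"),
}
_BASIC_ATOMS = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
_ACIDIC_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}
#: phosphate oxygen names used by nucleotide het groups (NAD, UDP, UDP-sugars)
_PHOSPHATE_O_NAMES = {
    "O1A", "O2A", "O3A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G",
    "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
}


@dataclass
class HBond:
    donor: AtomRecord
    acceptor: AtomRecord
    distance: float
    donor_label: str = ""
    acceptor_label: str = ""


@dataclass
class SaltBridge:
    basic_atom: AtomRecord
    acidic_atom: AtomRecord
    distance: float
    basic_label: str = ""
    acidic_label: str = ""


@dataclass
class CatalyticGeometry:
    """Hydride-transfer geometry of a ternary complex."""

    c4_sugar: AtomRecord
    c4_nicotinamide: AtomRecord
    distance: float
    productive: bool
    o4_tyr_oh_distance: float | None = None


@dataclass
class ConformerCalls:
    ring_face: str  # "standard" | "flipped"
    asn_swing: str  # "swing_in" | "swing_out"
    chi1: float  # degrees
    chi2: float
    carboxamide_to_pocket: float  # A


@dataclass
class LigandRoles:
    """Maps ligand roles to het codes and the atom names geometry needs.

    Chemical-component dictionaries name the nicotinamide ring N1N..C6N in
    NAD and the sugar atoms C1'..O6' in UDP-sugars; toy fixtures use plain
    names.  Everything is overridable so the same operations serve both.
    """

    nicotinamide_code: str = "NAD"
    nicotinamide_ring: tuple[str, ...] = ("N1N", "C2N", "C3N", "C4N", "C5N", "C6N")
    nicotinamide_c4: str = "C4N"
    sugar_code: str = "UPG"
    sugar_c4: str = "C4'"
    sugar_o4: str = "O4'"
    sugar_c2_substituent: str = "O2'"
    tyr_resnum: int = 150
    asn_resnum: int = 200
    chain_id: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "LigandRoles":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise InputError(f"unknown ligand-role keys: {sorted(extra)}")
        d = dict(d)
        if "nicotinamide_ring" in d:
            d["nicotinamide_ring"] = tuple(d["nicotinamide_ring"])
        return cls(**d)

    def replace(self, **kw) -> "LigandRoles":
        return replace(self, **kw)


#: roles preset for the synthetic toy ternary complexes
TOY_ROLES = LigandRoles(
    nicotinamide_code="NIC",
    nicotinamide_ring=("N1", "C2", "C3", "C4", "C5", "C6"),
    nicotinamide_c4="C4",
    sugar_code="SUG",
    sugar_c4="C4",
    sugar_o4="O4",
    sugar_c2_substituent="N2",
)


AtomLike = AtomRecord | tuple[ResidueRecord, AtomRecord]


def _normalize(group) -> list[tuple[ResidueRecord | None, AtomRecord]]:
    out = []
    for item in group:
        if isinstance(item, AtomRecord):
            out.append((None, item))
        else:
            res, atom = item
            out.append((res, atom))
    return out


def _is_polar(atom: AtomRecord) -> bool:
    return atom.element.upper() in {"N", "O", "S"}


def _is_donor(res: ResidueRecord | None, atom: AtomRecord) -> bool:
    """Plausible H-bond donor by residue chemistry.

    Without residue context (bare atoms, het groups, waters) any polar atom
    is assumed able to donate; sugar hydroxyls make this the right default.
    """
    if not _is_polar(atom):
        return False
    if res is None or res.is_het or res.is_water:
        return True
    if atom.name == "N":  # backbone amide
        return True
    return (res.name, atom.name) in _SIDECHAIN_DONORS


def atom_distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(a.coords - b.coords))


def detect_hbonds(group_a, group_b, dmax: float = HBOND_DMAX) -> list[HBond]:
    """Donor-acceptor contacts between two disjoint atom groups.

    Each group is a list of AtomRecord or (ResidueRecord, AtomRecord) pairs;
    residue context enables the donor-chemistry filter.  Results are sorted
    by distance.
    """
    ga, gb = _normalize(group_a), _normalize(group_b)
    bonds: list[HBond] = []
    for ra, aa in ga:
        for rb, ab in gb:
            if aa is ab:
                raise InputError("hbond groups must be disjoint")
            if not (_is_polar(aa) and _is_polar(ab)):
                continue
            d = atom_distance(aa, ab)
            if d > dmax:
                continue
            a_don, b_don = _is_donor(ra, aa), _is_donor(rb, ab)
            if not (a_don or b_don):
                continue
            donor, acceptor = (aa, ab) if a_don else (ab, aa)
            dres, ares = (ra, rb) if a_don else (rb, ra)
            bonds.append(HBond(
                donor=donor, acceptor=acceptor, distance=d,
                donor_label=f"{dres.label}/{donor.name}" if dres else donor.name,
                acceptor_label=f"{ares.label}/{acceptor.name}" if ares else acceptor.name,
            ))
    bonds.sort(key=lambda h: h.distance)
    return bonds


def _charge_class(res: ResidueRecord | None, atom: AtomRecord) -> str | None:
    if res is not None:
        key = (res.name, atom.name)
        if key in _BASIC_ATOMS:
            return "basic"
        if key in _ACIDIC_ATOMS:
            return "acidic"
        if (res.is_het and not res.is_water and atom.element.upper() == "O"
                and atom.name in _PHOSPHATE_O_NAMES):
            return "acidic"
    return None


def detect_salt_bridges(group_a, group_b, dmax: float = SALT_DMAX) -> list[SaltBridge]:
    """Charged-group contacts (basic N vs carboxylate/phosphate O) within dmax."""
    ga, gb = _normalize(group_a), _normalize(group_b)
    bridges: list[SaltBridge] = []
    for ra, aa in ga:
        for rb, ab in gb:
            ca, cb = _charge_class(ra, aa), _charge_class(rb, ab)
            if {ca, cb} != {"basic", "acidic"}:
                continue
            d = atom_distance(aa, ab)
            if d > dmax:
                continue
            basic, acidic = (aa, ab) if ca == "basic" else (ab, aa)
            bres, xres = (ra, rb) if ca == "basic" else (rb, ra)
            bridges.append(SaltBridge(
                basic_atom=basic, acidic_atom=acidic, distance=d,
                basic_label=f"{bres.label}/{basic.name}" if bres else basic.name,
                acidic_label=f"{xres.label}/{acidic.name}" if xres else acidic.name,
            ))
    bridges.sort(key=lambda s: s.distance)
    return bridges


def _find_residue(s: Structure, resnum: int, chain_id: str | None) -> ResidueRecord:
    chains = [chain_id] if chain_id else list(s.chains)
    for cid in chains:
        for r in s.chains.get(cid, []):
            if r.seq_number == resnum and not r.is_het:
                return r
    raise NotFoundError(f"residue {resnum} not found (chains {chains})")


def catalytic_c4c4(s: Structure, roles: LigandRoles,
                   productive_range: tuple[float, float] = PRODUCTIVE_RANGE,
                   ) -> CatalyticGeometry:
    """Sugar-C4 to nicotinamide-C4 distance with the productive-mode call.

    ``productive`` is True when the distance lies within the inclusive range
    (default [3.0, 3.7] A, the span compatible with hydride transfer).  When
    the catalytic Tyr is resolvable, its OH to sugar-O4 distance is reported
    alongside.
    """
    nic = extract_ligand(s, roles.nicotinamide_code)
    sug = extract_ligand(s, roles.sugar_code)
    c4n = nic.atom(roles.nicotinamide_c4)
    c4s = sug.atom(roles.sugar_c4)
    d = atom_distance(c4s, c4n)
    lo, hi = productive_range
    o4_tyr = None
    try:
        tyr = _find_residue(s, roles.tyr_resnum, roles.chain_id)
        o4_tyr = atom_distance(tyr.atom("OH"), sug.atom(roles.sugar_o4))
    except NotFoundError:
        pass
    # inclusive bounds, with a 1e-9 A guard against float accumulation
    productive = bool(lo - 1e-9 <= d <= hi + 1e-9)
    return CatalyticGeometry(
        c4_sugar=c4s, c4_nicotinamide=c4n, distance=d,
        productive=productive, o4_tyr_oh_distance=o4_tyr,
    )


def _ring_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Newell normal of a ring given its atoms in dictionary order.

    With atoms ordered N1 -> C2 -> ... -> C6, the returned normal points
    toward the face from which that ordering appears counterclockwise; by
    this package's convention that is the pro-S face at the ring C4.
    """
    c = coords.mean(axis=0)
    v = coords - c
    n = np.zeros(3)
    for i in range(len(v)):
        n += np.cross(v[i], v[(i + 1) % len(v)])
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ClassificationError("ring atoms do not define a plane")
    return n / norm, c


def ring_face(s: Structure, roles: LigandRoles) -> str:
    """Which nicotinamide face the sugar C4 occupies: pro-S -> "standard",
    pro-R -> "flipped".

    The face is the sign of (sugar C4 - ring centroid) . n where n is the
    Newell normal of the nicotinamide ring traversed in dictionary atom
    order; reflection of the coordinates flips the call, proper rotation
    leaves it unchanged.
    """
    nic = extract_ligand(s, roles.nicotinamide_code)
    sug = extract_ligand(s, roles.sugar_code)
    ring = np.array([nic.atom(n).coords for n in roles.nicotinamide_ring])
    normal, centroid = _ring_normal(ring)
    side = float(np.dot(sug.atom(roles.sugar_c4).coords - centroid, normal))
    return "standard" if side > 0 else "flipped"


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2  # b0 points back toward p0
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def classify_c2_swing(s: Structure, asn_resnum: int | None = None,
                      roles: LigandRoles = TOY_ROLES,
                      threshold: float = SWING_THRESHOLD) -> ConformerCalls:
    """Swing conformer of the C2-pocket Asn.

    Primary discriminant: distance from the carboxamide centroid (midpoint
    of OD1/ND2) to the sugar C2 substituent (the group the pocket must
    accommodate).  Within ``threshold`` -> "swing_in" (pocket closed around
    the substituent), beyond -> "swing_out".  chi1 (N-CA-CB-CG) and chi2
    (CA-CB-CG-OD1) are reported for transparency but do not drive the call.
    """
    resnum = asn_resnum if asn_resnum is not None else roles.asn_resnum
    res = _find_residue(s, resnum, roles.chain_id)
    if res.name != "ASN":
        raise ClassificationError(f"residue {resnum} is {res.name}, expected ASN")
    try:
        n, ca_, cb, cg = (res.atom(x).coords for x in ("N", "CA", "CB", "CG"))
        od1, nd2 = res.atom("OD1").coords, res.atom("ND2").coords
    except NotFoundError as exc:
        raise ClassificationError(f"Asn{resnum}: side-chain atoms missing: {exc}") from exc
    chi1 = dihedral(n, ca_, cb, cg)
    chi2 = dihedral(ca_, cb, cg, od1)
    sug = extract_ligand(s, roles.sugar_code)
    try:
        pocket = sug.atom(roles.sugar_c2_substituent).coords
    except NotFoundError:
        pocket = sug.atom("C2").coords
    centroid = 0.5 * (od1 + nd2)
    dist = float(np.linalg.norm(centroid - pocket))
    call = "swing_in" if dist <= threshold else "swing_out"
    return ConformerCalls(
        ring_face=ring_face(s, roles), asn_swing=call,
        chi1=chi1, chi2=chi2, carboxamide_to_pocket=dist,
    )
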
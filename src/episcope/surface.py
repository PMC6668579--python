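"""Solvent-accessible surface area and dimer-interface burial.

Shrake-Rupley sphere sampling with a deterministic golden-spiral point set:
every atom is expanded by the probe radius (1.4 A default, a water molecule),
test points are placed on the expanded sphere, and a point counts as
accessible when it lies outside every neighboring expanded sphere.  The
golden spiral replaces the usual random point set so repeated runs are
bit-identical.

Interface burial follows the usual assembly convention:

    buried_total = SASA(A alone) + SASA(B alone) - SASA(AB assembly)

with ``buried_half`` (= buried_total / 2) also reported because published
"interface area" figures use either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from episcope.errors import InputError, RadiusTableError
from episcope.structure_io import AtomRecord, ResidueRecord, Structure
from episcope.active_site import detect_hbonds, detect_salt_bridges, HBOND_DMAX, SALT_DMAX

PROBE_RADIUS = 1.4
N_POINTS = 960

#: van der Waals radii in Angstrom for the elements that occur in protein
#: crystal structures with common cofactors; config-overridable.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "MG": 1.73, "ZN": 1.39, "CA": 2.31, "NA": 2.27,
    "K": 2.75, "MN": 1.97, "FE": 1.94,
}


@dataclass
class SasaResult:
    per_atom: np.ndarray  # A^2
    total: float
    probe_radius: float
    n_points: int


@dataclass
class InterfaceReport:
    sasa_a: float
    sasa_b: float
    sasa_ab: float
    buried_total: float
    buried_half: float
    interface_residues: dict[str, list[str]] = field(default_factory=dict)
    hbonds: list = field(default_factory=list)
    salt_bridges: list = field(default_factory=list)


def golden_spiral(n: int) -> np.ndarray:
    """n deterministic, nearly uniform points on the unit sphere."""
    i = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def _radii(atoms: list[AtomRecord], radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(atoms))
    for k, a in enumerate(atoms):
        r = radii.get(a.element.upper())
        if r is None:
            raise RadiusTableError(
                f"no van der Waals radius for element {a.element!r} (atom {a.name})"
            )
        out[k] = r
    return out


def shrake_rupley_sasa(atoms: list[AtomRecord], probe: float = PROBE_RADIUS,
                       n_points: int = N_POINTS,
                       radii: dict[str, float] | None = None) -> SasaResult:
    """Per-atom solvent-accessible area by deterministic sphere sampling."""
    if not atoms:
        return SasaResult(np.zeros(0), 0.0, probe, n_points)
    rads = _radii(atoms, radii or VDW_RADII)
    centers = np.array([a.coords for a in atoms])
    expanded = rads + probe
    sphere = golden_spiral(n_points)
    rmax = expanded.max()
    tree = cKDTree(centers)
    per_atom = np.zeros(len(atoms))
    for k in range(len(atoms)):
        pts = centers[k] + expanded[k] * sphere
        nbr = [j for j in tree.query_ball_point(centers[k], expanded[k] + rmax)
               if j != k]
        if nbr:
            d2 = ((pts[:, None, :] - centers[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[k] = 4.0 * np.pi * expanded[k] ** 2 * frac
    return SasaResult(per_atom=per_atom, total=float(per_atom.sum()),
                      probe_radius=probe, n_points=n_points)


def _heavy_atoms(s: Structure, chain_id: str | None = None,
                 include_waters: bool = False, include_ions: bool = False,
                 ) -> list[tuple[ResidueRecord, AtomRecord]]:
    out = []
    for r in s.residues(chain_id=chain_id):
        if r.is_water and not include_waters:
            continue
        if r.is_het and len(r.atoms) == 1 and not include_ions:
            continue  # monoatomic ions
        for a in r.atoms:
            if a.element.upper() == "H":
                continue
            out.append((r, a))
    return out


def structure_sasa(s: Structure, chain_id: str | None = None,
                   probe: float = PROBE_RADIUS, n_points: int = N_POINTS,
                   include_waters: bool = False) -> tuple[SasaResult, list]:
    pairs = _heavy_atoms(s, chain_id, include_waters=include_waters)
    res = shrake_rupley_sasa([a for _, a in pairs], probe=probe, n_points=n_points)
    return res, pairs


def interface_report(dimer: Structure, probe: float = PROBE_RADIUS,
                     n_points: int = N_POINTS,
                     dmax_hbond: float = HBOND_DMAX,
                     dmax_salt: float = SALT_DMAX) -> InterfaceReport:
    """SASA burial and contact inventory for a two-chain assembly.

    Interface residues are those losing any accessible area on assembly;
    H-bond and salt-bridge lists cover inter-chain pairs only.
    """
    chain_ids = list(dimer.chains)
    if len(chain_ids) != 2:
        raise InputError(f"interface analysis needs exactly 2 chains, got {len(chain_ids)}")
    ca, cb = chain_ids
    res_a, pairs_a = structure_sasa(dimer, ca, probe, n_points)
    res_b, pairs_b = structure_sasa(dimer, cb, probe, n_points)
    atoms_ab = pairs_a + pairs_b
    res_ab = shrake_rupley_sasa([a for _, a in atoms_ab], probe=probe, n_points=n_points)
    buried_total = max(res_a.total + res_b.total - res_ab.total, 0.0)
    if buried_total < 1e-9:  # float accumulation across per-atom sums
        buried_total = 0.0

    # per-residue area loss
    iso = np.concatenate([res_a.per_atom, res_b.per_atom])
    loss_by_res: dict[tuple[str, str], float] = {}
    for (r, _), area_iso, area_ab in zip(atoms_ab, iso, res_ab.per_atom):
        key = (r.chain_id, r.label)
        loss_by_res[key] = loss_by_res.get(key, 0.0) + (area_iso - area_ab)
    interface_residues = {ca: [], cb: []}
    for (cid, label), loss in loss_by_res.items():
        if loss > 1e-6:
            interface_residues[cid].append(label)

    hb = detect_hbonds(pairs_a, pairs_b, dmax=dmax_hbond)
    sb = detect_salt_bridges(pairs_a, pairs_b, dmax=dmax_salt)
    return InterfaceReport(
        sasa_a=res_a.total, sasa_b=res_b.total, sasa_ab=res_ab.total,
        buried_total=float(buried_total), buried_half=float(buried_total / 2.0),
        interface_residues=interface_residues, hbonds=hb, salt_bridges=sb,
    )


def sphere_cap_buried_area(r1: float, r2: float, d: float) -> float:
    """Closed-form buried area for two intersecting spheres (total over both).

    Each sphere loses the spherical cap cut off by the radical plane:
    cap area = 2 pi R h.  Returns 0 when the spheres do not intersect; when
    one sphere is engulfed, the smaller sphere's full area is buried.
    """
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rs = min(r1, r2)
        return 4.0 * np.pi * rs**2
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    h1 = r1 - x1
    h2 = r2 - (d - x1)
    return float(2.0 * np.pi * (r1 * h1 + r2 * h2))
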
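import numpy as np
import pytest

from episcope import synthetic as syn
from episcope.active_site import (
    TOY_ROLES,
    atom_distance,
    catalytic_c4c4,
    classify_c2_swing,
    detect_hbonds,
    detect_salt_bridges,
    dihedral,
    ring_face,
)
from episcope.errors import ClassificationError, NotFoundError
from episcope.structure_io import AtomRecord, ResidueRecord


def _atom(name, element, xyz):
    return AtomRecord(name, element, np.asarray(xyz, float))


def test_atom_distance():
    assert atom_distance(_atom("A", "C", [0, 0, 0]), _atom("B", "C", [0, 0, 0])) == 0.0
    assert atom_distance(_atom("A", "C", [0, 0, 0]), _atom("B", "C", [3, 4, 0])) == pytest.approx(5.0)


def test_planted_hbond_distances():
    ga, gb, man = syn.make_hbond_set([2.8], seed=0)
    bonds = detect_hbonds(ga, gb, dmax=3.5)
    assert len(bonds) == 1
    assert bonds[0].distance == pytest.approx(2.8, abs=1e-9)


def test_hbond_out_of_range_empty():
    ga, gb, _ = syn.make_hbond_set([5.0], seed=1)
    assert detect_hbonds(ga, gb, dmax=3.5) == []


def test_hbond_count_monotone_in_dmax():
    ga, gb, _ = syn.make_hbond_set([2.5, 3.0, 3.4, 3.6, 4.2], seed=2)
    counts = [len(detect_hbonds(ga, gb, dmax=d)) for d in (2.6, 3.1, 3.5, 4.0, 4.5)]
    assert counts == sorted(counts)
    assert counts == [1, 2, 3, 4, 5]


def test_hbond_requires_a_donor():
    # two backbone carbonyl oxygens: both acceptors only -> no bond
    res1 = ResidueRecord("ALA", 1, "", "A", [])
    res2 = ResidueRecord("ALA", 2, "", "A", [])
    o1 = _atom("O", "O", [0, 0, 0])
    o2 = _atom("O", "O", [2.8, 0, 0])
    assert detect_hbonds([(res1, o1)], [(res2, o2)], dmax=3.5) == []
    # serine hydroxyl can donate
    ser = ResidueRecord("SER", 3, "", "A", [])
    og = _atom("OG", "O", [0, 0, 0])
    assert len(detect_hbonds([(ser, og)], [(res2, o2)], dmax=3.5)) == 1


def test_salt_bridge_detection():
    lys = ResidueRecord("LYS", 10, "", "A", [])
    asp = ResidueRecord("ASP", 20, "", "A", [])
    nz = _atom("NZ", "N", [0, 0, 0])
    near = _atom("OD1", "O", [3.2, 0, 0])
    far = _atom("OD1", "O", [5.5, 0, 0])
    assert len(detect_salt_bridges([(lys, nz)], [(asp, near)], dmax=4.0)) == 1
    assert detect_salt_bridges([(lys, nz)], [(asp, far)], dmax=4.0) == []
    # a charged pair also registers as donor/acceptor contact
    assert len(detect_hbonds([(lys, nz)], [(asp, near)], dmax=3.5)) == 1


def test_phosphate_oxygen_counts_as_acidic():
    arg = ResidueRecord("ARG", 292, "", "A", [])
    udp = ResidueRecord("UDP", 500, "", "A", [], is_het=True)
    nh1 = _atom("NH1", "N", [0, 0, 0])
    o1a = _atom("O1A", "O", [2.9, 0, 0])
    assert len(detect_salt_bridges([(arg, nh1)], [(udp, o1a)], dmax=4.0)) == 1


@pytest.mark.parametrize("planted,productive", [
    (3.4, True), (3.5, True), (3.0, True), (3.7, True),  # inclusive bounds
    (9.4, False), (2.9, False), (3.71, False),
])
def test_catalytic_c4c4(planted, productive):
    s, man = syn.make_toy_complex(c4c4=planted, seed=7)
    geom = catalytic_c4c4(s, TOY_ROLES)
    assert geom.distance == pytest.approx(planted, abs=1e-6)
    assert geom.productive is productive
    assert geom.o4_tyr_oh_distance == pytest.approx(man["tyr_o4_dist"], abs=1e-6)


def test_catalytic_missing_ligand_errors(toy_peptide):
    with pytest.raises(NotFoundError):
        catalytic_c4c4(toy_peptide, TOY_ROLES)


@pytest.mark.parametrize("face,expected", [("pro_S", "standard"), ("pro_R", "flipped")])
def test_ring_face_calls(face, expected):
    s, _ = syn.make_toy_complex(face=face, seed=3)
    assert ring_face(s, TOY_ROLES) == expected


def test_ring_face_flips_under_reflection():
    s, _ = syn.make_toy_complex(face="pro_S", seed=4)
    assert ring_face(s, TOY_ROLES) == "standard"
    for r in s.chains["A"]:
        for a in r.atoms:
            a.coords = a.coords * np.array([-1.0, 1.0, 1.0])  # mirror in x
    assert ring_face(s, TOY_ROLES) == "flipped"


@pytest.mark.parametrize("rotamer,expected", [("in", "swing_in"), ("out", "swing_out")])
def test_swing_classification(rotamer, expected):
    s, man = syn.make_toy_complex(asn_rotamer=rotamer, seed=5)
    calls = classify_c2_swing(s, roles=TOY_ROLES)
    assert calls.asn_swing == expected
    assert calls.carboxamide_to_pocket == pytest.approx(
        man["carboxamide_to_pocket"], abs=1e-6)


def test_swing_requires_asn(toy_complex_in):
    s, _ = toy_complex_in
    with pytest.raises(ClassificationError):
        classify_c2_swing(s, asn_resnum=150, roles=TOY_ROLES)  # that's the Tyr


def test_calls_invariant_under_rigid_motion():
    s, _ = syn.make_toy_complex(c4c4=3.3, face="pro_S", asn_rotamer="in", seed=6)
    before_geom = catalytic_c4c4(s, TOY_ROLES)
    before_calls = classify_c2_swing(s, roles=TOY_ROLES)
    moved, _ = syn.make_rotated_copy(s, noise_sd=0.0, seed=99)
    after_geom = catalytic_c4c4(moved, TOY_ROLES)
    after_calls = classify_c2_swing(moved, roles=TOY_ROLES)
    assert after_geom.distance == pytest.approx(before_geom.distance, abs=1e-6)
    assert after_calls.asn_swing == before_calls.asn_swing
    assert after_calls.ring_face == before_calls.ring_face == "standard"
    assert after_calls.chi1 == pytest.approx(before_calls.chi1, abs=1e-5)
    assert after_calls.chi2 == pytest.approx(before_calls.chi2, abs=1e-5)


def test_dihedral_sign_convention():
    # a +90 degree torsion built by hand
    p0, p1, p2 = np.array([1.0, 0, -1]), np.zeros(3), np.array([0.0, 0, 1])
    p3 = np.array([0.0, 1.0, 2.0])
    assert dihedral(p0, p1, p2, p3) == pytest.approx(90.0, abs=1e-9)
    assert dihedral(p0, p1, p2, np.array([0.0, -1.0, 2.0])) == pytest.approx(-90.0, abs=1e-9)
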
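import numpy as np
import pytest

from episcope.errors import MappingError
from episcope.sequences import ResidueMap, build_residue_map, global_align
from episcope.specificity import (
    ANCHOR_POSITIONS,
    classify_group,
    mutate_and_reclassify,
    pocket_profile,
    profile_from_codes,
)
from episcope.structure_io import ResidueRecord, Structure
from episcope.structure_io import AtomRecord

# characterized enzymes: pocket residues and their established group labels
KNOWN_ENZYMES = [
    # id, C2 residue, C5 residue, clade hint, expected group, expected call
    ("bGalE", "ASN", "CYS", None, "2", "dual"),
    ("hGalE", "ASN", "CYS", None, "2", "dual"),
    ("eGalE", "ASN", "TYR", None, "1b", "Glc/Gal preferring"),
    ("tGalE", "HIS", "LEU", None, "1a", "Glc/Gal preferring"),
    ("WbpP", "ALA", "SER", None, "3", "GlcNAc/GalNAc preferring"),
    ("BLLJ_1592", "ASN", "LEU", "unplaced", "1", "Glc/Gal preferring"),
]


@pytest.mark.parametrize("sid,c2,c5,clade,group,call", KNOWN_ENZYMES)
def test_classifier_reproduces_known_assignments(sid, c2, c5, clade, group, call):
    pred = classify_group(profile_from_codes(sid, c2, c5), clade=clade)
    assert pred.group == group
    assert pred.substrate_call == call
    assert pred.rule_trace


def test_unplaced_clade_gives_group1_like_caveat():
    pred = classify_group(profile_from_codes("BLLJ_1592", "ASN", "LEU"),
                          clade="unplaced")
    assert pred.group == "1"
    assert any("group 1-like" in step for step in pred.rule_trace)


def test_mutant_direction_flips():
    egale = profile_from_codes("eGalE", "ASN", "TYR", c5_pos=299)
    y299c = mutate_and_reclassify(egale, "c5", "CYS")
    assert y299c.group == "2"  # gains the N-acetyl series
    hgale = profile_from_codes("hGalE", "ASN", "CYS", c5_pos=307)
    c307y = mutate_and_reclassify(hgale, "c5", "TYR")
    assert c307y.group.startswith("1")  # loses it
    same = mutate_and_reclassify(egale, "c5", "TYR")  # identity mutation
    assert same.group == classify_group(egale).group


def test_prediction_deterministic():
    p = profile_from_codes("bGalE", "ASN", "CYS")
    a, b = classify_group(p), classify_group(p)
    assert a.group == b.group and a.rule_trace == b.rule_trace


def test_c5_rule_dominates_c2():
    """Changing C2 alone never crosses the group-1 vs group-2/3 boundary."""
    codes = ["ALA", "ASN", "HIS", "GLY", "SER", "TYR", "LEU", "TRP", "GLN"]
    for c5, is_group1 in [("TYR", True), ("LEU", True), ("CYS", False), ("SER", False)]:
        for c2 in codes:
            g = classify_group(profile_from_codes("x", c2, c5)).group
            if is_group1:
                assert g.startswith("1")
            else:
                assert not g.startswith("1")


def test_unknown_outcomes():
    pred = classify_group(profile_from_codes("odd", "TRP", "CYS"))
    assert pred.group == "unknown" and pred.rule_trace
    p = profile_from_codes("noC5", "ASN", "CYS")
    p.c5_residue = (None, None)
    assert classify_group(p).group == "unknown"


def test_triad_deviation_flagged_not_fatal():
    p = profile_from_codes("weird", "ASN", "CYS", triad=("ALA", "TYR", "LYS"))
    pred = classify_group(p)
    assert pred.group == "2"
    assert any("triad" in step for step in pred.rule_trace)


def test_pocket_profile_from_sequence(anchor_like_sequence):
    anchor = anchor_like_sequence
    # homolog: insertion of 7 before the triad -> all later positions shift
    homolog = anchor[:100] + "GGSGGSG" + anchor[100:]
    aln = global_align(anchor, homolog, ids=("bGalE", "homolog"))
    m = build_residue_map(aln)
    prof = pocket_profile(homolog, m)
    assert prof.c2_residue == (207, "ASN")
    assert prof.c5_residue == (306, "CYS")
    assert prof.triad == ("SER", "TYR", "LYS")
    assert prof.n180_ok
    assert classify_group(prof).group == "2"


def test_pocket_profile_from_structure():
    # minimal structure carrying only the anchor-position residues
    def res(name, num):
        return ResidueRecord(name, num, "", "A",
                             [AtomRecord("CA", "C", np.zeros(3))])

    s = Structure(id="mini", chains={"A": [
        res("LYS", 85), res("SER", 125), res("TYR", 150), res("LYS", 154),
        res("ASN", 180), res("ASN", 200), res("CYS", 299),
    ]})
    identity = {v: v for v in ANCHOR_POSITIONS.values()}
    m = ResidueMap("bGalE", "mini", identity)
    prof = pocket_profile(s, m, subject_id="mini")
    assert prof.source == "structure"
    assert prof.c2_residue == (200, "ASN") and prof.c5_residue == (299, "CYS")
    assert classify_group(prof).group == "2"


def test_pocket_profile_requires_mappable_pockets(anchor_like_sequence):
    m = ResidueMap("bGalE", "bad", {85: 85, 125: 125})  # pockets unmappable
    with pytest.raises(MappingError):
        pocket_profile(anchor_like_sequence, m)
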
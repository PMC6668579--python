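"""End-to-end orchestration: one config in, one machine-readable report out.

The report is a plain JSON-serializable dict covering, per the config:
pairwise identities and an NJ tree over the subjects' sequences, trimmed and
untrimmed superpositions for requested comparisons, active-site geometry and
conformer calls for subjects with coordinates, pocket profiles and group
predictions against the anchor (bGalE) reference, an interface report when a
two-chain assembly is supplied, and a provenance block with every effective
parameter.  Failures are isolated per subject/stage as error records; the
run continues.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import episcope
from episcope.errors import ConfigError, EpiscopeError
from episcope import active_site as ag
from episcope import sequences as sq
from episcope import specificity as sp
from episcope import superposition as sup
from episcope import surface as sf
from episcope.structure_io import chain_one_letter, read_structure
from episcope.synthetic import read_fasta

log = logging.getLogger("episcope")

DEFAULT_OPTIONS = {
    "cutoff": 2.0,
    "probe": sf.PROBE_RADIUS,
    "n_points": sf.N_POINTS,
    "hbond_dmax": ag.HBOND_DMAX,
    "salt_dmax": ag.SALT_DMAX,
    "swing_threshold": ag.SWING_THRESHOLD,
    "productive_range": list(ag.PRODUCTIVE_RANGE),
    "align": dict(sq.DEFAULT_ALIGN_PARAMS),
    "seed": 0,
}


@dataclass
class RunConfig:
    """Validated run configuration (see docs/methods.md for the schema)."""

    subjects: list[dict]
    anchor: dict
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    roles: dict = field(default_factory=dict)
    dimer: str | None = None
    options: dict = field(default_factory=dict)
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        for key in ("subjects", "anchor"):
            if key not in raw:
                raise ConfigError(f"config missing required key {key!r}")
        if not isinstance(raw["subjects"], list) or not raw["subjects"]:
            raise ConfigError("subjects must be a non-empty list")
        for s in raw["subjects"]:
            if "id" not in s:
                raise ConfigError("every subject needs an 'id'")
            if not any(k in s for k in ("structure", "sequence", "sequence_str")):
                raise ConfigError(f"subject {s['id']}: needs structure and/or sequence")
        anchor = raw["anchor"]
        if "id" not in anchor or not any(k in anchor for k in ("sequence", "sequence_str")):
            raise ConfigError("anchor needs 'id' and a sequence")
        opts = dict(DEFAULT_OPTIONS)
        align = dict(opts["align"])
        user_opts = raw.get("options", {}) or {}
        align.update(user_opts.get("align", {}) or {})
        opts.update(user_opts)
        opts["align"] = align
        comparisons = [tuple(c) for c in raw.get("comparisons", []) or []]
        cfg = cls(
            subjects=raw["subjects"], anchor=anchor, comparisons=comparisons,
            roles=raw.get("roles", {}) or {}, dimer=raw.get("dimer"),
            options=opts, base_dir=base_dir or Path("."),
        )
        cfg._check_files()
        return cfg

    def _check_files(self) -> None:
        # missing subject files surface as per-subject error records at run
        # time (fault isolation); the anchor sequence is required up front
        # because every profile stage depends on it
        if "sequence" in self.anchor and not self._path(self.anchor["sequence"]).exists():
            raise ConfigError(f"anchor sequence file missing: {self.anchor['sequence']}")
        for s in self.subjects:
            for key in ("structure", "sequence"):
                if key in s and not self._path(s[key]).exists():
                    log.warning("subject %s: %s file %s missing; stage will error",
                                s["id"], key, s[key])

    def _path(self, p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p


def _first_fasta_seq(path: Path) -> str:
    seqs = read_fasta(path)
    if not seqs:
        raise ConfigError(f"no sequences in {path}")
    return next(iter(seqs.values()))


def _load_subject(cfg: RunConfig, spec: dict):
    """Resolve a subject into (Structure | None, sequence, numbering).

    ``numbering`` (author residue numbers per sequence position) is only set
    when the sequence was derived from the structure chain itself; an
    explicitly supplied sequence uses plain 1-based numbering.
    """
    structure = None
    seq = None
    numbering = None
    if "structure" in spec:
        structure = read_structure(cfg._path(spec["structure"]))
    if "sequence_str" in spec:
        seq = spec["sequence_str"].upper()
    elif "sequence" in spec:
        seq = _first_fasta_seq(cfg._path(spec["sequence"]))
    if seq is None and structure is not None:
        chain = spec.get("chain") or next(iter(structure.chains))
        seq, numbering = chain_one_letter(structure, chain)
    return structure, seq, numbering


def run_report(cfg: RunConfig, out_path: str | Path | None = None) -> dict:
    """Execute all configured stages and return (optionally write) the report."""
    report: dict = {
        "subjects": {}, "superpositions": {}, "identities": {},
        "tree_newick": None, "interface": None,
        "provenance": {
            "package": "episcope", "version": episcope.__version__,
            "options": cfg.options,
        },
    }
    errors = 0
    opts = cfg.options
    roles = ag.LigandRoles.from_dict(cfg.roles) if cfg.roles else None

    # --- load everything, isolating per-subject failures
    anchor_seq = (cfg.anchor.get("sequence_str")
                  or _first_fasta_seq(cfg._path(cfg.anchor["sequence"]))).upper()
    anchor_id = cfg.anchor["id"]
    loaded: dict[str, tuple] = {}
    for sdef in cfg.subjects:
        sid = sdef["id"]
        entry: dict = {}
        report["subjects"][sid] = entry
        try:
            loaded[sid] = _load_subject(cfg, sdef)
            entry["loaded"] = True
        except (EpiscopeError, OSError) as exc:
            entry["error"] = f"load failed: {exc}"
            errors += 1

    seqs = {anchor_id: anchor_seq}
    for sid, (st, seq, _num) in loaded.items():
        if seq:
            seqs[sid] = seq

    # --- identity matrix and tree
    try:
        if len(seqs) >= 2:
            d, ids = sq.distance_matrix(seqs, opts["align"])
            report["identities"] = {
                f"{ids[i]}|{ids[j]}": round(100.0 * (1.0 - d[i, j]), 2)
                for i in range(len(ids)) for j in range(i + 1, len(ids))
            }
            if len(ids) >= 3:
                report["tree_newick"] = sq.nj_tree(d, ids).newick
    except EpiscopeError as exc:
        report["identities"] = {"error": str(exc)}
        errors += 1

    # --- superpositions
    for a_id, b_id in cfg.comparisons:
        key = f"{a_id}|{b_id}"
        try:
            st_a, _, _ = loaded[a_id]
            st_b, _, _ = loaded[b_id]
            if st_a is None or st_b is None:
                raise ConfigError(f"comparison {key}: both subjects need structures")
            # pair on the chains' own sequences, not any user-supplied ones
            chain_a_seq, _ = chain_one_letter(st_a, next(iter(st_a.chains)))
            chain_b_seq, _ = chain_one_letter(st_b, next(iter(st_b.chains)))
            aln = sq.global_align(chain_a_seq, chain_b_seq, opts["align"], (a_id, b_id))
            pairs = sup.pair_calpha_by_alignment(st_a, st_b, aln)
            trimmed = sup.trimmed_superpose(pairs, cutoff=opts["cutoff"])
            report["superpositions"][key] = {
                "rmsd_no_cutoff": round(sup.rmsd_no_cutoff(pairs), 4),
                "rmsd_trimmed": round(trimmed.rmsd, 4),
                "n_pairs_total": len(pairs),
                "n_pairs_retained": trimmed.n_pairs_used,
                "cutoff": opts["cutoff"],
            }
        except (EpiscopeError, KeyError) as exc:
            report["superpositions"][key] = {"error": str(exc)}
            errors += 1

    # --- per-subject active-site geometry and specificity
    for sdef in cfg.subjects:
        sid = sdef["id"]
        if sid not in loaded:
            continue
        st, seq, numbering = loaded[sid]
        entry = report["subjects"][sid]
        has_cofactor = (st is not None and roles is not None and
                        any(l.name == roles.nicotinamide_code for l in st.ligands))
        if st is not None and roles is not None and not has_cofactor:
            entry["catalytic"] = None  # not a ternary complex
        if has_cofactor:
            try:
                geom = ag.catalytic_c4c4(st, roles, tuple(opts["productive_range"]))
                entry["catalytic"] = {
                    "c4c4": round(geom.distance, 1),
                    "productive": geom.productive,
                    "tyr_oh_o4": (round(geom.o4_tyr_oh_distance, 1)
                                  if geom.o4_tyr_oh_distance is not None else None),
                }
                calls = ag.classify_c2_swing(st, roles=roles,
                                             threshold=opts["swing_threshold"])
                entry["conformers"] = {
                    "ring_face": calls.ring_face, "asn_swing": calls.asn_swing,
                    "chi1": round(calls.chi1, 1), "chi2": round(calls.chi2, 1),
                }
            except EpiscopeError as exc:
                entry["catalytic_error"] = str(exc)
                errors += 1
        if seq:
            try:
                aln = sq.global_align(anchor_seq, seq, opts["align"], (anchor_id, sid))
                # structure-backed profiles need the map in author numbering,
                # which is only available when the sequence came from the chain
                amap = sq.build_residue_map(aln, homolog_numbers=numbering)
                subject_obj = st if (st is not None and numbering is not None) else seq
                prof = sp.pocket_profile(subject_obj, amap, subject_id=sid,
                                         chain_id=sdef.get("chain"))
                pred = sp.classify_group(prof, clade=sdef.get("clade"))
                entry["pocket_profile"] = {
                    "c2": list(prof.c2_residue), "c5": list(prof.c5_residue),
                    "triad": list(prof.triad), "source": prof.source,
                }
                entry["prediction"] = {
                    "group": pred.group, "substrate_call": pred.substrate_call,
                    "rule_trace": pred.rule_trace,
                }
            except EpiscopeError as exc:
                entry["profile_error"] = str(exc)
                errors += 1

    # --- dimer interface
    if cfg.dimer:
        try:
            dimer = read_structure(cfg._path(cfg.dimer))
            rep = sf.interface_report(dimer, probe=opts["probe"],
                                      n_points=opts["n_points"],
                                      dmax_hbond=opts["hbond_dmax"],
                                      dmax_salt=opts["salt_dmax"])
            report["interface"] = {
                "sasa_a": round(rep.sasa_a, 1), "sasa_b": round(rep.sasa_b, 1),
                "sasa_ab": round(rep.sasa_ab, 1),
                "buried_total": round(rep.buried_total, 1),
                "buried_half": round(rep.buried_half, 1),
                "n_hbonds": len(rep.hbonds), "n_salt_bridges": len(rep.salt_bridges),
                "n_interface_residues": {k: len(v) for k, v in rep.interface_residues.items()},
            }
        except (EpiscopeError, OSError) as exc:
            report["interface"] = {"error": str(exc)}
            errors += 1

    report["n_errors"] = errors
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
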
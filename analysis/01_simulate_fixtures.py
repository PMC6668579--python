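#!/usr/bin/env python
"""Generate the synthetic study fixtures for all downstream analyses.

Writes PDB/FASTA files plus JSON manifests (planted ground truth) under
results/fixtures/.  Every later script regenerates what it needs from the
same seed, so this step is a convenience for inspection, not a dependency.
"""

import argparse
import json
from pathlib import Path

from episcope import synthetic as syn
from episcope.structure_io import write_structure

FAMILY_NEWICK = "((A:0.06,B:0.06):0.05,(C:0.06,D:0.06):0.05,(E:0.06,F:0.06):0.05);"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/fixtures"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    manifests = {}
    for face in ("pro_S", "pro_R"):
        for rot in ("in", "out"):
            s, man = syn.make_toy_complex(face=face, asn_rotamer=rot, seed=args.seed)
            name = f"toy_complex_{face}_{rot}"
            write_structure(s, out / f"{name}.pdb")
            manifests[name] = man

    s, man = syn.make_dimer_spheres(n_atoms_per_protomer=1, separation=3.0,
                                    seed=args.seed)
    write_structure(s, out / "dimer_single_atoms.pdb")
    manifests["dimer_single_atoms"] = man

    seqs, man = syn.make_sequence_family(FAMILY_NEWICK, length=400, seed=args.seed)
    syn.write_fasta(seqs, out / "family.fasta")
    manifests["sequence_family"] = man

    pep = syn.make_toy_peptide(40, seed=args.seed)
    write_structure(pep, out / "peptide.pdb")
    moved, man = syn.make_rotated_copy(pep, noise_sd=0.3, seed=args.seed + 1)
    write_structure(moved, out / "peptide_moved.pdb")
    man.pop("noise")  # bulky; realized coordinates live in the PDB itself
    manifests["peptide_moved"] = man

    (out / "manifests.json").write_text(json.dumps(manifests, indent=2) + "\n")
    print(f"wrote {len(manifests)} fixtures to {out}/ (seed {args.seed})")


if __name__ == "__main__":
    main()
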
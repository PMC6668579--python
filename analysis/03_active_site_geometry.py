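#!/usr/bin/env python
"""Active-site geometry across the toy ternary-complex grid.

Measures the catalytic C4-C4 distance (with the 3.0-3.7 A productive-mode
call), the Tyr-OH to sugar-O4 hydrogen bond, the sugar ring face, and the
C2-pocket Asn swing conformer on complexes planted at known geometry.
Writes results/active_site.tsv.
"""

import argparse
import csv
from pathlib import Path

from episcope import synthetic as syn
from episcope.active_site import TOY_ROLES, catalytic_c4c4, classify_c2_swing

GRID = [
    # planted C4-C4, face, rotamer  (3.4/3.5: the two sugar complexes;
    # 9.4: the displaced nonproductive mode seen for a C5-pocket mutant)
    (3.4, "pro_S", "in"),
    (3.5, "pro_S", "out"),
    (3.0, "pro_S", "in"),
    (3.7, "pro_S", "out"),
    (9.4, "pro_S", "in"),
    (3.4, "pro_R", "in"),
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/active_site.tsv"))
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    rows = []
    for k, (d, face, rot) in enumerate(GRID):
        s, man = syn.make_toy_complex(c4c4=d, face=face, asn_rotamer=rot,
                                      seed=args.seed + k)
        geom = catalytic_c4c4(s, TOY_ROLES)
        calls = classify_c2_swing(s, roles=TOY_ROLES)
        rows.append({
            "planted_c4c4": d, "planted_face": face, "planted_rotamer": rot,
            "c4c4": round(geom.distance, 1),
            "productive": int(geom.productive),
            "tyr_oh_o4": round(geom.o4_tyr_oh_distance, 1),
            "ring_face": calls.ring_face,
            "asn_swing": calls.asn_swing,
            "chi1": round(calls.chi1, 1), "chi2": round(calls.chi2, 1),
        })

    with open(args.out, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=rows[0].keys(), delimiter="\t")
        w.writeheader()
        w.writerows(rows)

    n_prod = sum(r["productive"] for r in rows)
    ok_face = sum((r["planted_face"] == "pro_S") == (r["ring_face"] == "standard")
                  for r in rows)
    ok_swing = sum((r["planted_rotamer"] == "in") == (r["asn_swing"] == "swing_in")
                   for r in rows)
    print(f"{len(rows)} complexes measured: {n_prod} productive (planted "
          f"distances within [3.0, 3.7] A), face calls correct {ok_face}/{len(rows)}, "
          f"swing calls correct {ok_swing}/{len(rows)}; Tyr-OH..O4 = "
          f"{rows[0]['tyr_oh_o4']} A throughout.")
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
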
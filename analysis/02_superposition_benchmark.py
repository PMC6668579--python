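#!/usr/bin/env python
"""Benchmark the rigid-body fit and the 2.0-A trimming variant.

On seeded coordinate fixtures: compares the closed-form Kabsch RMSD with a
brute-force rotation-search oracle, and checks that distance-cutoff trimming
recovers exactly the planted-outlier-free pair set.  Writes
results/superposition.csv.
"""

import argparse
import csv
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "tests"))
from helpers import bruteforce_rmsd  # noqa: E402

from episcope import synthetic as syn  # noqa: E402
from episcope.superposition import kabsch_fit, rmsd_no_cutoff, trimmed_superpose  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-fixtures", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results/superposition.csv"))
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    rows = []
    for k in range(args.n_fixtures):
        p, _ = syn.make_paired_cloud(n=50, noise_sd=0.5, seed=args.seed + k)
        fit = kabsch_fit(p)
        oracle = bruteforce_rmsd(p.coords_a, p.coords_b, n_starts=8,
                                 seed=args.seed + k)
        po, man = syn.make_paired_cloud(n=25, noise_sd=0.3, n_outliers=5,
                                        outlier_shift=5.0, seed=args.seed + 100 + k)
        t = trimmed_superpose(po, cutoff=2.0)
        exact = set(np.where(~t.retained)[0].tolist()) == set(man["outlier_indices"])
        rows.append({
            "seed": args.seed + k,
            "kabsch_rmsd": round(fit.rmsd, 6),
            "oracle_rmsd": round(oracle, 6),
            "abs_dev": round(abs(fit.rmsd - oracle), 8),
            "trim_retained": t.n_pairs_used,
            "trim_exact_recovery": int(exact),
            "trim_rmsd": round(t.rmsd, 6),
            "untrimmed_rmsd": round(rmsd_no_cutoff(po), 6),
        })

    with open(args.out, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=rows[0].keys())
        w.writeheader()
        w.writerows(rows)

    max_dev = max(r["abs_dev"] for r in rows)
    n_exact = sum(r["trim_exact_recovery"] for r in rows)
    print(f"{len(rows)} fixtures: max |Kabsch - oracle| = {max_dev:.2e} A; "
          f"trimming recovered the planted clean set in {n_exact}/{len(rows)} cases; "
          f"trimmed RMSD <= untrimmed in all "
          f"{sum(r['trim_rmsd'] <= r['untrimmed_rmsd'] for r in rows)}/{len(rows)}.")
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
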
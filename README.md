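# episcope

Structural comparison and substrate-specificity analysis of UDP-glucose
4-epimerases (GalE, EC 5.1.3.2).

GalE enzymes interconvert UDP-Glc ↔ UDP-Gal (and in some homologs
UDP-GlcNAc ↔ UDP-GalNAc) by NAD⁺-mediated C4 oxidation, rotation of the
4-ketopyranose intermediate, and re-reduction.  Which sugar series an
enzyme accepts — group 1 (Glc/Gal only, subgroups 1a/1b), group 2 (dual),
or group 3 (GlcNAc/GalNAc preferring) — is encoded in two active-site
subsites: the **C2 pocket** around the sugar C2 substituent (hydroxy vs
N-acetyl; lined by Asn200 in the *Bifidobacterium longum* enzyme) and the
**C5 pocket** around the C5 ring atom (lined by Cys299).  A small C5
residue leaves a large pocket that tolerates both series; a bulky one
excludes the N-acetyl sugars.

This package is for structural biologists and enzymologists doing that
kind of comparative analysis.  It provides, as a library, a CLI
(`episcope`) and a set of analysis drivers:

* **Superposition** — least-squares Cα fit (SVD with reflection guard) and
  the iterative trimming variant: fit, drop pairs deviating > 2.0 Å,
  refit until stable; reports RMSD over the retained pairs together with
  their count ("0.69 Å (306 a.a.)"-style).
* **Active-site geometry** — catalytic C4(sugar)–C4(nicotinamide)
  distance with the productive-mode call (within 3.0–3.7 Å, the span
  compatible with hydride transfer), H-bond and salt-bridge inventories,
  sugar ring face (standard vs flipped), and the C2-pocket Asn swing
  conformer (swing in/out).
* **Surface & interface** — deterministic Shrake–Rupley SASA (golden
  spiral, probe 1.4 Å) and dimer burial
  SASA(A) + SASA(B) − SASA(AB).
* **Sequences & phylogeny** — Needleman–Wunsch/BLOSUM62 global alignment,
  percent identity, cross-homolog residue maps (e.g. *B. longum* Tyr150 ↔
  human Tyr157), sequence-deduced average mass, and neighbor-joining trees
  on 1 − identity distances.
* **Specificity classifier** — the two-pocket rule cascade predicting the
  GalE group from the residues at the 200/299-equivalent positions, with
  a full rule trace and in-silico point-mutant reclassification.
* **Synthetic data** — seeded generators (rigid-motion clouds with planted
  outliers, toy ternary complexes at prescribed geometry, sphere dimers,
  sequence families evolved along a known tree) with exact ground-truth
  manifests, so the whole pipeline runs and is tested without downloads.

## Worked example

Classify a homolog from its pocket residues and inspect the rule trace:

```python
>>> from episcope.specificity import classify_group, profile_from_codes
>>> pred = classify_group(profile_from_codes("bGalE", "ASN", "CYS"))
>>> pred.group, pred.substrate_call
('2', 'dual')
>>> pred = classify_group(profile_from_codes("BLLJ_1592", "ASN", "LEU"),
...                       clade="unplaced")
>>> pred.group
'1'
```

Measure a ternary complex (here a synthetic one planted at known geometry):

```bash
$ episcope simulate toy_complex --seed 3 --out fx
$ episcope active-site fx/toy_complex.pdb --toy
{
  "c4c4": 3.4,
  "productive": true,
  "tyr_oh_o4": 2.6,
  "ring_face": "standard",
  "asn_swing": "swing_in",
  "chi1": 19.1,
  "chi2": 94.0
}
```

The C4–C4 distance of 3.4 Å lies inside the 3.0–3.7 Å productive window
(hydride transfer geometrically possible); the 2.6 Å Tyr-OH⋯O4 contact is
the catalytic acid/base hydrogen bond; the sugar sits on the pro-S face of
the nicotinamide ("standard" conformation) and the C2-pocket Asn is closed
around the C2 substituent ("swing in").

The numbered drivers under `analysis/` run each study stage end to end and
write tables under `results/`; for example

```bash
$ python analysis/02_superposition_benchmark.py --seed 1
20 fixtures: max |Kabsch - oracle| = 0.00e+00 A; trimming recovered the
planted clean set in 20/20 cases; trimmed RMSD <= untrimmed in all 20/20.

$ python analysis/06_specificity_calls.py
8/8 predictions match the activity-derived labels (5 characterized
enzymes, BLLJ_1592 group-1-like, 2 C5 mutants).
```

To analyze real deposited entries, put the files where the config points
and run the full pipeline:

```bash
episcope run config.yaml --out report.json
```

(the config schema is documented in `docs/methods.md`).

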
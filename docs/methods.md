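# Methods

## Scope and model

`episcope` implements the computational side of a comparative structural
study of UDP-glucose 4-epimerases (GalE, EC 5.1.3.2).  GalEs are
SDR-superfamily enzymes that interconvert UDP-Glc/UDP-Gal — and in some
homologs the N-acetylated UDP-GlcNAc/UDP-GalNAc — through transient C4
oxidation by a tightly bound NAD⁺, rotation of the 4-ketopyranose
intermediate, and re-reduction.  Substrate range falls into groups:
group 1 (Glc/Gal only; phylogenetic subgroups 1a and 1b), group 2 (dual),
and group 3 (GlcNAc/GalNAc preferring).  The analyses the package covers:

* rigid-body Cα superposition with iterative distance-cutoff trimming,
* active-site geometry: catalytic C4–C4 distance with a productive-mode
  call, hydrogen-bond/salt-bridge inventories, sugar ring face, and the
  C2-pocket Asn swing conformer,
* solvent-accessible surface area (SASA) and dimer-interface burial,
* pairwise global alignment, percent identity, cross-homolog residue
  mapping, sequence-deduced protein mass, and neighbor-joining phylogeny,
* the two-pocket substrate-specificity classifier.

## Superposition (`superposition`)

The core fit is the closed-form least-squares rotation (SVD of the paired
covariance, smallest singular axis flipped when the raw solution is a
reflection), applied to Cα pairs derived from the non-gap columns of a
sequence alignment — pairing is alignment-driven, never author-numbering
driven, because homolog numbering differs (e.g. the catalytic Tyr is 150 in
the *B. longum* enzyme and 157 in the human one).

The trimmed variant iterates: fit the retained pairs, recompute every
retained pair's deviation, drop **all** pairs above the cutoff (2.0 Å
default), and stop when the retained set is stable.  Dropping all
over-cutoff pairs per round (rather than one at a time) converges in a few
iterations and is the common practice; `max_iter` defaults to 20 and
non-convergence is reported as a warning carrying the last fit.  Reported
statistics are the RMSD and pair count over the final retained set, the
convention behind "0.69 Å (306 a.a.)"-style numbers.  Fewer than three
retained pairs raises a convergence error; collinear inputs raise a
degenerate-geometry error (the rotation about the line is undefined; the
test is `s₂/s₁ < 1e-9` on the covariance singular values).

## Active-site geometry (`active_site`)

All criteria are heavy-atom-only (crystal structures at this resolution
carry no hydrogens):

* **Hydrogen bond** — N/O/S pair within `dmax` (default 3.5 Å) where at
  least one side is a plausible donor.  Donor chemistry for protein atoms
  follows a fixed side-chain table (backbone N always donates; Asp/Glu
  carboxylates and backbone carbonyls never do); atoms of het groups and
  waters are assumed donor-capable, which is the right default for sugar
  hydroxyls.  No angle term is applied — without hydrogens an angle would
  be a guess.
* **Salt bridge** — Lys NZ / Arg NE,NH* / His ND1,NE2 within `dmax`
  (default 4.0 Å) of a carboxylate oxygen or a nucleotide phosphate oxygen
  (name-matched against the standard O1A/O2B/OP1… set).
* **Productive mode** — sugar-C4 to nicotinamide-C4 distance within
  [3.0, 3.7] Å, the span compatible with hydride transfer.  Bounds are
  inclusive, with a 1 × 10⁻⁹ Å guard against float accumulation.
* **Ring face** — the nicotinamide plane normal is the Newell normal of the
  ring atoms taken in dictionary order (N1→C2→…→C6); the package's
  convention is that the +normal side (the face from which that ordering
  appears counterclockwise) is the pro-S face.  The sugar C4 on the pro-S
  side ⇒ "standard" sugar conformation, the other side ⇒ "flipped".  The
  call is invariant under proper rotation and flips under reflection, which
  the tests assert.
* **Asn swing** — the primary discriminant is the distance from the
  carboxamide centroid (OD1/ND2 midpoint) to the sugar C2 substituent
  (O2 or N-acetyl nitrogen): within the threshold ⇒ "swing in" (pocket
  closed around the substituent), beyond ⇒ "swing out".  χ1 (N–CA–CB–CG)
  and χ2 (CA–CB–CG–OD1) are reported for transparency but do not drive the
  call, as χ clustering is less robust across homologs.  The threshold
  defaults to 5.0 Å — a side-chain contact-distance scale; it could not be
  calibrated against the two deposited sugar complexes in this build (no
  local copies), so it is config-exposed and should be re-checked against
  them when coordinates are at hand.

Ligand atom naming is configurable through `LigandRoles` (role → het code
and atom names), defaulting to the chemical-component-dictionary names
(NAD ring N1N…C6N, sugar C4′/O4′); the synthetic toy complexes use a plain
preset (`TOY_ROLES`).

## Surface area and interface (`surface`)

Shrake–Rupley sphere sampling with a deterministic golden-spiral point set
(no RNG) so results are bit-reproducible; default 960 points per atom,
probe radius 1.4 Å (a water).  Van der Waals radii come from one documented
element-keyed table (C 1.70, N 1.55, O 1.52, S/P 1.80, Mg 1.73, …),
config-overridable.  Waters and monoatomic ions are excluded by default.
Interface burial of a two-chain assembly is

    buried_total = SASA(A) + SASA(B) − SASA(AB)

with `buried_half = buried_total / 2` also reported, because published
"interface area" figures use either the total-burial or the half-sum
convention and rarely say which; comparisons against published values
should try `buried_total` first and record the convention that reproduces
the number.  Interface residues are those losing any accessible area
(> 1 × 10⁻⁶ Å²) on assembly.  Verified closed forms: a single sphere's
4π(r+1.4)² and the two-sphere spherical-cap formula; the sampler agrees to
< 1% at 960 points (single sphere) and at 9 600 points for small caps,
and is additionally cross-checked against biotite's independent sampler.

## Sequences and phylogeny (`sequences`)

Needleman–Wunsch global alignment with affine gaps via Biopython's
`PairwiseAligner`: BLOSUM62, gap open 10, gap extend 0.5 by default, first
(high-road) traceback for deterministic ties.  'X' is tolerated but never
counted identical.  Percent identity defaults to the
non-gap-aligned-columns denominator; `shorter_seq` and `alignment_length`
are selectable because published identity figures rarely state one.
Residue maps are built from non-gap columns only and carry author
numbering when derived from structures.  Protein mass is the
average-isotopic residue sum plus one water (Biopython's tables).

Distances for trees are 1 − fractional identity (matching the
"% sequence divergence" scale bars of the field's figures); a Kimura-style
correction −ln(1 − p − 0.2p²) is optional.  Neighbor joining runs through
scikit-bio; negative branch-length estimates are clamped to zero and
flagged.  NJ is exact on additive matrices — the tests assert exact
recovery of 4- and 5-taxon tree metrics and topology recovery on simulated
families.

## Specificity classifier (`specificity`)

Pocket profiles take the residues at the *B. longum* anchor positions
(Lys85, Ser125/Tyr150/Lys154 triad, Asn180, C2 pocket 200, C5 pocket 299)
through an alignment-derived residue map.  The rule cascade, with C5 pocket
size as the primary factor:

1. bulky C5 residue (Tyr/Phe/Leu/Ile/Met/Trp/His, plus other large side
   chains by volume) ⇒ small C5 pocket ⇒ group 1 (Glc/Gal preferring).
   The 1a/1b split is phylogenetic: a clade hint ("1a"/"1b") is taken
   directly; "unplaced" (outside the characterized clades) yields group "1"
   with an explicit group-1-like caveat; without a tree, C2 refines —
   His-like large ⇒ 1a, Asn ⇒ 1b.
2. small C5 (Cys/Ser/Gly/Ala/Thr, …) and C2 = Asn ⇒ group 2 (dual).  The
   trace carries the caveat that a group-1b enzyme with a small C5 residue
   would be indistinguishable by pocket identity alone.
3. small C5 and small C2 (Ala/Gly/Ser) ⇒ group 3.
4. anything else ⇒ unknown (a valid outcome).

Size classes beyond the residues observed in characterized enzymes are
assigned by side-chain volume and are config-overridable.  Predictions are
categorical; no activity magnitudes are estimated, and no pocket-volume
computation is attempted — the argument is by residue identity.  In-silico
point swaps (`mutate_and_reclassify`) model the characterized C5 mutants:
Tyr→Cys at the eGalE 299 position moves the profile to the dual side,
Cys→Tyr at the hGalE 307 position moves it to group 1.

## Synthetic data (`synthetic`)

All randomness flows through numpy's PCG64 `default_rng`; the same seed
reproduces a fixture byte-for-byte, and every generator returns a manifest
recording the planted ground truth so oracles are exact.  What the
generators emulate, and what they do not:

* **paired clouds / rotated copies** — uniform point clouds under exact
  rigid motion, Gaussian coordinate noise (σ in Å), and planted outliers at
  a fixed displacement.  They exercise the fit and trimming machinery but
  have no protein-like covariance structure.
* **toy ternary complexes** — idealized planar rings (1.39/1.45 Å bonds)
  standing in for nicotinamide and pyranose, a Tyr-like OH at a planted
  O4 distance (2.6 Å default), an Asn-like carboxamide planted at the
  swing-in (3.5 Å) or swing-out (9.0 Å) distance, the whole complex under
  a random rigid motion.  Geometry operations read only names and
  coordinates, so the chemical idealization does not affect what is tested;
  it does mean passing tests certify the measurement conventions, not
  crystallographic realism.
* **dimer spheres** — one- or many-atom protomers at a set separation,
  with the single-atom case giving a closed-form buried area.
* **sequence families** — a root sequence mutated along a given tree:
  Poisson(branch length × length) substitutions per branch, each at a
  uniform site to a uniform different residue.  Expected per-site
  divergence matches path length only for short branches (no multiple-hit
  correction is applied in the generator; corrections belong to, and are
  tested in, the distance step).  No rate heterogeneity, indels, or
  site-specific conservation — so tree tests certify the NJ machinery,
  not robustness to realistic protein evolution.

## Pipeline and configuration (`pipeline`, `cli`)

`run_report` executes align → map → superpose/profile → classify → tree
(→ interface) from a YAML config:

```yaml
anchor:   {id: bGalE, sequence: bgale.fasta}       # or sequence_str
subjects:
  - {id: hGalE, sequence: hgale.fasta, clade: "2"} # clade hint optional
  - {id: 6K0H, structure: 6k0h.pdb, chain: A}
comparisons: [[6K0H, hGalE]]
dimer: dimer.pdb                                   # optional, 2 chains
roles: {nicotinamide_code: NAD, sugar_code: UD1}   # ligand role map
options: {cutoff: 2.0, probe: 1.4, n_points: 960,
          align: {matrix: BLOSUM62, gap_open: 10, gap_extend: 0.5}}
```

Stage failures are isolated per subject as error records; `n_errors`
summarizes.  The catalytic stage applies only to subjects whose structure
contains the configured cofactor het group.  Reports are deterministic
(byte-identical on re-run) and embed all effective options.  The analysis
never fetches remote data; deposited entries are supplied as local files.
The `episcope` command exposes each module as a subcommand (`superpose`,
`active-site`, `interface`, `identity`, `tree`, `classify`, `simulate`,
`run`).

## Problem sizes and numerical choices

Default benchmark sizes, chosen to characterize the estimators well while
keeping each analysis script in the seconds range: 20 seeded 50-point
clouds for the fit-vs-oracle comparison (the oracle is a multi-start
Nelder–Mead search over rotation space), 10 trimming fixtures of 20 true +
5 outlier pairs, 960/9 600 SASA points, 400-residue simulated families with
six leaves.  Ties in altloc resolution go to the earlier letter; ties in
alignment traceback to the aligner's first path.  Distances are reported to
one decimal in reports (full precision internally).

## Limitations

* The deposited-entry comparisons (RMSD panels, C4–C4 distances, interface
  areas, identity percentages against the real GalE homologs) require
  local copies of the published PDB/UniProt entries under `data/deposited/`;
  the corresponding tests state exactly which files they need and fail
  with that message when the files are absent.
* The swing threshold awaits calibration against the two deposited sugar
  complexes (above).
* The published interface figures come from PISA, whose exact radii and
  solvation model are not reproduced here; agreement should be expected at
  the few-percent level and the ΔG of assembly is deliberately out of
  scope.
* Group 1b vs group 2 cannot be separated by pocket identity alone (both
  can carry C2 Asn); the classifier says so in its trace rather than
  guessing.
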
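# Deposited inputs (not redistributed)

The tests and pipeline configs that reproduce measurements on the real GalE
entries look for local copies of published database files in this
directory.  Fetch them once and place them here:

| file              | contents                                              | source            |
|-------------------|-------------------------------------------------------|-------------------|
| `6K0G.pdb`        | bGalE + NAD+/UDP ternary complex                      | RCSB PDB 6K0G     |
| `6K0H.pdb`        | bGalE + NAD+/UDP-GlcNAc                               | RCSB PDB 6K0H     |
| `6K0I.pdb`        | bGalE + NAD+/UDP-Glc                                  | RCSB PDB 6K0I     |
| `1HZJ.pdb`        | human GalE (chain B used)                             | RCSB PDB 1HZJ     |
| `1XEL.pdb`        | E. coli GalE                                          | RCSB PDB 1XEL     |
| `2CNB.pdb`        | T. brucei GalE (chain A used)                         | RCSB PDB 2CNB     |
| `1SB8.pdb`        | P. aeruginosa WbpP                                    | RCSB PDB 1SB8     |
| `6K0G_dimer.pdb`  | two-chain biological assembly of 6K0G (e.g. PISA/PDB  | assembly file for |
|                   | assembly 1, chains renamed A/B)                       | 6K0G              |
| `bgale.fasta`     | bGalE sequence (B. longum JCM1217, locus BLLJ_1620)   | UniProt/GenBank   |
| `hgale.fasta`     | human GalE sequence                                   | UniProt Q14376    |
| `bllj1592.fasta`  | BLLJ_1592 paralog sequence                            | GenBank           |
| `3enk.fasta`      | B. pseudomallei GalE sequence (entry 3ENK)            | RCSB PDB 3ENK     |
| `construct.fasta` | 348-residue recombinant bGalE construct               | bgale.fasta 1-340 |
|                   | (residues 1-340 + C-terminal LEHHHHHH tag)            | + tag             |

mmCIF files work equally (`read_structure` auto-detects); keep the `.pdb`
names above or adjust the paths in your config.
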
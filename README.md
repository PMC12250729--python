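# mfccpocket

Per-residue protein–ligand interaction energies by conjugate-cap
fragmentation, with binding-pocket radius-convergence scans and
conceptual-DFT reactivity descriptors.

## Who this is for

Structural bioinformaticians and computational chemists who want to decompose
a receptor–ligand binding energy into individual amino-acid contributions —
for example to rank the residues of a GPCR binding pocket by how much they
stabilize an antagonist — without committing to a particular energy engine.
The package supplies the fragmentation bookkeeping, the pocket-selection
protocol and a classical pairwise backend for desk-scale work, plus a
file-based adapter for handing fragment geometries to an external
quantum-chemistry code.

## The method

**MFCC decomposition.** For a target residue R<sub>i</sub> in a polypeptide,
the molecular fractionation with conjugate caps (MFCC) scheme cleaves the two
peptide bonds flanking R<sub>i</sub>, caps the fragment with the entire
neighbouring residues C<sub>i−1</sub> and C<sub>i+1</sub>, terminates every
broken bond with a hydrogen, and combines four single-point energies into the
ligand–residue interaction energy:

```
E_I(L−R_i) = E(L·C_{i−1}R_iC_{i+1}) − E(C_{i−1}R_iC_{i+1})
           − E(L·C_{i−1}C_{i+1})   + E(C_{i−1}C_{i+1})
```

The concap term (last) corrects for the cap–ligand interaction being
subtracted twice. No fragment is re-optimized: every atom keeps its source
coordinates, so for any pairwise-additive backend the combination collapses
exactly to the direct ligand–residue pair energy — a cancellation the test
suite verifies against an independent brute-force double loop.

**Pocket convergence.** Residues enter the analysis through spheres of
increasing radius around the ligand (r = 2.0 … 8.0 Å in 0.5 Å steps). The
running total — the sum of per-residue E_I over the shell — is declared
converged at the first radius where its relative change falls below 10% at
every dielectric (ε = 10, 20, 40 by default; the dielectric divides the
Coulomb term as a uniform screen).

**Descriptors and scores.** From frontier-orbital energies the package
computes I = −E(HOMO), A = −E(LUMO), GAP, hardness η = (I−A)/2, softness
σ = 1/η, chemical potential μ = −(I+A)/2, electronegativity χ = −μ and the
electrophilicity index ω (both the standard μ²/2η and the μ²·η/2 convention
used in some published tables), plus the weighted docking-score combination
HS = 1.0·E_vdw + 0.2·E_elec + 1.0·E_desolv + 0.1·E_air.

## Worked example

The `demo` subcommand builds a synthetic three-residue complex with a rigid
four-atom ligand at controlled distances, writes it as PQR with a matching
ground-truth JSON, and runs the full decomposition:

```bash
mfccpocket demo --outdir demo --seed 7
cat demo/run/report.txt
```

```
Per-residue ligand interaction energies (MFCC, classical backend)
input: demo/fixture/fixture.pqr
dielectrics: 10, 20, 40
converged pocket radius: 3 Å

ranking at dielectric 10 (most attractive first):
  GLY1 (A)  E_I = -0.3008 kcal/mol  (min distance 2.08 Å)
  GLY2 (A)  E_I = -0.0099 kcal/mol  (min distance 3.38 Å)
  GLY3 (A)  E_I = -0.0024 kcal/mol  (min distance 5.98 Å)
  total at r = 8 Å: -0.3131 kcal/mol
```

Reading this: the residue closest to the ligand (2.08 Å) dominates binding
at −0.30 kcal/mol; contributions fall off with distance, and the shell total
stops changing once all three residues are inside, so the scan declares the
pocket converged at 3 Å. `demo/run/per_residue.tsv` holds the same numbers
machine-readably, and `demo/run/convergence.json` the radius-by-radius
totals. Raising the dielectric from 10 to 40 shrinks the screened Coulomb
part of each entry, which is why GLY1's energy relaxes from −0.3008 to
−0.2558 kcal/mol across the three columns of the TSV.

Descriptors from a small TSV of orbital energies:

```bash
mfccpocket descriptors orbitals.tsv --convention table -o out
mfccpocket score --vdw -25.2 --elec -59.6 --desolv -5.0 --air 0
# -42.1200
```

As a library, the same pipeline is three calls:

```python
from mfccpocket import ClassicalBackend, read_structure, run_scan

complex_ = read_structure("complex.pqr", ligand_selector="LIG")
scan, profile = run_scan(complex_, ClassicalBackend())
print(scan.converged_radius, profile.to_frame())
```

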
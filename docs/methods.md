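# Methods

This note records the models, conventions and design decisions behind
`mfccpocket`, in the spirit of a package manual's "theory" chapter. Nothing
here states an empirical result that the test suite or the acceptance script
does not itself compute.

## Fragmentation model

A complex is one or more polypeptide chains partitioned into residue groups
plus exactly one ligand group. For a target residue R_i the four MFCC systems
are built at frozen source geometry:

- **cap·R·cap** — C_{i−1} + R_i + C_{i+1}, where the caps are the *entire*
  neighbouring residues (side chains included). No reduced CH3CO/NHCH3 caps
  are offered; whole-residue caps preserve the local chemical environment
  with no extra geometry decisions.
- **concap** — the two caps with R_i removed and the two bonds that went to
  R_i replaced by *junction hydrogens*, placed along the exact former bond
  unit vectors: on the C_{i−1} carbonyl carbon at the C–H length (1.090 Å
  default) and on the C_{i+1} amide nitrogen at the N–H length (1.010 Å
  default). The two caps are not fused — they are not covalently adjacent —
  so the concap is simply both hydrogen-terminated caps in one calculation.
- The ligand-containing partners of both, sharing the receptor atoms
  object-identically.

**Outer hydrogens.** The far ends of the caps (where residues i−2 and i+2
were attached) are always hydrogen-saturated, along the former bond vector
when that neighbour exists. When a cap is a true chain terminus there is no
former bond; the hydrogen is then placed along the missing-valence direction,
−Σ(unit vectors to the atoms bonded to the junction atom). Outer hydrogens
appear identically in the cap·R·cap and concap systems, so they cancel in
the four-term combination; junction hydrogens appear only in the concaps.
This is why, for a strictly pairwise-additive backend,

    E_I = pairsum(L, R_i) − pairsum(L, junction hydrogens)

holds exactly (term cancellation), and with ghost cap hydrogens (zero charge,
zero LJ depth — the default) E_I equals the direct ligand–residue pair energy
to summation precision. The test suite asserts both identities.

**Edge cases.** A terminal target residue gets a cap on its one existing
side only; a residue with no bonded neighbour on either side is an error.
A sequence neighbour counts as bonded only if the peptide N–C distance is
≤ 2.0 Å; larger gaps are chain breaks treated as termini (logged). A target
residue whose side chain is covalently bonded outside its own group (e.g. a
disulfide bridge) is refused — cross-link cleavage is out of scope. Proline
would be treated like any residue: the junction hydrogen replaces the
R_i-ward bond and ring atoms are untouched.

## Energy backends

The backend contract is a deterministic scalar energy (kcal/mol) for an atom
system at a dielectric. Two implementations:

**Classical pairwise.** E = Σ_{i<j} [332.0637·q_i q_j/(ε r_ij) +
ε_ij((r_min,ij/r_ij)¹² − 2(r_min,ij/r_ij)⁶)] with ε_ij = √(ε_i ε_j) and
r_min,ij = r_min,i/2 + r_min,j/2. There are no bonded terms and no 1-2/1-3
exclusions: the MFCC combination subtracts identical-geometry subsystems, so
every intra-fragment term cancels and exclusions would be dead weight. The
uniform dielectric divides the Coulomb term (distance-independent screen),
standing in for a continuum solvent model; Coulomb-only systems therefore
scale exactly as 1/ε. Pair sums use exactly-rounded (`math.fsum`) summation —
the four-term combination cancels large intra-fragment contributions, and
naive summation-order noise would otherwise leak into the result at ~1e-7
kcal/mol. Distances below 0.1 Å are treated as clashes and rejected.

**External-QM file adapter.** Emits a generic plain-text single-point input
(route line with method/basis/solvent labels and the dielectric, title,
`net_charge multiplicity`, Cartesian block; defaults B97D/6-311+G(d,p)/CPCM)
and parses a final-energy line (Hartree, configurable regex; last match wins)
from the output, converting at 627.509474 kcal/mol per Hartree. The net
charge defaults to the rounded sum of partial charges; a sum more than 0.3 e
from an integer is refused so the caller must decide. Without a configured
runner the adapter emits inputs and reports "awaiting energies" — it never
executes external programs on its own.

## Pocket protocol

A residue is inside radius r when the minimum over all ligand-atom/
residue-atom distances (hydrogens included — the wording of distance criteria
rarely excludes them explicitly, and including them is the conservative
choice) is ≤ r. The schedule is r = 2.0 … 8.0 Å in 0.5 Å steps,
config-overridable. Each residue's quartet is built and evaluated once; shell
totals are exact sums (`fsum`) of the cached per-residue energies, so the
"totals equal shell-restricted profile sums" invariant holds bitwise.

Convergence: the first successor radius r′ with
|total(r′,ε) − total(r,ε)|/|total(r,ε)| < tolerance (default 0.10)
*simultaneously at every dielectric*. A zero previous total makes that
comparison undefined; it is skipped and logged, and a step with no valid
comparison cannot declare convergence. The strict `<` means tolerance 0
never converges. Ranking sorts most-negative-first with ties broken by
(chain, sequence number).

## Descriptors

Koopmans-style identifications I = −E(HOMO), A = −E(LUMO). Chemical potential
and electronegativity carry their standard signs (μ < 0 for bound systems);
`mu_as_printed`/`chi_as_printed` expose the flipped orientation some
published tables use. Two electrophilicity conventions are exposed
explicitly — standard ω = μ²/(2η) and the table convention ω = μ²·η/2 —
because published descriptor tables are not consistent about which they
print; their ratio is exactly η². Degenerate orbitals (η = 0) leave softness
and electrophilicity undefined rather than infinite.

## Synthetic fixtures

The generator emulates the *geometry and bookkeeping* of a binding pocket,
not its chemistry: GLY-like five-atom residues (N, CA, C, O, amide H; an
optional CB pseudo-atom exercises side-chain capping) in an extended chain
with 3.8 Å CA–CA spacing and ~1.4 Å peptide C–N bonds; a rigid ligand of
3–10 atoms on a 0.8 Å Fibonacci sphere, posed by a 6-dof Nelder–Mead search
so that chosen residues sit at requested minimum distances (met within
0.05 Å, aimed 0.02 Å under the request so a shell at exactly the requested
radius contains the residue despite coordinate quantization). Coordinates
and charges are quantized to 4 decimals — the precision the PQR writer
emits — so the in-memory structure, the file and the ground truth describe
the same numbers and file round-trips are exact.

Default per-residue charges form a neutral dipole pattern
(N −0.4, CA +0.1, C +0.5, O −0.5, H +0.3 e); LJ well depths are Amber-like
but the radii are scaled to the fixture's contact scale (r_min/2: H 0.4,
C 1.0, N 0.95, O 0.9 Å) so a ~2 Å ligand contact sits near the LJ minimum
rather than deep inside the repulsive wall — pocket shells start at 2 Å.
The decaying-energy fixture uses five residues, Coulomb-only parameters and
per-residue charge scales falling off along the chain (0.5, 1.0, 0.08, 0.04,
0.02 with the ligand nearest residue 2), so the first shell addition changes
the running total by well over 10% and later additions by much less; its
ground truth records the resulting converged radius.

The ground truth is computed by a deliberately naive pure-Python double loop
that shares no code with the vectorized backend; the end-to-end agreement
tests are meaningful only because the two routes are independent.

**What passing fixtures does and does not show.** Agreement validates the
fragmentation algebra, capping geometry, shell bookkeeping and dielectric
handling. It says nothing about force-field accuracy, protonation states,
conformational sampling or solvent structure in real receptors — fixtures
have no realistic parameterization, no membrane or water, and single static
geometries. Published per-residue DFT energies for real receptor–drug
complexes additionally depend on MD-final coordinates and the quantum
backend, neither of which the classical desk-scale route reproduces; such
values are used here only as ready-made inputs for ranking/summation
checks and descriptor arithmetic.

## Numerical choices and problem sizes

- Electrostatic constant 332.0637 kcal·Å/(mol·e²); 1 Ha = 627.509474
  kcal/mol; distances in Å, energies in kcal/mol, charges in e.
- Parsed PQR/PDB values are re-quantized to their written decimal precision
  (4/3 places) because MDAnalysis stores them in single precision; rounding
  recovers the exact written value in double precision.
- Alternate locations other than blank/"A" are discarded with a warning;
  hydrogens present in the input are kept and none are added.
- Ionizable-residue charge states are never guessed: fixtures declare their
  charges explicitly, and real inputs carry theirs in the PQR.
- Randomized equivalence tests use 20 complexes of 3–6 residues and 3–9
  ligand atoms — large enough to exercise one-sided caps, both junction
  types and every shell transition, small enough that the whole suite runs
  in well under a minute of energy evaluation.

## Known limitations

- Single static geometry per analysis; no trajectory averaging.
- No mmCIF input, no structure repair, no protonation assignment.
- The classical backend is a screened-Coulomb + LJ stand-in; it shares the
  MFCC bookkeeping with a QM treatment but none of its electronic structure
  (polarization, dispersion beyond LJ, charge transfer).
- Cross-linked residues (disulfides) cannot be fragmented.
- The concap convention (two individually capped neighbours, not fused) is a
  documented choice; other MFCC implementations differ, and absolute E_I
  values from non-additive backends will depend on it.
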
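# Methods

## The QTY substitution model

The QTY code maps L→Q, I→T, V→T, F→Y and leaves every other residue fixed.
Q, T and Y are themselves fixed points, so the conversion is idempotent; it is
also invertible given the substitution list, which the package records as
`(position, from, to)` triples. By default substitutions are restricted to
annotated TM segments (`scope="tm_only"`), because the analysis separates TM
from overall variation and the conversion is motivated by the lipid-facing
helices; a `whole_sequence` scope exists for experimentation. Requesting
`tm_only` conversion of a record without TM annotation raises an error rather
than silently returning the input. TM segments are user-supplied (UniProt
TRANSMEM-style, 1-based inclusive everywhere); the package does not predict
topology.

Variation percentages are 100·(substitutions)/(sequence length) overall and
100·(TM substitutions)/(TM residues) within segments, reported to two
decimals (Python's round-half-even). A record with zero TM residues has an
*undefined* TM percentage, flagged as `None` / an exception, never silently 0.

## Molecular weight and isoelectric point

MW is the sum of Expasy-compatible average in-chain residue masses plus one
water (18.0153 Da). The commonly printed *free amino-acid* masses
(e.g. L 131.17, Q 146.14, F 165.19, Y 181.19 Da) are these residue masses
plus one water; `free_amino_acid_mass()` exposes them. Per-substitution mass
deltas are Q−L = +14.97, T−V = +1.97, Y−F = +16.00 and T−I = −12.05 Da; only
the I→T substitution loses mass, so the analog MW of a typical TM helix
rises slightly. The
mass-delta closure invariant (analog MW − native MW = Σ per-substitution
deltas, ±0.01 Da) is tested on random sequences.

pI is the root of the Henderson–Hasselbalch net-charge function over the
termini and the ionizable side chains D, E, H, C, Y, K, R, using the
Bjellqvist/Expasy pKₐ set (N-term 7.5, C-term 3.55, D 4.05, E 4.45, H 5.98,
C 9.0, Y 10.0, K 10.0, R 12.0; configurable via `PkaTable`). The charge is
strictly decreasing in pH and brackets zero on [0, 14], so bisection to
0.001 pH always converges. Tests compare against an exhaustive 10⁻⁴-pH grid
scan and against Biopython's independent solver. QTY conversion shifts pI
weakly because Q and T are non-ionizable and Y contributes only near pH 10;
this is asserted as a <1 pH-unit property on synthetic TM sequences, not as
an exact value.

## Structure handling and superposition

Structures are read with gemmi (PDB and mmCIF), keeping author residue
numbering, resolving altlocs to the highest-occupancy conformer, and dropping
waters and hetero ligands. Residue correspondence between a native reference
and a predicted model is by author number within mapped chains: residues
missing from either side (cryo-EM loop gaps, trimmed monomers) are dropped
and recorded, and residue-name mismatches are accepted when the pair lies in
one QTY equivalence class ({L,Q}, {I,V,T}, {F,Y}) so that native-vs-analog
comparisons pair cleanly. Sequence-independent structural alignment is out
of scope by design — the compared structures share numbering by
construction.

Superposition is the closed-form Kabsch solution (SVD of the covariance
matrix with determinant correction, guaranteeing det R = +1) over Cα atoms by
default; any atom subset (e.g. full backbone) can be requested. Fewer than
three pairs, or collinear point sets (second singular value < 1e-8 of the
first), raise explicit errors. Optional outlier rejection repeats the fit up
to `max_cycles` times, each cycle removing pairs deviating beyond
max(cutoff, 2·current RMSD); the adaptive floor prevents one gross outlier —
which inflates every residual of the initial fit — from triggering mass
rejection. Defaults are rejection *off* and, when enabled, (2.0 Å, 5 cycles);
both settings should be reported side by side when they differ, since
refinement-based tools (e.g. PyMOL's `super`) trim pairs with unpublished
parameters and bit-exact agreement with them is not promised. The test suite
checks Kabsch output against an independently coded Horn quaternion
eigenvalue solver (1e-6 Å) and against exhaustive rotation grids on tiny
point sets.

## Hydrophobic surface

SASA is computed by the Shrake–Rupley method: each heavy atom is inflated by
the probe radius (1.4 Å, water), its sphere is sampled with a deterministic
golden-spiral point set (default 960 points; the isolated-atom closed form
4π(r+probe)² is matched within 1%, and doubling the point count changes
totals by <0.5%), and a point is accessible when outside every neighboring
inflated sphere. Van der Waals radii are a Bondi-style standard set
(C 1.70, N 1.55, O 1.52, S 1.80 Å …), configurable; hydrogens are excluded
by default. mdtraj's implementation serves as an independent cross-check in
the tests.

The hydrophobic surface fraction — SASA of residues {L, I, V, F, M, W, A}
over total, optionally restricted to TM residues so extramembrane surface
does not dilute the signal — is the quantitative surrogate for hydrophobic
surface renderings. Proline is sometimes listed with the Type-II
(TM-helix) hydrophobic alphabet; the default set excludes it, and
`HydrophobicitySpec.with_proline()` / `--include-proline` adds it. At fixed
coordinates, QTY relabeling can only shrink the hydrophobic residue set, so
the fraction never increases — equality holds only when every substituted
residue is fully buried. This monotonicity is asserted; no absolute
hydrophobic-area values are claimed, since the reduction is the meaningful
quantity.

## DockQ interface scoring

Scoring follows the DockQ standard: contacts are residue pairs with any
heavy-atom distance < 5 Å; Fnat = |native ∩ model| / |native|; the receptor
is the larger chain (ties broken lexicographically); LRMS is the ligand
backbone ({N, CA, C, O}) RMSD after a Kabsch fit on the receptor backbone;
iRMS is the backbone RMSD over native interface residues (inter-chain heavy
atoms < 10 Å) after fitting on those same atoms;
DockQ = (Fnat + 1/(1+(LRMS/8.5)²) + 1/(1+(iRMS/1.5)²))/3, classed as
High ≥ 0.80, Medium ≥ 0.49, Acceptable ≥ 0.23, else Incorrect (lower edges
inclusive). All constants are configurable.

For a multi-chain complex every chain pair with at least one *native*
contact is scored; pairs with an empty native contact set are excluded, not
scored zero (their Fnat is undefined). The overall complex score is the
unweighted mean of per-interface DockQ values — the aggregation behind a
single "overall" number is not standardized, so a native-contact-weighted
mean is available as an option — and medians are reported over the scored
interfaces. Every score is checked against an independently coded oracle
(O(n²) contact scan + quaternion superpositions) to 1e-6 on randomized
two-chain fixtures.

## Synthetic data: what it emulates and what it does not

The generators produce, from a single integer seed, byte-identical fixtures:

* `make_tm_sequence` — one central TM segment covering `tm_fraction` of the
  chain, each TM position drawn as L/I/V/F with probability
  `hydrophobic_bias` (default 0.5 — roughly the L/I/V/F content of genuine
  TM helices, which is what yields TM substitution percentages in the
  25–65% range after conversion) and polar otherwise; loops use a polar
  alphabet free of substitutable residues.
* `make_helix` — ideal α-helix, CA on a 2.3 Å-radius wheel with 1.5 Å rise
  and 100° twist (≈3.8 Å CA–CA, 3.6 residues/turn), with schematically
  placed N, C, O and CB atoms so backbone- and heavy-atom-based operations
  have realistic atom sets.
* `make_toy_complex` — parallel helices at 9.5 Å axis spacing (adjacent
  chains in heavy-atom contact, non-adjacent ones beyond the 10 Å interface
  cutoff), plus a model copy under a named perturbation: rigid (known
  rotation/shift of the ligand chain or the whole complex), Gaussian
  coordinate noise of known σ, or loop deletion from the *native* copy,
  emulating unmodelled cryo-EM residues. The truth record carries the exact
  transform / σ / deleted residue list, so expected RMSD (√3·σ for Gaussian
  noise at large n), exact LRMS for pure translations, and the surviving
  pair set are all computable without re-running generation.

The geometry is schematic: no side chains beyond CB, no packing energetics,
no membrane. Passing tests therefore demonstrate the *algorithms* — 
substitution bookkeeping, trimming, superposition, contact and interface
mathematics, surface quadrature — under controlled truth, not predictive
accuracy on real structures. Conclusions about a real complex still require
real coordinates (a cryo-EM reference and predicted models), which the
pipeline consumes as ordinary PDB/mmCIF files.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run on small fixtures chosen to
keep the full run in seconds on one CPU while leaving every statistic
well-resolved: 20 synthetic subunits of length 80 for conversion statistics,
helices of 20–500 residues for superposition checks, an 8-chain × 30-residue
bundle (7 scored interfaces) for the DockQ report, and 960 sphere points for
SASA. Bisection tolerance is 0.001 pH; superposition degeneracy threshold
1e-8 (relative); PDB coordinates are written at the format's native 0.001 Å
resolution, which makes synthetic write/read round trips bit-exact.

## Known limitations

* No TM-topology prediction, reverse-QTY design, or structure prediction —
  predicted models are consumed as files.
* Correspondence is numbering-based; renumbered models need an explicit
  chain map and consistent author numbering.
* The outlier-rejection superposition approximates, but does not replicate,
  refinement-based tools; when comparing to numbers produced by such tools,
  report both with- and without-rejection RMSDs.
* SASA treats missing side chains as absent surface; comparisons should use
  models of comparable completeness (the loop-trimming step exists for
  exactly this reason).
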
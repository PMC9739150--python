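# Methods

## The geometric reactivity model

The analysis treats the first catalytic step of protein S-acylation —
autoacylation of the DHHC enzyme from acyl-CoA — as a geometry problem.
MD cannot describe the chemistry, so a frame is scored by whether the
reaction centers are arranged for a nucleophilic attack on the thioester
carbonyl:

* **D2 < 6 Å** — the catalytic nucleophile (Cys156 Sγ; the Ser156
  hydroxyl O when the catalytically dead mutant is analysed) is within
  roughly van der Waals contact of the carbonyl carbon;
* **αBD > 90°** — the Bürgi–Dunitz angle, defined here as the
  Nu–C(carbonyl)–O(carbonyl) angle with the vertex at the carbonyl
  carbon, is obtuse. The textbook optimum for simple carbonyls is ≈ 107°;
  enzyme active sites are known to relax it toward ~90°, but a productive
  attack remains on the oxygen's far side. The Flippin–Lodge angle, which
  would complete the attack coordinate system, is deliberately out of
  scope.

Both inequalities are strict: a frame exactly at a threshold is neither
reactive nor "improper" (improper = D2 < 6 Å with an acute angle — close
approach from the wrong side). With floating-point series the boundary is
measure-zero; strictness only pins down the contract.

**D1** measures cavity fitness: the ΔZ, along the membrane normal,
between the acyl tail's terminal carbon and the center of mass of the
cavity-ceiling triad (Ser29/Val185/Ser217 in hDHHC20). The ceiling COM
uses *all heavy atoms* of the three residues, mass-weighted. A Cα-only
convention shifts D1 by a few tenths of an Å; the crystal-reference
tolerance (±0.5 Å) absorbs this, and the choice is recorded here so
numbers are comparable.

**Selectivity profile.** Per chain length, the reactive fraction is the
share of frames classified reactive; the profile divides each fraction by
the sum across chain lengths and scales to percent, so the columns sum to
100 exactly and bars are comparable across lengths. The same
normalisation applied to improper fractions gives the contrast profile.

**Conditional averaging.** Table-style summaries report D1 averaged over
all frames, and D2/αBD averaged over frames with D2 < 6 Å (states where
the reaction partners are at least in contact). An alternative reading —
averaging over fully reactive frames only — is exposed as
`summarize(..., conditional="reactive")`. Standard deviations are the
sample (n−1) definition, recorded in the output metadata.

## Frames, membranes and orientation

The membrane normal is the laboratory Z axis; the membrane frame puts
Z = 0 at the mean Z of the lipid phosphorus atoms. No per-frame bilayer
plane fitting is attempted — trajectories are assumed pre-centered on the
protein (the convention of the common MD workflows this pipeline
consumes), and no periodic-image handling is applied inside the
protein–ligand complex for the same reason.

A crystal structure carries no bilayer, so for single-structure reference
values the membrane normal is defined by the first principal axis of the
transmembrane Cα cloud, sign-disambiguated by requiring the ceiling triad
above the catalytic residue (the teepee narrows toward the extracellular
side). Because D1 is a ΔZ, the unknown bilayer-center offset cancels;
only the axis direction matters, and the ±0.5 Å tolerance on the crystal
D1 covers the residual convention dependence.

Cα RMSD is computed against the first frame, mass-unweighted, after
optimal superposition (Kabsch via SVD; proper rotations only).

## Interaction fingerprints

* **Contacts**: heavy atoms only, fraction of frames with any pair below
  4.0 Å (strict). Hydrogens would double-count their carbons under a
  criterion calibrated for heavy atoms.
* **Hydrogen bonds**: donor–acceptor distance ≤ 3.5 Å and H–D–A angle
  ≤ 30°, the default geometric criterion of the standard gmx-style hbond
  tools; both configurable and echoed in the output manifest. Donor
  hydrogens are detected covalently (≤ 1.25 Å in the first frame).
  *Lifetime* is simple occupancy — the fraction of frames satisfying the
  criterion — not a continuous-segment statistic; reporting keeps bonds
  with lifetime strictly above 0.10, and a bond pooled over several
  trajectories is reported if it passes in at least one.
* **π-cation**: cation (Arg guanidinium CZ) within 6.0 Å of the
  aromatic-ring centroid and within 45° of the ring normal (plane fitted
  per frame by SVD). The interacting literature reports the lifetime but
  no criterion; these are common fingerprint defaults, configurable and
  recorded.

## Density profiles

Partial mass density per Z bin (default 1.0 Å): each atom's standard
atomic weight is assigned to its bin and divided by the slab volume, the
per-frame box XY area × bin width (semi-isotropic pressure coupling makes
the area fluctuate). Profiles are averaged over frames, which conserves
the group mass exactly — the suite asserts ∫ρ dz × area = group mass to
1e-6 relative. Units are amu/Å³ with an SI conversion helper. Per-frame
averaging (rather than pooling coordinates first) is the documented
choice; for constant boxes the two coincide.

## The synthetic generator

The generator emulates the *study design*, not the physics: a rigid
pseudo-enzyme with four tilted helical Cα lines (teepee), the ceiling
triad's heavy atoms all at Z = +8.1 Å (so the triad COM is exact by
construction), the catalytic residue at the cavity bottom, a pseudo-lipid
phosphorus slab at Z = ±17.5 Å, and an acyl-CoA-like ligand: an ideal
zig-zag acyl chain (1.53 Å C–C bonds, tetrahedral angles) hanging from
the terminal carbon, a thioester carbonyl at its base, a
pyrophosphate-like acceptor group and an adenine-like six-membered ring.

Per frame, D2 and αBD are drawn from truncated normals, D1 from a normal,
and the coordinates *realise the draws exactly*: the chain translates
along Z so the tip sits at ceiling-COM + D1, and the nucleophile atom is
placed at distance D2 from the carbonyl carbon in the attack plane at
angle αBD to the C=O bond. H-bond acceptors and the Arg guanidinium
toggle between bound and unbound geometries at prescribed occupancies
(deterministic toggling gives exactly `round(occ·n)/n`; Bernoulli
toggling is available). Every realised value lands in a ground-truth
ledger that the analysis modules never read.

Default conditions mirror the representative MD runs of the system this
package was built for: per-chain D1 means/sds of (−2.7 ± 0.6, −2.0 ± 0.6,
−2.1 ± 0.3, −2.1 ± 0.8, −1.9 ± 0.3) Å for C12…C20, a shared αBD truncated
normal (105 ± 35°, bounds 30–170°), D2 sd 0.5 Å (bounds 3–12 Å), H-bond
occupancies Ser143 0.30, Lys135 0.85, His140 0.80, His141 0.75, π-cation
0.95. The ceiling at +8.1 Å makes the C16 terminal-methyl level come out
at Z ≈ +6 Å, consistent with the D1 targets. For the benchmark suite the
reactive probabilities (0.05, 0.10, 0.60, 0.30, 0.08) are prescribed
analytically: the αBD marginal is fixed and each chain's D2 mean is
solved (Brent's method on the truncated-normal CDF) so that
P(D2 < 6)·P(αBD > 90) equals the prescription exactly. Realised flags
derive from the sampled values, so measured fractions scatter around the
prescriptions with plain binomial noise — the basis of the 3-SE recovery
tests.

Frames are independent draws by default. An AR(1) option correlates them
through a Gaussian copula (latent AR(1) normals mapped through the
truncated-normal quantile function), which preserves the marginals while
adding frame-to-frame memory; the recovery statistics are stated for the
independent case.

What the generator does **not** emulate: force-field energetics, protein
flexibility (the scaffold is rigid; only the reaction-center and toggled
atoms move), water/ions, chain exit/re-entry events, and autocorrelated
MD noise (unless AR(1) is switched on). Passing tests therefore
demonstrate the *correctness of the measurement pipeline* on systems with
known truth — not the physical realism of any MD data it may be applied
to.

The crystal-pose fixture is the same scaffold with the mutant Ser156
nucleophile and the ligand frozen at D1 = −4.07 Å, D2 = 6.6 Å,
αBD = 127° — the reference geometry of the trapped mutant complex —
optionally put through a random rigid motion so that recovering the
values exercises the orientation step for real.

## Numerical choices and degenerate inputs

* 2D (D2, αBD) histograms: default bins 0.25 Å × 5°, edges anchored at
  multiples of the bin width (sample-order independent); the mode is the
  maximal-count bin center with ties broken toward the lowest D2, then
  the lowest αBD.
* Summaries with no frame satisfying the condition flag the conditional
  fields as undefined (NaN), never zero; single-frame systems get NaN
  standard deviations.
* An all-zero selectivity profile is returned as all-zero with a warning
  rather than dividing by zero.
* Selections resolving to nothing are an error at pipeline start (fail
  fast), but an empty selection result is legal at the library level.
* Coordinates are Å everywhere; GRO nm are converted on read. Masses come
  from a built-in standard-atomic-weight table keyed by element, so COM
  work needs no force-field topology; atom names with no derivable
  element are an explicit error.
* Degenerate geometry (zero-length angle vectors, collinear ring or Cα
  clouds) raises rather than returning NaN.

## Problem sizes

The bundled tests and the acceptance script run the benchmark at 5000
frames per chain length (25 000 frames total, ~265 atoms per system) —
large enough that binomial recovery bounds are meaningful and small
enough to run in seconds. Determinism checks rerun the pipeline on
150-frame systems and compare outputs byte for byte.

## Known limitations

* Occupancy lifetimes ignore kinetics: a bond present in alternating
  frames and one present in a single long block score identically.
* The principal-axis membrane normal for crystals is a convention; values
  quoted for crystal structures carry the stated ±0.5 Å D1 tolerance for
  that reason.
* Contact-map columns are ligand atoms, so very large ligands produce
  wide tables; rows follow the topology's residue order.
* XTC/DCD input is supported through the same trajectory contract but is
  exercised less than the text formats in the test suite.
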
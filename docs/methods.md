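# Methods

## Scope and model

`pdzbind` analyses ordered ensembles of a two-chain complex (a PDZ-like
domain plus a C-terminal peptide ligand) under a purely geometric model:
every quantity is a function of atomic coordinates and explicit distance or
angle thresholds. No energies, force fields or solvent models enter
anywhere. The binding layer is likewise analytic: a 1:1 equilibrium with
ligand depletion for fluorescence polarization (FP), and the standard
thermodynamic identities for ITC-derived records.

The interchange format is the multi-model PDB file (one MODEL/ENDMDL block
per frame, fixed v3.3 ATOM columns). Every model must present an identical
(chain, residue, atom-name) sequence; insertion codes are ignored, altloc
conflicts resolve to blank-or-'A' by default, HETATM records are accepted
for peptide residues, and waters are dropped on read unless requested.
Binary trajectory formats are out of scope by design: desk-scale ensembles
in a fully specifiable text format keep the package dependency-light and
the artifacts diffable.

## Superposition and ensemble descriptors

Rigid superposition is the classical least-squares fit, computed by
`scipy.spatial.transform.Rotation.align_vectors` on centred coordinates.
Reflections are excluded (proper rotation always); fewer than three paired
points, or collinear points (rank of the centred coordinate matrix < 2 at
tolerance 1e-9), raise a degenerate-geometry error. Weights are optional
and default to uniform.

RMSD series superpose each frame onto a reference frame using a *fit*
selection and evaluate the RMSD over a separate *analysis* selection, which
expresses patterns like "peptide backbone RMSD after a domain Cα fit". The
default is the domain fit; fitting on the peptide itself is a configuration
choice. The reference frame reports exactly zero.

RMSF defaults to the starting structure as reference, matching the
convention of monitoring drift from an initial model; the ensemble-mean
reference is available for comparison and is never larger than the
starting-structure value. When a residue contributes several selected
atoms, its RMSF is the RMS over those atoms. Frames are assumed pre-aligned
unless an alignment selection is supplied. For iid isotropic Gaussian
fluctuations of width sigma about the reference, RMSF converges to
sqrt(3)·sigma — the closed form used throughout the recovery tests.

Ring-plane normals are the smallest-singular-vector of the centred ring
coordinates, *sign-matched to the Newell cross-product sum over the ordered
atom cycle* (for imidazoles: CG→ND1→CE1→NE2→CD2). The inter-normal angle is
therefore reported raw on [0, 180]° without folding: two near-parallel
imidazole rings whose cycles run in opposite senses legitimately read
~160°, not ~20°. This convention makes reported stacking angles
reproducible across software that preserves atom order. Collinear rings
(second singular value < 1e-9) are rejected.

## Interaction criteria and occupancy

Default thresholds (all configurable, echoed into reports for provenance):

| criterion | default | unit |
|---|---|---|
| H-bond donor-acceptor distance | 3.5 | Å |
| H-bond hydrogen-acceptor distance | 2.5 | Å |
| H-bond D-H-A angle (minimum) | 120 | deg |
| salt bridge N-O distance | 4.0 | Å |
| hydrophobic C-C distance | 5.0 | Å |
| stacking centroid distance | 6.0 | Å |
| stacking parallel tolerance (both ends of [0,180]) | 30 | deg |
| "stable" occupancy label | 0.7 | fraction |

Hydrogen-bond detection runs in two modes because ensembles may or may not
carry hydrogens: `with_hydrogens` applies the full three-part criterion;
`heavy_only` applies the donor-acceptor distance alone. The pipeline
auto-selects the mode from the topology.

Donor/acceptor atoms, charged groups, apolar carbons and ring cycles come
from name-based residue templates. Apolar carbons are side-chain carbons
minus carboxylate/carbonyl/guanidinium carbons; His ring carbons (CG, CD2,
CE1) count as apolar so His-ring/Arg contacts are detected. Histidine is
neutral by default in the Nδ1-protonated tautomer (ND1 donates, NE2
accepts); a charged-His flag makes both ring nitrogens donors and adds them
to the cationic table for low-pH scenarios.

A salt-bridge contact in which one nitrogen reaches both carboxylate
oxygens (or one oxygen both guanidinium nitrogens) in the same frame is one
*bifurcated* event, not two events; the reported distance is the minimum
over its qualifying pairs. Hydrogen bonds are reported once per (D, H, A)
triple. Scanning is inter-molecular (domain vs peptide) by default.

Occupancy is the fraction of analysed frames (a 0-based, half-open
(start, stop, stride) window) in which a pair meets its criteria; means and
SDs of distance/angle are taken over detected frames only, a deliberate
choice where gaps between detections are excluded from the averages.
Records are ordered by pair label for determinism. Every detector is
required by test to agree *exactly* with a naive all-pairs brute-force
filter — the implementation may be reorganised (vectorised, spatially
hashed) only if that equivalence is preserved.

The automatic interface scan enumerates candidate pairs across the chain
boundary whose reference-frame distance is within 1.5x the type's cutoff; a
planted or real contact therefore appears among the candidates whenever the
reference geometry satisfies it.

## FP and ITC mathematics

Anisotropy is r = (I∥ − I⊥)/(I∥ + 2 I⊥), bounded on [−0.5, 1]. Titrations
of protein P into fixed labelled ligand L follow the exact 1:1 depletion
isotherm (quadratic in the complex concentration); the quadratic form is
required because L is comparable to K_D in these assays. The discriminant
is clamped at zero against roundoff, and the P = 0 and Kd = 0 limits are
returned exactly.

The fit floats (A0, Am, Kd) — whether published fits fixed the anisotropy
bounds is generally unknown, so floating all three is the safe default —
with Kd bounded below by zero, A0/Am inside the physical anisotropy range,
trust-region least squares, and multi-starts from the half-range crossing
plus five log-spaced Kd guesses; the best SSR wins. Standard errors come
from the Jacobian at the optimum (covariance = RSS/dof x (JᵀJ)⁻¹). Flat
curves are *flagged* unidentifiable, not raised; a fitted Kd above the
highest titrated concentration clears the `saturation_reached` flag.
Replicates sharing the ligand concentration are pooled. A Monte-Carlo
calibration (200 seeded repetitions, 1% noise, 3 replicates) verifies that
the 3-SE interval covers truth in ≥ 95% of runs.

ITC records carry (K_D, ΔH°, T, n). ΔG° = −RT ln(1/K_D) against a 1 M
standard state with R = 1.9872e-3 kcal mol⁻¹ K⁻¹ and T = 298.15 K by
default; ΔS° = 1000·(ΔH° − ΔG°)/T in cal mol⁻¹ K⁻¹. Records may also carry
the instrument's own ΔG°/ΔS° columns: ΔΔ ledgers difference the supplied
values when present (differences of published columns reproduce published
ΔΔ figures, which recomputed values cannot when the table's K_D is
rounded), and any supplied ΔG° more than 0.05 kcal/mol from the recomputed
one is flagged as discrepant rather than silently overridden. Affinity
tables that mix K_D and EC50 labels are modelled identically by the 1:1
isotherm, with the label kept as metadata. Raw thermogram integration and
baseline correction are instrument-side and out of scope.

Histidine protonation uses the Henderson-Hasselbalch fraction
1/(1 + 10^(pH − pKa)) with pKa values supplied as inputs (the packaged
table carries published side-chain estimates for the His pairs at the
PDZ1-peptide interface).

## Synthetic ensembles: what they emulate, and what they do not

The generator emulates what an equilibrated MD trajectory looks like *to
the analysis code*: a fixed topology whose atoms fluctuate isotropically
and independently about a reference (per-residue sigma, default 0.3 Å,
chosen so typical Cα RMSF sits near the ~0.5 Å of a rigid, well-bound
domain core), with selected contacts present in a Bernoulli fraction of
frames at exact planted geometry. Frame 0 is the unperturbed reference, so
starting-structure references are noise-free and reference-frame scans see
every planted contact.

The default planted complex mirrors the interface this package was built
around: a bifurcated Glu-carboxylate/Arg-guanidinium salt bridge at 2.5 Å
(target occupancy 0.9), His-ring-carbon/Arg C-C contacts at 4.6 and 4.5 Å
(0.8 each), two His-His stacking pairs at centroid distances 5.0 and 5.2 Å
with a 160° raw normal angle (0.8 each), and a Thr-hydroxyl hydrogen bond
at 2.9 Å (0.7).

"On" frames place partner atoms exactly at the requested geometry relative
to the (noised) anchor; "off" frames push them at least 1 Å beyond the
distance criterion, so detector output on planted pairs equals the manifest
with no boundary flicker, and occupancy recovery is a pure binomial
sampling question (within 3·sqrt(p(1−p)/n) of target). Randomness flows
from one master seed through per-purpose `default_rng([seed, stream, ...])`
keys, so adding a plant never perturbs the base fluctuations or earlier
plants — a property under test.

What the generator deliberately does **not** emulate: bonded structure and
stereochemistry, correlated or anisotropic motions, slow conformational
drift, autocorrelation between frames, solvent, or boundary-straddling
contact distances. Passing recovery tests therefore demonstrates that the
*analysis* is correct and calibrated — not that any particular real system
behaves this way; statistics of real trajectories (frame correlation in
particular) will widen occupancy confidence intervals beyond the iid
binomial bound used here.

## Numerical choices and problem sizes

- Superposition optimality is tested against a brute-force rotation search
  (6° Euler grid plus 20,000 seeded random rotations, each with its optimal
  translation) rather than an exhaustive fine grid; the property checked is
  unchanged.
- Detector-oracle equivalence runs on 100 random 50-atom frames; planted
  recovery on 2,000-frame ensembles; RMSF calibration on 5,000 frames
  (20,000 for the closed-form unit check); the FP Monte-Carlo on 200
  repetitions. These sizes put every statistical bound well inside its
  tolerance while keeping the whole suite fast on one CPU.
- Degenerate inputs fail loudly and specifically: collinear fit points or
  rings, empty selections, empty frame windows, single-frame ensembles with
  an ensemble-mean reference, non-positive K_D, both FP intensities zero.
- Pipeline stages run in a fixed order and write artifacts as they
  complete; a stage failure raises a stage-tagged error, so a corrupt
  binding-assay input can never alter trajectory-analysis outputs (tested).
  Reports exclude timestamps, making regeneration byte-identical.

## Known limitations

- Interaction classes are distance/angle based only: no cation-π, π-anion
  or water-mediated bridges, and no energetic scoring.
- The PDB reader targets well-formed fixed-column files; it is not a
  recovery parser for pathological legacy files, and mmCIF is unsupported.
- Occupancy uncertainty assumes independent frames; users analysing
  correlated trajectories should subsample to an effective sample size
  before interpreting the binomial bounds.
- The FP model is strictly 1:1; competition/displacement formats and n ≠ 1
  stoichiometries are out of scope.
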
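# Methods

This note records the models, conventions and numerical choices behind
`nanostab`, in the order the pipeline applies them.

## Scope and system model

The package analyses *centered cluster* systems: a positionally restrained
drug crystal (≈35 Å cluster scale) surrounded by excipient, counterion and
water molecules. Coordinates are taken as already whole and imaged; all
distances are plain Euclidean and no minimum-image convention is applied
anywhere. Periodic analysis is deliberately out of scope.

Roles (`drug`, `excipient`, `counterion`, `water`) are attached per molecule
and drive everything downstream. The "drug crystal" is always the union of
all drug-role molecules. A heavy atom is any element other than H or D.

## Contacts

Two molecules are in contact in a frame when their minimum heavy-atom
distance is ≤ 4.5 Å. The boundary is inclusive ("within 4.5 Å" read as ≤);
exactly-on-boundary pairs are measure-zero in practice, so the choice is a
documented convention rather than a numerically consequential one. Setting
`heavy_only=False` includes hydrogens.

Neighbor search uses a k-d tree (`scipy.spatial.cKDTree`); an exhaustive
O(N²) all-pairs implementation is kept alongside as an independent oracle,
and the equivalence of the two is asserted exactly over hundreds of random
systems in the test suite — correctness is demonstrated, not assumed.

Trajectory statistics discard the first `equilibration_fraction` (default
0.5, i.e. the first half — the analogue of dropping 100 ns of a 200 ns run)
of frames:

* **Atomistic contact frequencies** — for each drug atom, the fraction of
  analyzed frames in which it lies within the cutoff of any excipient heavy
  atom (and symmetrically for excipient atoms vs drug). The frequency is
  per-frame/any-partner: touching three excipients in one frame counts once.
* **Coordination distributions** — the number of neighbor-role molecules in
  contact with a reference-role molecule, pooled over all analyzed frames
  and all reference molecules; molecules with no contacts populate bin 0.
* **Complex extraction** — the drug crystal plus every excipient *or
  counterion* in contact with any drug molecule in the chosen frame; water
  is always excluded, as are non-contacting molecules.

## Surface descriptors

**SASA** is computed with the Shrake–Rupley algorithm: each atom's sphere of
radius `r_vdw + probe` is sampled at `n_sphere_points` points of a
deterministic Fibonacci (golden-angle) sphere; a point buried strictly
inside any neighbor's expanded sphere is discarded, and the exposed fraction
scales the analytic sphere area. Defaults: probe 1.4 Å, 960 points, Bondi
radii (the radius table is pluggable). The point count satisfies a 1%
self-convergence criterion (960 vs 3840 points) on complex-sized systems. A
point lying exactly on a neighbor's boundary is assigned to the
lower-indexed atom — a tie-break that only matters for degenerate coincident
spheres, where it makes the pair report a single sphere's area instead of
double-counting the shared boundary.

**Polarity** (for FASA_p) uses an element rule: N, O, S and P atoms are
polar, plus every hydrogen attached to one of them; all else is nonpolar.
Hydrogen attachment uses explicit bonds when the molecule has them and falls
back to the nearest heavy atom in the same molecule otherwise (structures
read from PDB carry no bonds). The rule is a deterministic stand-in for the
partial-charge-threshold classifications of commercial packages; it is
pluggable, and no claim of numerical equivalence with any particular tool is
made. FASA_p = (polar-atom SASA) / (total SASA) ∈ [0, 1]; a zero total area
is an error, not a zero.

**R_g** is the mass-weighted radius of gyration about the center of mass
(standard atomic weights). **Dipole** is |Σ qᵢ·(rᵢ − r_com)| × 4.803 D/e·Å,
using per-atom partial charges when present and molecular formal charges at
molecule centroids otherwise. For net-charged systems the dipole is
origin-dependent; the center-of-mass origin is the fixed convention and the
value should be read accordingly (dipole is also the least predictive of the
four descriptors).

**Window statistics**: post-equilibration frames are split into five equal
contiguous windows; the complex is extracted at each window's *final frame*
(a snapshot, not a window-average structure — the procedure is open either
way and the snapshot choice is ours) and descriptors evaluated per window.
Reported values are across-window mean ± std. ASA and R_g ratios divide by
the bare crystal evaluated at frame 0 — legitimate because the crystal is
restrained and hence time-invariant.

## 2-D descriptors and the closed-form FASA_p model

Descriptor counting follows the Lipinski convention: HA = number of N and O
atoms; HD = number of hydrogens bonded to N or O; MW from standard atomic
weights; |q| = absolute molecular formal charge. Counting agrees with
RDKit's `NOCount`/`NHOHCount` on a 22-molecule fixture panel (oracle test).
Known caveat: the tool that produced the original descriptor tables is not
fully specified for sulfate-ester surfactants (SDS/SOS), whose published
acceptor counts appear to follow a different convention; predictions for
those excipients should be treated with care. Ionic drugs are described as
the bare ion (counterion excluded): anion MW, |q| = 1, and the acidic proton
removed from HD.

Oligomeric excipients are described at their simulated lengths: PEG and PPG
as 20-mers, poloxamer as an EO₅–PO₁₀–EO₅ triblock, Tween 80 with five
ethylene-oxide units per arm (w = x = y = z = 5; C₆₄H₁₂₄O₂₆, MW 1309.7,
HA 26, HD 3).

The reference predictor is linear in the six ratios HA_d/MW_d, HD_d/MW_d,
HA_e/MW_e, HD_e/MW_e, |q_d|/MW_d, |q_e|/MW_e with coefficients
(13.9, 27.0, 2.3, 4.3, 118, 10.6) and intercept −0.108. With no excipient,
all excipient terms are zero.

## Stability models

Logistic models are parameterised as log(P_f/P_s) = b0 + b1·x with natural
logarithm, so P_s = 1/(1+exp(b0+b1·x)); the shipped reference sets are
(6.14, −26.1) on simulated FASA_p and (13.5, −58.0) on predicted FASA_p.
Fitting is Newton–Raphson maximum likelihood (gradient tolerance 1e-8,
≤100 iterations), reported in the same sign convention. Perfect separation
is detected when iteration either diverges or "converges" with all fitted
probabilities saturated and label-perfect; the result is flagged rather than
silently returned.

Classification uses a P_s ≥ 0.5 threshold. Repeated k-fold cross validation
(default 100 rounds of 4-fold) partitions uniformly at random without
stratification — with n = 16 a fold can be single-class, which is fine for
scoring; only a single-class *training* set causes the fold to be skipped
with a warning. The reported standard deviation pools all rounds × folds.
Two small-sample facts are worth knowing when reading CV numbers at n = 16:
a single null dataset of that size can carry large accidental
x–label correlation, and CV on balanced null data is biased somewhat below
0.5 (training-set majorities anti-correlate with held-out composition). The
test suite therefore checks chance-level behaviour on an ensemble of null
datasets rather than a single draw.

LASSO fitting of the 2-D model uses scikit-learn's coordinate-descent
solver over a log-spaced penalty grid (default 0 plus 25 points in
[1e-6, 1]); the penalty minimising 4-fold cross-validated MSE is selected
and the model refit on all data (a training-MSE criterion is available
behind a flag, and λ = 0 falls back to OLS). Note that the CV-minimising
penalty shrinks truly-null coefficients strongly but rarely sets them
*exactly* to zero — exact support recovery requires a larger, fixed penalty,
and the tests distinguish these two regimes explicitly.

Pearson correlation (between min wt.% and descriptors) is the standard
product-moment coefficient via scipy; constant inputs are rejected.

## Synthetic data: what it emulates and what it does not

The generator replaces the MD engine, on the grounds that every analysis in
this package consumes contact geometry and surface composition only:

* `build_crystal_cluster` — nx·ny·nz copies of a unit molecule on a
  rectangular lattice (default 3×3×3, 6 Å spacing), all drug-role,
  clash-checked, deterministic.
* `simulate_adsorption` — each excipient follows an independent two-state
  Markov chain (per-frame bind probability `p_on`, unbind `p_off`), started
  from its stationary distribution so the bound fraction is
  p_on/(p_on+p_off) from frame 0. While bound, the excipient occupies a
  pre-computed surface site in contact with exactly k crystal molecules,
  with k redrawn from `k_dist` every bound frame (a surface-diffusion
  analogue; this per-frame redraw is what makes the pooled frame-level
  coordination distribution converge to `k_dist`). Sites are validated with
  the *same* contact function the analysis uses — one source of truth for
  the cutoff. Unbound excipients sit at least twice the cutoff from every
  crystal atom. Defaults (14 excipients, p_on 0.2, p_off 0.05, 2000 frames
  at 100 ps) describe a mostly-adsorbed population over a 200 ns-equivalent
  record. Optional far/near water decoys exercise the water-exclusion
  filters.
* `generate_logistic_dataset` / `generate_lasso_dataset` — labelled data
  from known logistic coefficients (x uniform on [0.05, 0.45], the FASA_p
  span of real complexes) and descriptor-ratio regression data (ratios
  uniform on [0, 0.3]) with Gaussian noise.

What passing these recovery tests shows: the analysis machinery is unbiased
and self-consistent at realistic problem sizes. What it does not show: that
a force field, water model or sampling protocol is adequate — there is no
energetics, no kinetics beyond the two-state chain, no crystal deformation,
no competitive adsorption, and excipients are rigid. Conclusions about real
systems inherit the assumptions of whatever trajectory is fed in.

All randomness flows from a single integer seed per run; generators record
seed and parameters in their ground-truth output, and every pipeline
artifact carries a provenance header (package version, seed, config hash).

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on synthetic inputs sized
for a desk machine: 27-molecule crystals with 10–20 excipients over ≤2000
frames, 200 random systems (≤60 molecules / ≤500 atoms) for the contact
oracle equivalence, SASA convergence at 960 vs 3840 points on a ~90-atom
complex, and regression recovery at n = 200–2000. The closed-form 2-D
predictions are exact evaluations and independent of problem size.

## Known limitations

* The element-based polarity rule is a proxy; FASA_p values are internally
  consistent but not numerically interchangeable with those of commercial
  surface calculators.
* Dipole depends on the charge source (partial vs formal) and, for charged
  complexes, on the origin convention.
* The reference logistic/LASSO coefficients are shipped as constants; the
  16-pair experimental training table and the 32 simulated complexes behind
  them are not redistributable, so refits of those exact numbers are out of
  scope (the machinery to refit on new data is fully tested).
* PDB round trips quantise coordinates to 1e-3 Å and drop bond topology;
  polarity for PDB-read structures relies on the geometric
  hydrogen-attachment fallback.
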
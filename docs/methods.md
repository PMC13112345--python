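# Methods

## The surrogate model

The system is a single titratable site whose only conformational degree
of freedom is its position `z` (nm) along the membrane normal, water
side positive.  Each protonation state `s ∈ {prot, deprot}` has an
analytic potential `U_s(z)` built from two term families:

- `gaussian(A, c, w)` = `A exp(−(z−c)²/2w²)` — interface wells and
  localized barriers;
- `sigmoid-step(A, c, w)` = `A / (1 + exp((z−c)/w))` — a smooth step
  with plateau `A` on the membrane-interior (low-z) side.

Both potentials are anchored to zero at a water reference position
(`z_water_ref`, default 2.0 nm ≙ +20 Å, the outermost umbrella of the
standard window ladders), so the aqueous pKa equals the configured
reference `pKa_w`.  Because energies are defined up to that reference,
a *negative*-amplitude step doubles as a confining wall on the water
side; this keeps the term family minimal.  The family is an extension
point: any term with `energy`/`gradient` methods can be added.

Position-dependent titration follows from the semi-grand-canonical
weights `w_prot ∝ e^{−βU_prot}`, `w_deprot ∝ e^{−βU_deprot}
10^{pH−pKa_w}`:

    pKa(z) = pKa_w + β [U_deprot(z) − U_prot(z)] / ln 10
    P(deprot | z, pH) = 1 / (1 + 10^{pKa(z) − pH})

The deprotonated/protonated weight ratio is class-independent; the
residue class only decides which state is the *ionized* one
(deprotonated for acids, protonated for bases).  All closed forms —
pKa(z), titration curves, state-marginalized densities, biased
densities, and the pH-dependent free-energy landscape
`−kT ln Σ_s w_s(z)` — are exposed as oracles for the estimators.

Shipped examples: an asp-like acid (pKa_w 3.94) whose ionized state
pays a 20 kJ/mol sigmoid penalty inside the membrane (pKa rises from
3.94 to ≈7.4 at deep insertion, a slope of ≈0.35 pKa/Å across the
interface), and a his-like base (pKa_w 6.54) with the mirrored
assignment (pKa falls on insertion).  Shared confining walls at
−12/+23 Å cancel exactly in pKa(z).

## Dynamics and titration

Conformational sampling is overdamped Brownian (Euler–Maruyama):

    z' = z − βD ∂_z[U_s(z) + V_bias(z)] dt + √(2D dt) η

with defaults `D = 0.05 nm²/step-unit`, `dt = 0.01`.  Inertia,
thermostats and constraints of the all-atom method are irrelevant to
the sampling schemes under test; only the stationary distribution
matters.  The Euler discretization inflates the variance of a harmonic
degree of freedom by `1/(1 − θ/2)` with `θ = βDk dt`; tests that compare
against equilibrium moments account for this, and scheme-comparison
tests compare engine output against engine output so the discretization
cancels.

Titration is an exact heat-bath resample of `s` from
`P(deprot | z, pH)` at fixed `z` — the surrogate of a converged
Poisson–Boltzmann/Monte-Carlo protonation step.  Heat-bath sampling
makes detailed balance of the titration kernel provable rather than
approximate.  The cadence mirrors the reference protocol cycle in toy time
units: titration every 20, exchange attempts every 20 starting at 10
(misaligned from titration, which starts at 0), and the first 25 units
flagged — not deleted — as equilibration; the analysis layer owns the
discard rule.

## Replica exchange

REUS swaps between adjacent umbrella windows use
`Δ = β[V_m(ξ_j) − V_m(ξ_i) − V_n(ξ_j) + V_n(ξ_i)]` with
`V_m(ξ) = k_m/2 (ξ − ξ_m)²`, accepted with `min(1, e^{−Δ})`.

The pHRE criterion for discrete protonation is derived from the
semi-grand weights: swapping the pH labels of replicas with proton
counts `N_i`, `N_j` changes the log stationary weight by
`ln10 (pH_i − pH_j)(N_i − N_j)`, giving

    Δ = ln10 (pH_i − pH_j)(N_j − N_i),

so that carrying the protonated configuration to the lower-pH rung is
always accepted.  An enumeration test verifies
`π(x) w(x→y) = π(y) w(y→x)` exactly on a discrete state space.

Sweeps attempt disjoint adjacent pairs with deterministically
alternating parity (even, odd, even, …) for reproducibility; exchanges
swap ladder labels (pH values or window references) rather than
coordinates, which is equivalent and keeps replica bookkeeping simple.
A single-rung ladder disables exchange with a warning.  Window ladders
are built inclusively (+20 → −12 Å at 2 Å spacing gives 17 windows;
+12 → −10 Å at 1 Å gives 23) with a per-window force-constant rule;
the dual-force REUS rule assigns 500 kJ mol⁻¹ nm⁻² to the water region
(+20…+8 Å) and 1000 from +6 Å inward.  The US-ext pH extension appends
two values continuing the (uniform) ladder spacing on the ionized side
— high pH for acids, low for bases.

## Membrane geometry

Insertion of the titratable site is `z_site − ⟨z_phosphate⟩` over the
phosphate-group atoms of the *closest leaflet* within a 6 Å radius of
the site, signed water-positive; if fewer than 5 atoms lie inside the
radius the whole closest leaflet is the reference and the result is
flagged.  The 6 Å neighborhood for insertion is a 3-D Euclidean ball
(configurable to lateral-only).  Local deformation is
`⟨z⟩_{≤6 Å} − ⟨z⟩_{>15 Å}` on the closest leaflet; its neighborhood is
*lateral* (xy, minimum-image) by default, because the quantity compares
surface heights and a 3-D ball around a site hovering above the
surface would exclude exactly the depressed atoms it measures.  Frames
with an empty local or bulk set yield missing values, which are
counted, never fabricated.  xy distances use the minimum-image
convention; z (the membrane normal) is non-periodic.  Orientation
(water-positive sign) follows the closest leaflet and can be pinned
per trajectory.

The GRO reader implements the fixed-column dialect (nm units,
optional velocity columns, multi-frame series) and reports malformed
lines with their line numbers; leaflets are assigned per frame by z
relative to the phosphate median.  Multi-atom site selections (e.g.
the two imidazole nitrogens) use their per-frame center of geometry.

The synthetic surface generator places phosphate pseudo-atoms on an
xy-jittered lattice, with the upper leaflet depressed by a Gaussian
dimple of amplitude `A` and width `σ` under the site plus optional
Gaussian roughness.  Ground truth for each frame (insertion and
deformation computed from the noiseless height field over the actual
atom positions, with the same radii the estimators use) is recorded in
the snapshot metadata, so at zero roughness the estimators must agree
to machine precision, and under noise the estimate is unbiased around
the recorded truth.

## WHAM, jackknife, reweighting

WHAM iterates the standard self-consistent equations in log space
(`logsumexp` throughout) until the per-window free energies change by
less than 1e−7 kT (max 10⁵ iterations), then reports
`PMF = −kT ln P(ξ)` anchored to zero at its minimum over occupied
bins, in kcal/mol on an Å grid.  Two numerical choices matter:

- **Bin-averaged bias.**  The per-(window, bin) bias energy enters as
  `−ln ⟨e^{−βV}⟩_bin` (5-point Gauss–Legendre), not as the bin-center
  value.  With stiff umbrellas (k = 1000 kJ mol⁻¹ nm⁻²) the bias varies
  by order-kT within a bin and the bin-center approximation accumulates
  a systematic offset across the ladder (≈0.15 kT over 17 windows at a
  0.2 Å bin width).
- **Histogram resolution.**  The default ξ bin width is 0.05 Å.  The
  residual histogram-WHAM bias (within-bin covariance of density and
  bias) scales as the bin width squared: measured on the double-well
  oracle with exact expected counts it is 0.14 kT at 0.2 Å, 0.035 kT at
  0.1 Å and 0.009 kT at 0.05 Å.  The coarser 0.2 Å grid is reserved
  for the ionized-population profile, where it matches the field-standard
  binning and no free-energy bridging is involved.

Adjacent windows (sorted by ξ_ref) must share at least one occupied
bin; a gap raises an error naming the window pair.  PMF errors use the
leave-one-out jackknife over replicates: each leave-one-out PMF is a
full WHAM solution of the pooled histograms of the remaining
replicates, anchored min-0, and
`err(ξ) = √((n−1)/n Σ_i (PMF_i − mean)²)` — invariant to the global
anchoring constant.  Frame weights for population reweighting follow
the WHAM-consistent (MBAR-form) estimator
`w(ξ) ∝ 1/Σ_j N_j e^{f_j − βV_j(ξ)}`, normalized to mean 1; frames
outside the histogram support get extrapolated weights plus a warning.
Profile alignment (e.g. matching a 1 Å-ladder PMF to a 2 Å-ladder PMF
in the water region) adds the constant minimizing the mean squared
difference over the stated interval.

## pKa profiles

The ionized-population profile counts ionized configurations in 0.2 Å
bins from −15 to 25 Å (half-open `[lo, hi)` everywhere; bin edges are
constructed as width × integer so round values land exactly on
boundaries).  Both the per-bin ionized *fraction* and the normalized
ionized *density* are emitted, since "probability of the ionized
species" admits either reading.

The pKa profile scans −12…22 Å with 1 Å bins advanced by 0.25 Å
(left edges −12.00, −11.75, …, 21.00; 133 bins).  Per bin, frames are
pooled over replicates and pH values and the per-pH mean protonations
are fitted to `⟨prot⟩(pH) = 1/(1 + 10^{pH − pKa})` — Hill slope fixed
at 1, per-pH frame counts as least-squares weights, fitted by bounded
scalar minimization (tolerance 1e−9).  Gates, applied in order:

1. ≥50 frames in *each* protonation state (pooled over pH/replicates);
2. each state observed at ≥2 pH values;
3. each state observed at ≥2 replicates;
4. per-pH mean protonation non-increasing with pH, with an absolute
   slack of 0.02 (configurable) for sampling noise.

Gate failures produce statuses, never exceptions, and all reductions
are permutation-invariant in the record rows.  Equilibration-flagged
frames are excluded from every profile reduction.

Errors are Bayesian bootstrap: 1000 flat-Dirichlet reweightings of the
frames within each pH group, each refitted (vectorized grid scan ±4
around the point estimate at 0.01 resolution with parabolic
refinement); the error is the standard deviation of the bootstrap pKa
distribution, with boundary hits and flat resamples counted as failed
refits.  Frame-level resampling within pH groups is the default;
replicate-level resampling is available through the same interface by
passing per-replicate aggregates.

## Study conditions for the oracle checks

The verification suite fixes its problem sizes as follows: aqueous
pKa recoveries use the standard four-point pH ladders, closed-form
titration means (deterministic) or 10⁵ heat-bath resamples per pH
(stochastic); the WHAM oracle uses the 17-window 2 Å ladder on the
double-well model with exact expected counts equivalent to 3 replicates
of 50 000 frames per window; exchange-kernel checks run one REUS
replicate of 400 000 steps against an independent umbrella campaign of
the same length; pKa-profile recovery uses 3 replicates × 4 pH ×
20 000 frames drawn uniformly in position from the exact protonation
conditional with the full 1000-bootstrap error; geometry oracles use
zero-roughness synthetic surfaces.

## What the generator does and does not emulate

Synthetic records drawn from the exact conditional emulate perfectly
converged protonation sampling at iid positions; they probe estimator
correctness, gate logic and error calibration, not the kinetic
trapping, slow lipid relaxation or conformational heterogeneity of
real membrane CpHMD.  Likewise the Brownian engine reproduces the
*stationary* statistics the schemes are designed to sample, but its
relaxation times are not calibrated to any physical system.  Passing
tests therefore demonstrate that the schemes and estimators are
implemented correctly, not that any particular lipid/peptide system is
described quantitatively.

## Known limitations

- Single titratable site; no multi-site coupling or tautomers.
- One reaction coordinate; no pH × window two-dimensional exchange.
- The histogram-WHAM estimator retains an O(w²) discretization bias;
  at the 0.05 Å default this is ≈0.01 kT, visible only against exact
  oracles.
- The maximum-deviation statistic of a sampled PMF against the analytic
  one is dominated by the lowest-count bins included; quantitative
  oracle comparisons therefore use exact expected counts, while sampled
  runs are checked at coarser tolerances.
- GRO is the only coordinate format; compressed trajectories are out
  of scope.
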
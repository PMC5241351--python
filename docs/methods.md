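# Methods

This note records the models implemented in `mesomix`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
generators do and do not emulate.

## Hydrogen-bond criterion

A bond is registered between a donor O–H and an acceptor oxygen when

* the H···O(acceptor) separation is **< 2.5 Å** (minimum image), and
* the O–H···O angle at the hydrogen is within **30° of linear**.

The angular band is specified as 150–210°; since a geometric angle lies in
[0°, 180°], the band is folded symmetrically about 180°, i.e. θ ≥ 150° with
the default settings. Donors are the two water hydrogens and the alcohol
hydroxyl hydrogen; acceptors are all oxygens; intramolecular pairs are
excluded. The covalent O–H assignment comes from molecule topology
(template order, or a one-time 1.2 Å proximity flag when reading foreign
files), never from per-frame distance inference, so close contacts cannot
reassign donors. Each directed donor-H → acceptor-O pair is reported once;
one hydrogen may bond several acceptors (the `trifurcated` toy case pins
this behaviour down).

Detection uses a periodic k-d tree over acceptor oxygens with exact
minimum-image re-checks; an O(n²) enumeration in the test suite confirms
exact agreement on random configurations.

### Alcohol classification

Classes are **exclusive and exhaustive** with precedence P–P > P–W: an
alcohol with any bond to another alcohol is P–P, otherwise any bond to water
makes it P–W, otherwise it is unbonded. Percentages therefore sum to exactly
100 per frame. (Published tables of this quantity sometimes sum to slightly
less than 100; with exclusive classes that residual cannot be reproduced,
and comparisons should use tolerances.) Trajectory summaries average the
per-frame percentages over a trailing window, by default the final 1 ns.

## Segregation (non-ideality) statistic

Each configuration's orthorhombic box is divided into a grid of equal
sub-boxes — by default **10 × 10 × 10 = 1000 cells**, which at the reference
scale of 3000 molecules gives a mean occupancy of 3 molecules per cell.
Presence rules:

* a **water** is counted in the single cell containing its oxygen;
* an **alcohol** is counted once in *each distinct* cell containing at least
  one of its three carbons (1–3 cells), making the count sensitive to
  molecular orientation and size;
* in point (united-atom) mode the per-molecule reference point stands in
  for both rules.

Cells are half-open intervals [0, L/n) after coordinate wrapping, so every
atom maps to exactly one cell with no boundary double-counting.

Occupancy histograms are normalized over all (cell, configuration) pairs to
give N(x), the fraction of cells with exactly x alcohols. The statistic is
the Euclidean distance between the simulated and null alcohol distributions
over the union of their supports (missing entries zero-filled). It is
computed on the **alcohol** distribution; water distributions are available
but excluded from the statistic.

**The null** is an ensemble of independent configurations with molecule
positions uniform in a box of matched volume and composition, orientations
uniform on SO(3) (quaternion sampling), matched in size to the simulated
ensemble (2500 configurations at reference scale). Steric overlap is not
enforced: the statistic only asks which cell each molecule occupies, so
packing effects on that scale are negligible for the null's purpose. When
the simulated side is atomistic the null is generated atomistically too, so
the carbon-presence rule acts on both sides.

**Sampling noise floor.** Two independent 2500-configuration nulls at 1 mol%
/ 3000 molecules / 1000 cells differ by < 10⁻⁴ in the statistic (2.5 × 10⁶
cell observations per side); the acceptance suite asserts < 0.01. Reported
values an order of magnitude above that floor are signal.

**Scaled-down systems.** The statistic depends on (n_molecules, n_boxes);
results are only comparable at matched mean occupancy. `PartitionSpec.auto`
chooses a cubic grid with m = round((n/3)^{1/3}) cells per axis, preserving
the reference 3-per-cell occupancy. An exact cube is used instead of the
literal "round(n/3) cells" because that count is often prime and would force
a degenerate (n × 1 × 1) grid.

## Synthetic mixtures

`gen_random_mixture` draws reference points uniformly and builds rigid
ideal-geometry molecules: water O–H 0.96 Å at 104.5°; 2-propanol as three
carbons (tetrahedral, C–C 1.53 Å), hydroxyl oxygen (C–O 1.43 Å) and hydroxyl
hydrogen (O–H 0.96 Å, C–O–H 108.5°) — the minimal atom set the analyses
need (methyl hydrogens carry no donor or presence role and are omitted).
Box volumes default to ideal-mixing liquid volumes (30.0 Å³ per water,
127.7 Å³ per 2-propanol, from the 25 °C molar volumes).

`gen_clustered_mixture` plants ground-truth segregation: a chosen fraction
of the alcohols is re-placed as wrapped Gaussian displacements (sd
`cluster_sigma`, default 3 Å) around uniform cluster centers, assigned
round-robin. Cluster draws come from a separate deterministic stream, so
`clustered_fraction=0` reproduces the random mixture bit-exactly and the
planted-fraction series is a controlled monotonicity probe: the statistic
must increase strictly along 0 → 0.25 → 0.5 → 0.75 → 1, exceeding 0.4 at
full single-cluster segregation.

All generators are pure functions of (spec, seed); per-frame and
per-configuration sub-seeds are spawned from the spec seed.

What the generators do **not** emulate: liquid structure (radial
distributions, realistic H-bond populations), excluded volume, dynamics and
frame-to-frame correlation. Passing tests demonstrate the *estimators* are
correct on known ground truth, not that any particular force field
reproduces experimental mixing behaviour — reproducing the published
per-composition bonding percentages would require actual MD trajectories,
which are deliberately outside this package's scope.

## Thermogram synthesis and reduction

The generator follows the measurement schedule it emulates: a
0.1 °C·min⁻¹ ramp with alternating ±4 bar pulses (starting with
pressurization) every 10 min, i.e. every 1 °C, with a 300 s lead-in; 1 Hz
sampling. Each pulse carries a spike of *planted* integrated area ΔQ(T)
(up-pulses carry the sign of ΔQ, down-pulses mirror it), on a linear
baseline (offset + drift per °C) with optional Gaussian noise. Spike shapes:
`rect` (fixed height; a fractional trailing sample makes the sampled
trapezoid exact for any duration), `gauss` (sd 15 s, centred 4σ after the
event), `expdecay` (τ = 20 s).

`integrate_pulse` fits a local linear baseline between the medians of a
60 s pre-event window and a 60 s window ending at the next event, then
integrates the residual by the trapezoid rule from the event start to
return-to-baseline: the first sample after the spike *peak* whose residual
stays within max(2 × pre-window noise sd, an absolute floor of 10⁻³ μW) for
10 s. Anchoring at the peak prevents pre-spike noise from truncating the
integral. Spikes still off-baseline at the next event are integrated to the
cap and flagged unreliable. Closure: planted areas are recovered to ≲0.01%
noise-free and within 2% at 0.5 μW noise for μJ-scale (≥~10³ μJ) areas.

`reduce_thermogram` assigns each pulse the sample temperature at the event
start and by default trims to the **9–61 °C usable range** (the first and
last pulses of a 7–62 °C schedule sit on unsettled baseline).

### Gradients and ΔΔQ

[δC̄p/δp]_T is estimated as the ordinary-least-squares slope of ΔQ/Δp
versus T inside a window (defaults 9–35 °C and 35–61 °C), reported in
μJ·bar⁻¹·K⁻¹ with R² and an R² < 0.8 low-confidence flag. A
single-predictor partial-least-squares fit with one component is equivalent
to OLS, so no separate PLS machinery is used. Published tables print this
gradient with an mJ·bar⁻¹·K⁻¹ label that is dimensionally inconsistent with
μJ-scale heats over ~26 K windows; no hidden ×1000 rescaling is applied —
the packaged gradient values are fixtures for I/O and comparison, not
regression targets. Up- and down-pulses are reduced separately; reports
default to up-pulses (pressurization).

ΔΔQ interpolates linearly between the 0 and 100 mol% endpoints and is
identically zero for any affine-in-composition series; from the packaged
reference table at 25.5 °C, ΔΔQ(20 mol%) = −15 924.4 μJ by direct
arithmetic.

### Expansivity equations

All thermodynamic evaluation is SI internally (K, Pa, m³, J) with heats
exposed in μJ; temperatures convert °C → K and pressures bar → Pa only
inside these functions.

* Single-population: ΔQ = T·Δp·(α0 − ᾱ)·V_part·g_s, invertible for ᾱ.
  Valid only where the solute's apparent volume approximates its
  infinite-dilution partial volume (dilute regime).
* Hydration-layer: ΔQ = T·Δp·x_s·[(n+1)·V_b·α_b − n·V̄_h·ᾱ_h − V_s·α_s] + A′,
  linear in each of α_h, n and A′ and inverted accordingly (with explicit
  errors when the relevant coefficient vanishes). A′ is treated purely as a
  free offset. The bookkeeping mole fractions x_b and x_h are carried on the
  parameter set but do not enter the printed formula. The model presumes
  isolated solutes with discrete hydration layers and is not fitted to
  mixtures where extended networks form.
* Volume-curvature: [δC̄p/δp]_T = −T·∂²V/∂T², evaluated analytically from
  polynomial coefficients, plus the first-derivative form −T·d(V_part·ᾱ)/dT
  from tabulated products via central finite differences (≥3 points).
  The sign convention is asserted structurally: the gradient is negative
  wherever V(T) is strictly convex.

## Problem sizes and determinism

Default test and acceptance runs use: full-scale nulls (2500 configurations
× 3000 molecules × 1000 cells) in point mode, where the statistic is
position-only; 200-frame planted-clustering trajectories; 100 random ≤60
molecule configurations for the exact detector/brute-force comparison; and
the full 56-pulse thermogram schedule. Atomistic generation is exercised at
smaller molecule counts where the carbon rule and H-bond geometry matter.
Every stochastic path takes an explicit integer seed (NumPy `SeedSequence`
spawning); identical inputs give bit-identical outputs, and pipeline runs
record version, config hash and seeds in `manifest.json`.

## Known limitations

* Orthorhombic boxes only; triclinic cells are rejected, not converted.
* The DL_POLY reader handles the formatted (text) HISTORY layout only,
  coordinates only.
* Molecule grouping in XYZ/HISTORY relies on contiguous template blocks
  (water, minimal alcohol, fully protonated alcohol); arbitrary topologies
  need an explicit species rule.
* The hydration-layer model and the single-population relation are provided
  as calculations, not fitted to the packaged experimental table — the
  mixtures of interest form networks where their assumptions break down.
* PDB round-trips are exact only to the format's 3-decimal coordinate
  precision.
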
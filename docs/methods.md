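# Methods

This note records the models, estimators, parameter choices and known
limitations behind permlab, in the order the pipeline applies them.

## Pore geometry

Each monomer's conducting pore is modelled as a cylinder of radius 6 Å
spanning a 30 Å z-section.  The lateral centre is the time-averaged
position of the anchor-arginine residue projected on the membrane
plane; the axial placement is centred on the membrane midplane,
estimated from the time-averaged z of lipid phosphorus atoms when
lipids are present and of all protein atoms otherwise.  The membrane
normal is fixed to the box z axis, the convention of the standard
bilayer builders.  The 6 Å radius is a deliberate compromise: wide
enough to enclose a single-file aquaporin lumen and its fluctuations,
narrow enough to exclude inter-monomer and lipid-facing waters.  All of
these are configurable; none is sharply determined by the physics, and
results should be checked for insensitivity to the radius in the
4–8 Å range.

Waters are wrapped into the primary box before membership tests; the
radial test uses minimum-image lateral distances.  Axial displacement
series are minimum-image unwrapped per molecule so that periodic
wrapping never masquerades as permeation.

## Crossing events

A crossing is a maximal run of frames inside one monomer's cylinder
whose flanking side labels (below/above the section) are opposite.
Runs that re-exit through the entry face, runs truncated by either
trajectory end, and runs entered through the cylinder wall are not
events.  This is stricter than counting waters that merely visit both
faces: it excludes vestibule-skirting waters, at the cost of
undercounting when the frame spacing is comparable to the boundary
recrossing time.  Frame spacings ≤ 0.05 ns keep that truncation bias
in the few-percent range for diffusivities typical of channel water.

## Osmotic permeability

The collective coordinate increments by `Σ Δz_i / L` over waters inside
the region at both endpoints of each frame step (boundary-straddling
waters are simply dropped from that step, which biases `D_n` low by
roughly twice the per-step turnover fraction — a few percent at the
recommended frame spacing).  `D_n` is half the slope of the MSD of
`n(t)` over lag times 0.1–1.0 ns with all overlapping origins; the
uncertainty is the standard error over 10 trajectory blocks, which
unlike the naive fit error survives the strong correlation between
overlapping origins.  A quadratic term is also fitted and reported as a
nonlinearity ratio; values above ~0.3 indicate drift or non-diffusive
behaviour and make the fit untrustworthy.  Finally
`pf = v_w · D_n` with `v_w = V_m/N_A`, `V_m = 18.02 cm³/mol`,
`N_A = 6.02214 × 10²³ /mol`.

Counts are treated as the primary permeability statistic and `pf` as
the secondary one, because the collective-coordinate estimate is
sensitive to thermal agitation of waters near the pore mouths.

## Free-energy profiles

`G(z) = −kT ln(ρ(z)/ρ_bulk)` on 0.5 Å slices, with `kT` evaluated at
the simulation temperature (default 310.15 K) using
R = 1.98588 × 10⁻³ kcal mol⁻¹ K⁻¹.  The bulk density is estimated in a
user-chosen solvent slab (the pipeline defaults to 2–12 Å above the
section); a warning fires if the slab overlaps the declared membrane
span.  Slices with zero sampled density are capped at 6 kcal/mol and
flagged rather than propagating infinities; the cap only matters for
profiles that genuinely dewet.

## Hydrogen bonds, bound states and affinity

Hydrogen bonds use the geometric criterion donor–acceptor ≤ 3.5 Å and
hydrogen–donor–acceptor angle ≤ 30°, the defaults of the common MD
analysis tools; donors are inferred as N/O atoms with a hydrogen within
1.25 Å in the same residue on the reference frame.  The ACBS-bound
state is "any H-bond with the anchor arginine" (residue number from
configuration, 187 for AQP2), and the bound-state window is the 50 ns
sliding window (1 ns stride, ties to the earliest) maximising the
bound-frame fraction.

Binding affinity is a linear model in heavy-atom ligand–protein contact
counts within 10.5 Å, classified by unordered element pair with
elements collapsed to {C, N, O, X}.  The engine assumes nothing beyond
linearity; the coefficients ship as configuration
(`data/contact_score_synthetic_defaults.yaml`).  **The shipped
coefficients are synthetic defaults**, chosen so that steroid-sized
vestibule poses score in the −8 to −10 kcal/mol range experimentally
typical of moderate-affinity steroid sites; substitute a published
parameter set for production scoring.  `K_D = exp(ΔG_S/RT)` at the 1 M
standard state, reported in nM: a printed convention with a negative
exponent and positive binding energies is dimensionally equivalent, but
only ΔG_S < 0 with this sign convention maps favourable binding to
sub-molar K_D.  The trajectory summary is the median (and mean) K_D
over frames sampled every 1 ns across the whole trajectory, bound or
not.

## WIP

`WIP = Δcounts · v_w / K_D,median` where `Δcounts` is the mean crossing
count of the control minus that of the steroid condition, converted to
a per-tetramer rate in s⁻¹ (mean per window-monomer replicate × 4
monomers / window length).  The constant placement is fixed by
dimensional analysis against the unit cm³ s⁻¹ nM⁻¹: multiplying WIP by
a concentration in nM yields a flux reduction in cm³ s⁻¹ (reported at
100 nM by default).  A negative Δcounts (flux enhancement) is preserved
with its sign and flagged.

## Statistics

Conditions are compared with the unpaired two-sided Wilcoxon rank-sum
(Mann–Whitney) test on the replicate count tables — 10 ns windows per
monomer, 80 replicates for a 200 ns tetramer run.  Pairing is
undefined across independently simulated systems, hence the unpaired
flavour.  The exact null distribution is used when both samples have
≤ 12 observations and no ties; otherwise the tie-corrected normal
approximation.  Bonferroni correction multiplies by the number of pairs
actually tested.  Replicates from adjacent windows of one trajectory
are weakly correlated (waters mid-pore at a window boundary), which
leaves the empirical type-I rate near 0.055 in the null calibration —
close to, but not exactly, nominal.

## Synthetic ground truth

The generator builds a labelled toy system: four rigid rings of
pore-lining pseudo-atoms (elements C/N/O/S to exercise every contact
class), one anchor "arginine" (N–H donor, carbonyl acceptor) per
monomer, lipid-phosphate markers pinning the midplane, pore waters,
ideal bulk waters at 0.0334 Å⁻³, and optionally a rigid steroid-like
ligand.  Defaults are the study conditions: 4 monomers, 30 Å section,
~7 pore waters per monomer, default diffusivity chosen so the imposed
permeability is 2 × 10⁻¹⁴ cm³/s (the magnitude measured for AQP2),
200 ns at 310.15 K.  Everything is reproducible bit-for-bit from one
seed.

Two water-dynamics modes:

* **Single-file (flat potential).**  The water file moves collectively:
  the file coordinate is Brownian with diffusion `D/N`, slots spaced
  `L/N`, exchange with vestibule reservoir waters at the faces.  This
  makes two closed forms exact — `D_n = N·D/L²` (hence the imposed
  `pf`) and a one-way tagged-traversal rate of `D/L²` per monomer —
  and every admission/release is logged, so the manifest carries the
  exact crossing-event ledger the detector must reproduce.  Reservoir
  waters are ideal (positions redrawn per frame): the reservoir is a
  bath, not a dynamical phase.
* **Independent (with potential).**  Non-interacting waters follow
  overdamped Euler–Maruyama dynamics on the periodic box with a
  piecewise-linear axial potential; the stationary density is exactly
  Boltzmann.  The Euler step is chosen adaptively so the drift per
  substep stays below 0.1 Å, which keeps the residual density bias
  below the sampling noise of the validation runs.  A direct rejection
  sampler (`sample_equilibrium_frames`) provides i.i.d. Boltzmann
  configurations when dynamical correlations are unwanted.

The ligand is a rigid 17-atom template.  Bound frames place its
hydroxyl oxygen 2.9 Å from the anchor nitrogen, collinear with the
anchor N–H (a textbook hydrogen bond); unbound frames park it in bulk,
beyond the contact cutoff plus 5 Å from every protein atom, so unbound
contacts are exactly zero.  State switching is a two-state
continuous-time Markov chain; the manifest records the interval list,
the per-state contact counts from an independent plain-loop counter,
and the per-state ΔG_S/K_D under the configured coefficients (−9.26
kcal/mol ≈ 296 nM for the default bound pose, inside the 10²–10³ nM
range expected for steroid–channel surface sites).

What the synthetics do **not** emulate: water–water sterics and
hydrogen bonding, electrostatics, lipid and protein dynamics, ligand
flexibility, and any coupling between ligand binding and water
transport (the "inhibited" preset imposes inhibition by reducing the
pore diffusivity to one quarter).  Passing the validation suite
therefore certifies the estimators — geometry, bookkeeping, statistics
and unit handling — not the realism of any force field.

## Validation problem sizes

Chosen to hold estimator noise well inside the stated tolerances:
pf recovery uses single-pore runs of 400 ns at 0.01 ns frames (relative
error budget ≈ 5% turnover bias + ≈ 8% MSD noise, against a 20%
tolerance); free-energy recovery uses 10⁵ i.i.d. samples for the
2 ± 0.1 kcal/mol step and 2 × 10⁵ for the ±0.05 kcal/mol flat-profile
noise floor; the rank-sum calibration uses 200 null pairs of 20
replicates.  The null-vs-inhibited comparison tests at the standard
80-replicate design, while the WIP point estimate averages the count
difference over five independent simulation pairs: single-file
traversal counts are bursty (completions cluster on large excursions
of the file coordinate), so a single 200 ns pair carries ~20% relative
noise on Δcounts, and the five-pair mean brings the total error
comfortably inside the 25% recovery tolerance.

## Known limitations

* The crossing definition requires continuous cylinder residence;
  waters that exit radially mid-pore and re-enter are not credited.
* `D_n` inherits a small negative bias from both-endpoint membership;
  use finer frame spacing if per-cent accuracy on `pf` matters.
* The trajectory-file round trip is limited by XTC precision (0.001 nm,
  i.e. 0.01 Å), not by the internal representation.
* Only orthorhombic boxes are supported.
* The contact-score coefficients shipped are placeholders calibrated on
  the synthetic template, not a fitted empirical model.
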
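# Methods

## The kinetic model

Pulsed-laser excitation of a flavin–tryptophan (F–W) dyad creates a
triplet state that is quenched bimolecularly, producing pairs of F and W
monoradicals. Both radical kinds disappear by second-order
cross-termination, so each concentration follows

    R(t) = R0 / (1 + kt·R0·t),

the closed form of dR/dt = −kt·R². Nuclear spin polarization is tracked in
two pools — P_R in the surviving radicals and P in diamagnetic products:

    dP_R/dt = −kt·P_R·R − kt·β·R² − P_R/T1
    dP/dt   = +kt·P_R·R + kt·β·R²

Here T1 is the nuclear *paramagnetic* relaxation time (the nucleus sits
next to an unpaired electron, so T1 is microseconds, not seconds), and
β = γ·P_G/R0 is the polarization created per F-pair (random re-encounter)
recombination, tied to the geminate polarization P_G by the ratio γ (3 for
an ideal triplet precursor; the default 2.8 accounts for incomplete
reversibility of the photoreaction). The observable is the product
polarization scaled by a detector factor, evaluated at the center of the
detection RF pulse (delay + duration/2); no convolution over the pulse
window is attempted.

Everything observable depends only on the products `kt_R0 = kt·R0` and
`γ·P_G`; the model is therefore parameterized by (kt_R0, T1, P_G, γ,
scale), with absolute R0 accepted only for concentration simulations.

Initial conditions are not unique in the literature convention; the
package default is the spin-sorting pair P(0) = +P_G (geminate products
present at flash end) and P_R(0) = −P_G (anti-phase polarization carried
by escaped radicals). Both are overridable in `integrate_polarization`.

Two limits anchor the implementation and the tests. The F-pair term
appears with opposite signs in the two equations, so d(P + P_R)/dt =
−P_R/T1: without relaxation the total is conserved, every escaped spin
eventually returns, and the net product polarization relaxes to
P(0) + P_R(0) — zero for the default conditions (the classic cancellation
of CIDNP in fully reversible cyclic reactions; analytically
P(t) = (P_G + γ·P_G·ln u)/u with u = 1 + kt_R0·t). In the opposite limit
T1 → 0 the radical-borne anti-polarization dies immediately and
P(∞) = (1 + γ)·P_G. Relaxation is thus what rescues net polarization, and
the asymptotic P decreases monotonically in T1 between these two limits.
The transient maximum of the observed kinetics inside the 0–100 µs window
follows from the same competition.

### Numerical evaluation

`integrate_polarization` uses LSODA with rtol 1e-8 / atol 1e-12 defaults
(both exposed). The fitter evaluates the model through an exponential
integrator (`_fastmodel`): on each step of a geometric time grid the
recombination rate kt_R0·r(t) is frozen at the step midpoint, making the
radical equation linear with constant coefficients and both updates exact
in closed form. The scheme is L-stable (the 1/T1 term never restricts the
step), second order in the logarithmic step, smooth in the parameters,
and agrees with the reference integration to ≲3e-4 relative over the
fitting box at the default 80 points per decade — three orders of
magnitude below the measurement noise it is fitted against, and roughly
three orders of magnitude faster than the adaptive solver.

## Fitting and the recovery protocols

Fits are bounded nonlinear least squares in log10 parameter space with
seeded log-uniform multi-start (8 random starts plus the box center),
tight tolerances, and variable projection: detector scales enter the
model linearly and are profiled out exactly per sharing group. Weights
are uniform unless every trace carries a per-point sigma (then inverse
variance). Default bounds encode physics: T1 ∈ [0.1 µs, 1 ms] (nuclear
paramagnetic relaxation in organic radicals), kt_R0 ∈ [1e3, 1e7] s⁻¹
(diffusion-limited termination at µM–0.1 mM radical concentrations).
Standard errors are asymptotic, from a numeric Jacobian over all free
parameters at the optimum.

A three-delay trace (effective times 2, 5, 102 µs) with three free
parameters is an interpolation problem, and it is not injective: distinct
(kt_R0, T1, scale) triples reproduce the same three points exactly, and
relaxation times beyond the 102 µs window barely imprint on the data at
all (`profile_identifiability` makes this visible as a flat residual
profile). Isolated per-trace fits of such designs are therefore not
meaningfully recoverable at 5% noise, no matter the optimizer. The
recovery protocols in `cidnpkit.protocols` instead mirror the published
global analysis: one termination rate shared by the five NH/NnBu dyads,
tryptophan relaxation times shared within the short-linker (500 µs) and
long-linker (150 µs) groups, per-dyad flavin times, separate traces for
F8′, W2 and W6, and — for the most photostable dyad — the additional
ten-delay series recorded with a 2 µs pulse. The four-proline dyad, whose
rate is four-fold faster and whose relaxation times sit inside the
kinetic window, is fitted on its own. Jointly this pins every parameter;
medians over 200 seeded noise replicates recover all generating values
within the 15% band (50 replicates in the test suite for runtime). The
protocol fits are unweighted, as in the published analysis.

## Sign rules, level anticrossing, and the classifier

The high-field (Δg) regime follows the Kaptein product rule
Γ = sgn(Δg)·sgn(a)·µ·ε — nucleus-specific through sgn(a). In a biradical
at restricted distance, polarization is generated at the level
anticrossing of the singlet with T±, where Γ = sgn(J_ex)·µ·ε — one sign
for *all* nuclei. The anticrossing field is B_LAC = |J_ex|/(g·µ_B), with
J accepted as an energy or a frequency (converted via h); `lac_field` and
`j_from_field` are exact inverses.

`classify_field_regime` quantifies the qualitative banding: "comparable"
means within a factor 3, "much greater" at least a factor 10, and the Δg
pathway switches on where the Zeeman *difference* competes with the
hyperfine mixing, B ≳ a_field/Δg_rel (≈1 T for mT-scale hyperfine fields
and Δg_rel = 1e-3, matching the observed 0.1–1 T null window).

`classify_mechanism` applies the three biradical criteria to a profile
set: (i) one polarization sign for every proton with a significant
mid-field feature, (ii) an interior extremum of |I| in the search window
(default 5–20 mT), (iii) a high-field (≥1 T) response at least 3× weaker
than that extremum. Mixed signs with a sustained high-field response give
the intermolecular Δg call; nucleus-specific signs confined below the
hyperfine scale (default ≤5 mT) give the low-field hyperfine call;
otherwise NONE.

Significance testing is deliberately conservative. The noise floor is
3× the RMS scatter of the 0.1–1 T null window pooled over all protons
(the window is signal-free by construction, so the efficient estimator is
used; a per-proton MAD over its ~7 points fluctuates by tens of percent
and misclassifies at the part-per-thousand level). A feature counts as
real only when its strongest point reaches 1.5× the floor *and* a second
point confirms it; the high-field response is the second-largest
|intensity| above 1 T, so a single noise excursion cannot dominate the
ratio; window extrema are accepted within one grid step of the window
edges (the argmax of a noisy peak jitters by a step) and the peak fields
of different protons must agree within 1.5 grid steps, since the
anticrossing field is a molecular property. With these rules the
classifier labels 6000/6000 synthetic sets correctly at SNR 10 across
three independent seed streams; peak localization is accurate to one grid
step (≈ a factor 1.37 in field) in all but ~1e-3 of cases.

`normalize_profiles` divides each profile by the magnitude of its
(log-linearly interpolated) intensity at a reference field (default
10 mT, the exchange-dominated feature), making concentration series
comparable; it is idempotent and fails loudly when the reference
intensity is consistent with zero.

## Geometry

Proline state is read from the peptide-bond dihedral ω (standard signed
dihedral, IUPAC convention, cross-checked against MDAnalysis): |ω| < 90°
is cis, the boundary is assigned trans, and the per-frame code orders
prolines flavin-first. The F/W "centers" are unweighted centroids of the
user-supplied moiety masks; plane normals come from total least squares
(smallest principal direction), with the angle folded to [0°, 180°] and
the stacking criterion treating θ and 180°−θ symmetrically: stacked means
3.0 Å ≤ d ≤ 6.5 Å (inclusive) and θ < 45° or θ > 135° (strict). A
hydrogen bond requires H···O < 3 Å with both the N–H···O and H···O–C
angles above 130°. Ensemble statistics are plain per-label counts
(conditional probabilities) plus distance/angle densities
(Freedman–Diaconis histograms, unit integral); the pooled "Sum"
distribution is exactly the label-fraction-weighted mixture.

## Diffusion

Pulsed-field-gradient decays follow I(g) = I0·exp(−D·γ²g²δ²(Δ−δ/3)); the
fit is nonlinear least squares initialized from the log-linear
regression, with gradients accepted in T/m or G/cm. The default design is
the experimental one (16 gradients spanning 2–95% of 50 G/cm, Δ = 50 ms,
δ = 2 ms); at 1% noise D is typically recovered to better than 1%, with
occasional ~2.5% excursions expected from the estimator's sampling
distribution. `compare_species` propagates the fit uncertainties into the
D ratio used for the compactness argument (faster diffusion = more
compact conformer).

## Synthetic data

The generators exist to close the loop on every analysis with known
truth; they emulate the *structure* of the real data, not its physics in
full:

* Kinetic traces: the model itself plus Gaussian noise (default 5%
  relative, stored as per-point sigma), at the two experimental delay
  designs (0/3/100 µs with a 4 µs pulse; ten delays over 0–100 µs with a
  2 µs pulse).
* Field profiles: 30 log-spaced points from 1 mT to 9.4 T. The
  J-resonance peak is a log-normal bump, the Δg onset a logistic in
  log B — generator conventions for classifier testing, not a spin
  simulation (the package deliberately contains no quantum-dynamical
  amplitude model); the physically meaningful content is the sign
  structure and the field scales. Noise is amplitude/SNR per point.
* Conformer ensembles: a synthetic two-ring dyad whose frames are drawn
  into exclusive stacked / H-bonded / extended classes with prescribed
  probabilities; stacked and H-bonded frames satisfy the respective
  criteria by construction, H-bonded frames are deliberately unstacked
  (perpendicular rings), extended frames center at 12 Å (the scale
  attributed to the all-cis configuration). Proline labels are realized
  through actual ω dihedrals drawn around 0° or 180° (σ = 10°, clipped to
  the basin so labels are exact).
* Diffusion decays: the Stejskal–Tanner model at the experimental
  gradient design, 1% relative noise by default.

All generators are bit-deterministic given a seed and never touch global
random state. Passing tests on these ensembles demonstrates correctness
of the analysis operators and the statistical behaviour of the estimators
under the stated noise models; they do not validate force fields,
spin-dynamical amplitudes, or spectrometer artifacts (baseline roll,
phase errors), which the generators do not emulate.

## Known limitations

* The kinetic model excludes the triplet-quenching step, diffusion-rate
  theory, and relaxation in diamagnetic products; γ is fixed unless
  explicitly freed.
* Relaxation times well beyond the kinetic window (T1 ≫ 100 µs) are
  recoverable only through the shared-parameter protocols; isolated
  three-point traces cannot determine them even in principle.
* The mechanism classifier is an algebraic decision procedure over
  printed sign rules; it does not simulate polarization amplitudes and
  its thresholds are calibrated for SNR ≥ 10 on the 30-point grid.
* Coordinate input is limited to multi-frame XYZ and PDB MODEL records;
  binary trajectory formats are out of scope.
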
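# Methods

`nrdecomp` analyses specular neutron reflectometry (NR) of solid-supported
phospholipid bilayers with and without a bound antimicrobial peptide
(maculatin 1.1, "Mac1"), and carries the two small spectroscopy conversions
used alongside such experiments (CD mean-residue ellipticity, paramagnetic
titration normalization).  This note records the models, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Scattering length densities

The SLD of a molecular species is `sum(n_i b_i) / V_m` with coherent
scattering lengths `b_i` from the bundled plain-text table
(`scattering_lengths.dat`; `b_H = -3.741e-5 A`, `b_D = +6.667e-5 A`).
Molecular volumes for the DMPC/DMPG (3:1) headgroup region (~313 A^3
mole-averaged), the myristoyl tail region (756 A^3 per lipid, fluid-phase
value) and per-residue peptide volumes (Zamyatnin-style consensus) are
defaults in `materials.MATERIALS`, overridable through the run
configuration.  They are literature-typical values, not fitted constants;
analyses sensitive to `V_m` (area per lipid) inherit their ~2-3%
uncertainty.

Labile hydrogens — backbone amides, Ser/Thr/Tyr/Lys/... side-chain protons,
termini, the DMPG glycerol hydroxyls — are assumed fully equilibrated with
the solvent: they scatter with `(1-f) b_H + f b_D` where `f` is the
solvent's deuterium fraction.  `f` is exposed per contrast because partial
exchange in a buried peptide is plausible but unquantified.

The half-deuterated peptide (d-Mac1, `GLFGVLAKVAAHVVPAIAEHF-NH2`) carries
methyl-deuterated residues only in its N-terminal half.  The exact labeled
positions are an explicit input; the default labels the six methyl-bearing
residues at positions 2, 5, 6, 7, 9 and 10 (L, V, L, A, V, A — 30
deuterons).  A 21-mer splits into halves 1-10 / 11-21, the midpoint residue
going to the C-half; segment SLDs use the segment's residue-volume share.
With this labeling the N-half SLD exceeds the C-half SLD by ~1.9e-6 A^-2,
which is the signal that makes peptide orientation visible in leaflet SLDs.

## Forward model

Reflectivity of a slab stack is computed by the Abelès transfer-matrix
method, vectorized over Q.  Conventions:

- `k_j = sqrt((Q/2)^2 - 4 pi (rho_j - rho_ambient))`, principal square root
  (evanescent waves get `Im k > 0`).
- Interfacial roughness is Gaussian, applied as a Névot–Croce damping
  `exp(-2 k_j k_{j+1} sigma^2)` on each Fresnel coefficient.
- R is clipped to <= 1 (the Névot–Croce factor can push |r| marginally
  above 1 in the evanescent region).
- Q is in 1/A everywhere.

An independent Parratt recursion coded in the test suite agrees with the
kernel to ~1e-13 relative on random 1-6-layer stacks.  One caveat worth
recording: "insert a zero-thickness layer and nothing changes" is exact
only for ideal interfaces, because a rough interface's damping factor uses
the wavevectors of its neighbours.

Resolution smearing is Gaussian in Q, by default a constant relative FWHM
`dQ/Q = 0.084` (a typical time-of-flight chopper setting), implemented as a
17-point fixed quadrature spanning +-3.5 standard deviations with the model
evaluated on the extended grid (no edge padding).  A per-point `dQ` column
(FWHM, converted by `1/(2 sqrt(2 ln 2))`) is used when the data file
provides one.

## Membrane model

The supported membrane is `Si | SiO2 | inner heads | tails | outer heads |
solvent`, with the beam incident through silicon, so "inner" is the
oxide-facing leaflet.  The tails are one layer (three-layer bilayer model)
or two sub-layers with independent SLDs (four-layer model, for
peptide-bound states where the leaflets may differ).  An interstitial water
layer between oxide and inner heads is supported but off by default, and
oxide hydration defaults to zero.  Inner and outer headgroup thicknesses
are tied by default.  No head/tail area-consistency constraint is imposed.

Structural parameters are shared across solvent contrasts; only solvent SLD
and exchange-dependent SLDs differ between D2O and H2O.  Each layer's SLD
is the volume-fraction-weighted mix of its dry components and solvent.
Tail layers can alternatively carry directly fitted per-contrast SLDs
(`fitted_tail_slds`), the parametrization used after peptide binding when
the layer composition is the unknown being sought; these fitted values are
total layer SLDs, solvent included, and feed the decomposition below.

## Refinement and uncertainties

All contrasts of one sample state are fitted simultaneously by minimizing
`chi2 = sum ((R_model - R)/dR)^2` over every curve.  The fit is in linear R
weighted by dR; a log-R objective is available behind a flag.  Global
search is `scipy.optimize.differential_evolution` within finite parameter
bounds (population 15x by default, latin-hypercube init seeded with the
model's current — typically composition-derived — parameter vector, fixed
seed), followed by a trust-region-reflective least-squares polish.  The
polish never accepts a worse point than its start.  Seeds are mandatory
arguments; there is no hidden global random state.

Parameter uncertainties use Monte-Carlo resampling: every data point is
perturbed by `N(0, dR)`, the perturbed data refit (local polish from the
best fit by default; a full global restart per replicate is opt-in), and
the 95% interval is the [2.5th, 97.5th] percentile range of the fitted
distribution.  The production default is 1008 replicates; tests and the
acceptance script use 100-200 to stay fast, which widens the CI estimate's
own noise to a few percent.  On a linear toy model the resampled CI
half-width agrees with the analytic slope standard error within ~7%, and
coverage over repeated simulations is consistent with 95%.  A cheap
linearized error (finite-difference Jacobian, `(J^T J)^-1`) is attached to
every fit and is used as the fallback uncertainty where no resampling has
been run.

## Composition decomposition and orientation

With >= 2 contrasts, each fitted layer SLD gives a linear system
`SLD_layer(c) = sum_k SLD_k(c) phi_k`, closed by `sum(phi) = 1`; it is
solved by least squares (exactly determined for two contrasts), the
condition number is reported, and out-of-range fractions are clipped and
flagged.

Area per lipid is `A = V_m / (tau phi_lipid)` with `V_m` the per-lipid tail
volume and `tau` the *per-leaflet* tail thickness (half the total tail
region in the symmetric models).  The fluid (L_alpha) vs gel (L_beta) call
uses a configurable threshold, default 47.0 A^2 — chosen midway between
the fluid and gel areas reported for di-C14 PC/PG supported bilayers
(~49-57 vs ~45 A^2) so that both regimes classify correctly; ties go to
fluid.  For peptide-bound layers `A` counts only the lipid fraction, so
lipid displacement inflates it; phase calls are meaningful mainly for
peptide-free states.

Leaflet SLD asymmetry after binding of a half-labeled peptide admits two
interpretations, both computed:

- **Uneven distribution** (scenario A): whole-peptide SLD in both leaflets,
  independent per-leaflet peptide and solvent fractions.  With two
  contrasts this system is saturated (residual ~0 by construction).
- **Oriented spanning** (scenario B): the N-half SLD is assigned to one
  leaflet and the C-half SLD to the other, with a *single* shared peptide
  fraction and per-leaflet solvent; both orientations (N-in, N-out) are
  solved by least squares over all leaflets and contrasts.

Because A is saturated, model selection is by parsimony: the better
oriented scenario wins if its residual is within the SLD uncertainty of
A's; otherwise A is reported.  The uncertainty is taken from the
Monte-Carlo CIs of the fitted tail SLDs when available, else from the
linearized errors, else a 2e-8 A^-2 default.  When the two orientations'
residuals differ by less than that uncertainty the comparison is flagged
indistinguishable — with noisy data or symmetric labeling the method
honestly declines to pick a direction.  Swapping the leaflet inputs swaps
the N-in/N-out residuals exactly.

## Synthetic study generator

`generate_study_fixture` emulates the full experimental design with no
measured input: 2 lipid labelings (chain-perdeuterated d54 and hydrogenous)
x 2 states (bilayer, bilayer + peptide) x 2 temperatures x 2 contrasts
(D2O, H2O) = 16 curves, each carrying its ground truth.  Generating values
are plausible for DMPC/DMPG (3:1) on silicon: fluid-phase tails 26.4 A
total at lipid fraction 0.95 (area per lipid 60.3 A^2), gel-phase tails
34.5 A at 0.97 (45.2 A^2), ~10 A oxide, 8 A headgroups at 30% hydration,
3 A roughnesses.  Peptide-bound truths thicken the tails and set peptide
fractions of 0.18/0.18 (oriented scenarios) or 0.10/0.22 (uneven).  Noise
is Gaussian with `sigma = max(0.01 R, 1e-8)` — 1% relative counting
statistics with a background-limited floor — on a 120-point geometric Q
grid over 0.01-0.3 1/A.

What passing recovery tests show: the estimator chain (kernel, co-refined
parameters, resampled errors, decomposition, scenario selection) is
self-consistent and unbiased under its own noise model at realistic count
levels.  What they do not show: robustness to imperfections real data
carry — background misestimation, normalization drift, non-Gaussian
outliers, interfacial structure outside the slab family (e.g. asymmetric
head hydration), or molecular-volume errors.  Generator values are inputs
to the simulation, not claims about any measured system.

## Problem sizes

Recovery tests and the acceptance script run two-contrast co-refinements of
4-6 free parameters on 120-point curves (differential evolution capped at
60 generations, population 8x), Monte-Carlo calibration with 100-200
replicates, and scenario identification over 6-10 independent seeds.
These sizes were chosen as the smallest at which the statistical checks are
stable; the production defaults (1008 replicates, population 15x, 150
generations) are what an analysis of measured data would use.

## Known limitations

- Off-specular scattering, polarized beams, absorption and incoherent
  backgrounds are out of scope; X-ray SLDs are not computed.
- The labile-H model is all-or-nothing equilibration at the solvent's D
  fraction.
- Scenario B assumes the peptide spans the bilayer with its halves cleanly
  partitioned between leaflets; tilt angles and oligomeric state are not
  inferred.
- The PRE helper normalizes titration intensities (per-step cumulative
  dilution correction); it deliberately does not fit attenuation curves.
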
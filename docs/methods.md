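# Methods

This note documents the models implemented in `qsarfep`, the conventions and
default parameters, what the synthetic-data generators do and do not emulate,
and the numerical choices a maintainer would want to know about.  It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Alignment

Congeneric series are superposed onto a template by rigid Kabsch
superposition over an explicit common-core atom mapping (CSV-style index
pairs; no substructure search).  The SVD solution carries a determinant
correction so only proper rotations are returned — chirality is never
inverted.  Collinear or coincident core mappings raise a degeneracy error.
Coordinates are Angstrom throughout; no unit conversion happens anywhere.

## CoMFA fields

A grid with 1 Å spacing (default) encloses the aligned set plus a 4 Å margin
on every side; dims = ceil(extent/spacing) + 1 per axis.  Every grid
intersection is probed by an sp³ carbon with charge +1:

* steric: 12-6 Lennard-Jones, `A/r¹² − C/r⁶`, built from an embedded
  class table of (r_min/2, ε) values combined by Lorentz–Berthelot mixing.
  The table is deliberately small, Tripos-like in magnitude, and part of
  this package's contract — reproducibility was chosen over fidelity to any
  proprietary parameter set.
* electrostatic: Coulomb with a distance-dependent dielectric ε(r) = r,
  i.e. `332.0636 · q_i / r²` kcal/mol.

Both fields are truncated at ±30 kcal/mol (configurable).  Electrostatic
values at grid points whose steric energy reached the cap (probe inside the
molecule) carry no information and are replaced by the column mean over the
unburied compounds — the long-standing CoMFA convention.

## CoMSIA fields

Gaussian-attenuated similarity indices `field_k(g) = −Σ_i w_ik e^{−α r²}`
with attenuation α = 0.3 Å⁻² (the standard literature default, configurable)
and probe weight +1.  Per-atom properties come from an element-level table:
steric weight is an r³ van-der-Waals volume proxy, electrostatic weight is
the partial charge, hydrophobicity is a coarse ±1 scale, and donor/acceptor
are element-level flags (the molecules carry no bond graphs, so N counts as
donor+acceptor, O and F as acceptors).  The default kind combination is
{S, E, D}.  Gaussians are bounded, so no truncation is applied.

## Descriptor block

Columns are ordered by (field kind, flat grid index).  Columns with standard
deviation below `min_sigma` are dropped and logged; the default 2.0 kcal/mol
follows CoMFA practice and is appropriate for energy-valued fields — CoMSIA
similarity values are orders of magnitude smaller, so callers pass a
proportionally smaller threshold there.  Surviving kinds receive CoMFA-STD
block scaling: each kind is divided by its pooled column standard deviation
so that every field type enters the regression with equal overall variance.

## PLS and component selection

Single-response NIPALS PLS on centered (not autoscaled) data; for one
response each component is closed-form (weight ∝ X'y), so the fit is exact
and deterministic — the tolerance (1e-12) and iteration cap (500) exist only
as interface guards.  Training statistics: r² = 1 − RSS/SS, SEE =
√(RSS/(n−c−1)), F = (r²/c)/((1−r²)/(n−c−1)).  Per-kind field fractions are
the normalized sums of |coefficient × column stdev|.

Leave-one-out cross-validation reuses the column filtering and block scaling
fixed on the full training block rather than re-deriving them per fold,
mirroring classic CoMFA implementations.  The optimal number of components
maximizes q² = 1 − PRESS/SS over a scan (default cap 6 in the pipeline);
ties, including a flat trace, break toward fewer components (parsimony).

## Validation battery and gates

The external battery follows the Golbraikh–Tropsha conventions: k = Σyŷ/Σŷ²
and k′ with the axes swapped; r₀² from the through-origin regression with
predictions on the abscissa, the primed variant with axes swapped;
r_m² = r²(1 − √|r² − r₀²|); r²_pred = Q²F1 = 1 − PRESS/Σ(y−ȳ_train)²;
Q²F2 uses the test mean; Q²F3 compares per-compound mean squared errors
scaled by the training variance; Q_ccc is Lin's concordance coefficient.
χ² is Σ(y−ŷ)²/|ŷ| by default (the denominator is switchable to the observed
values; the QSAR-metrics literature uses both and neither is canonical).
When predictions are constant the correlation-based statistics are reported
as NaN rather than raising, so a null model can still be scored by the
PRESS-based coefficients.

Threshold gates (all strict): q² > 0.5, r² > 0.6, 0.85 ≤ k or k′ ≤ 1.15,
r₀²−r′₀² < 0.3, r_m² or r′_m² > 0.5 (each on the external test set),
r²_pred > 0.6, χ² < 1.0 and RMSE < 0.5 (on the training fit).  The overall
verdict is the conjunction.

The stratified split bins compounds into low/medium/high activity classes at
two pIC50 cut points (default: terciles — the class boundaries are exposed
as configuration because no canonical values exist) and draws
round(n_class/4) compounds per class into the test set with a seeded
generator, giving the 3:1 ratio.  Bootstrap r² refits the model on resamples
drawn with replacement (default 100), redrawing degenerate resamples at most
10 times.

## Applicability domain

Leverages are computed in the PLS latent space on the intercept-augmented
score matrix — raw field-space leverage is singular at 10³–10⁴ columns, and
latent-space leverage is the standard Williams-plot practice for PLS.  The
warning leverage is h\* = 3(c+1)/n_train; compounds beyond h\* or with
|standardized residual| > 3 (residuals scaled by the training RMSE) are
flagged.  A known property of this construction: a structural outlier whose
deviation is orthogonal to the latent space shows *low* leverage and is
caught, if at all, by the residual criterion — the displaced-compound tests
reflect this.

## Contour maps

Column j contributes stdev_j × coefficient_j at its grid location (dropped
columns contribute zero).  Favored/disfavored iso-levels default to the 80th
percentile of the positive contributions and the 20th percentile of the
negative contributions per kind, the classic contouring split; both are
configurable.  Grids are exported as OpenDX scalar fields in the standard DX
data order (C order, last axis fastest) with full double precision, so
export/import round-trips are bit-identical and third-party readers parse
the files unchanged.

## End-state energetics

ΔTOTAL is the sum of the four per-frame term means (VDWAALS, EEL, EGB or
EPB, ESURF).  The interaction entropy −TΔS = β⁻¹ ln⟨e^{β(E_int−⟨E_int⟩)}⟩
is evaluated through log-sum-exp; E_int defaults to VDWAALS + EEL (the term
subset is configurable, since which subset upstream tools use is not
standardized).  By Jensen's inequality the estimator is non-negative for any
fluctuating series; for Gaussian fluctuations of spread σ it converges to
βσ²/2, which is the analytic oracle used in the tests.  ΔG_bind = ΔTOTAL +
(−TΔS), with k_B = 0.0019872041 kcal/(mol·K) and T = 300 K by default.  The
binding energy is understood in the standard end-state form
ΔG_bind = ΔG_COM − (ΔG_PROT + ΔG_LIG).  The contact shell returns residues
with at least one atom strictly within the cutoff (default 4 Å) of any
ligand atom; a non-positive cutoff returns an empty list.

## BAR and the thermodynamic cycle

For each adjacent λ pair, ΔG solves the Fermi-function self-consistency
equation with M = ln(n_F/n_R), root-bracketed within ±100 kcal/mol and
polished by Brent's method to machine tolerance; the asymptotic standard
error is Bennett's variance estimator evaluated at the solution.  Estimates
are exactly antisymmetric under exchanging the forward/reverse roles, which
is what closes reversed cycles identically.  The λ schedule is uniform with
12 windows by default (the sub-scheduling of individual coupling parameters
belongs to the sampling engine, which is out of scope here).  Legs are
chained per replicate; summaries report the replicate mean, the SD across
replicates (preferred in tables) and the aggregate asymptotic standard
error.  The cycle closes as ΔΔG_RBFE = ΔG_COM − ΔG_LIG with leg SDs combined
in quadrature.  Experimental references use ΔG_EXP = −RT ln10 · pIC50 at
T = 300 K (exposed as configuration: activity data cannot pin T more
precisely than a few kelvin).

## Synthetic data: what it emulates and what it does not

*Ligand series.*  A rigid core (8 atoms by default) shared bit-identically
by all compounds, with 3 R-group sites at 3.5 Å from the core centroid.
Each site carries a small per-seed library of 6 discrete substituent
variants (0–3 atoms from a C/N/O/Cl palette at jittered radii of 1.2–2.5 Å);
every compound draws one variant per site and adds 0.05 Å positional jitter.
The discrete, shared substituents are deliberate: real congeneric series
reuse a limited set of R-groups, and that redundancy is precisely what gives
field descriptors the low-rank structure PLS exploits — fully random
per-compound decoration produces descriptor matrices no field-based method
could generalize from.  Activities are planted as pIC50 = 7.0 + Σ_s w_s ·
X[col_s] + N(0, 0.2²), where the planted columns are actual surviving CoMFA
steric columns near each site (the highest-variance column within 2.5 Å)
and the default weights are (1.0, −0.8, 0.6).  The 7.0 baseline puts
activities in a realistic potency range.  In the noiseless limit the planted
model is exactly linear in surviving columns by construction.  Not emulated:
chemically valid bond graphs, conformational flexibility, tautomers,
receptor-based field masking — so passing tests demonstrate statistical
recovery of a field-linear signal, not chemical realism.

*Energy series.*  I.i.d. Gaussian per-frame terms with planted means and
spreads.  Real MM-PB/GBSA series are autocorrelated and occasionally
heavy-tailed; the interaction-entropy tests therefore validate the estimator
against its analytic Gaussian limit, not its behavior on correlated data.

*Work samples.*  Forward samples ~ N(ΔG + βσ²/2, σ²) and reverse samples
~ N(−ΔG + βσ²/2, σ²), which satisfies the Crooks fluctuation relation
exactly, so the planted ΔG is the analytic free energy of each pair.  Real
alchemical work distributions are skewed and window-dependent; the BAR
tests validate estimator correctness and error calibration in the Gaussian
regime.

All randomness flows through numpy's PCG64 `default_rng`; each artifact
takes one seed, split into independent child streams per compound, replicate
and window via `SeedSequence.spawn`, making outputs bit-reproducible across
runs and platforms.

## Problem sizes and runtime

The shipped study conditions are small by design: 40-compound series on a
~20³ grid (a few thousand surviving columns), LOO scans to 6 components,
100-sample bootstraps (20 in the multi-seed sweeps), 5000 work samples per
window direction, and 10⁵-frame entropy series.  The full test suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

* The LJ and CoMSIA property tables are package-defined contracts, not fits
  to any published force field; absolute field values are therefore not
  comparable across programs, though all downstream statistics are.
* Leverage-based AD cannot flag structural outliers orthogonal to the
  latent space (see above).
* No MBAR, no PLS2, no per-fold refiltering (exposed as a possible
  extension), no flexible alignment.
* External test residuals include model error on top of the planted noise;
  with the default conditions their spread sits between 1× and 2.5× the
  planted noise SD rather than at the noise floor.
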
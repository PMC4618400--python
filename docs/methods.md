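# Methods

This note documents the models implemented in `lsferric`, the defaults
and numerical choices behind them, and what the synthetic-data tests do
and do not demonstrate.

## Ligand-field model of the low-spin d5 ground state

A low-spin Fe(III) ion has a (t2g)^5 configuration: a single hole in
{d_yz, d_xz, d_xy}. A rhombic protein field splits the three orbitals by
a tetragonal parameter Δ (d_xy vs the {d_xz, d_yz} pair center) and a
rhombic parameter V (d_xz vs d_yz), with hole energies
(E_yz, E_xz, E_xy) = (−V/2, +V/2, Δ). Negative Δ places the hole in
d_xy. The in-state spin–orbit interaction −ζ L·S (hole convention; ζ is
the one-hole coupling constant, cm⁻¹) mixes the orbitals, so the ground
Kramers doublet is a|yz⟩ + b|xz⟩ + c|xy⟩ in orbital composition with
the appropriate spin pairing, and the principal g values are exact
quadratic forms in (a, b, c):

    g_x = 2[a² − (b+c)²],  g_y = 2[(a+c)² − b²],  g_z = 2[(a+b)² − c²].

Because g_z + g_y = 4a(a+b+c) (and cyclic analogues), the map inverts in
closed form: a:b:c = (g_z+g_y):(g_z−g_x):(g_y−g_x), and

    V/ζ = g_x/(g_z+g_y) + g_y/(g_z−g_x)
    Δ/ζ = g_x/(g_z+g_y) + g_z/(g_y−g_x) − V/2ζ.

The rhombicity |V/2Δ| ∈ [0, 1/3] under the proper-axis convention and
is ζ-independent. The two intra-t2g excitations sit at |Δ| ∓ |V|/2, so
they differ by exactly |V|.

Two independent routes to g are implemented and cross-checked to 1e−8:
the closed forms above applied to the diagonalized doublet's
coefficients, and direct magnetic-moment matrix elements
μ_k = L_k + 2S_k evaluated in the doublet {ψ, Tψ}. For the latter, the
3×3 matrix of Pauli coefficients B equals diag(g)·Rᵀ up to a pseudo-spin
gauge rotation R; |g_k| is the k-th row norm and the conventional signs
follow once the gauge is anchored on the spin-down d_xy member with real
positive amplitude (so a pure d_xy hole gives g = (−2, 2, −2), the
standard sign pattern of this analysis). The orbital angular-momentum
matrices on (yz, xz, xy) are derived from L = −i r×∇ and satisfy
[L_x, L_y] = −i L_z (the t2g set behaves as an effective l = 1 with
inverted sign).

**Parameters.** ζ defaults to 380 cm⁻¹, an effective (covalently
reduced) one-hole constant appropriate for a thiolate-rich Fe(III) site;
free-ion ζ is ≈460 cm⁻¹. It is exposed everywhere as a parameter; the
rhombicity and the coefficient ratios do not depend on it. The orbital
reduction factor is fixed at 1 (pure in-state treatment, no covalency
scaling of L), which keeps the inversion closed-form.

**Sign/assignment search.** EPR gives only |g|. `assign_g_tensor`
enumerates the 6 axis permutations × sign patterns (modulo the overall
Kramers sign, fixed by g_y > 0), scores each by the Euclidean distance
between the input triple and the g re-predicted from its own
coefficients, and filters to candidates with rhombicity ≤ 1/3 and
V ≥ 0. The V ≥ 0 filter removes an exact relabelling degeneracy:
swapping the x and y magnitudes with matching signs swaps a↔b and flips
V while describing the same site, so only the representative with d_yz
below d_xz is kept. Ties are broken toward lower rhombicity. Degenerate
inputs (axial/isotropic) flag candidates with `parameters=None` rather
than dividing by zero.

## Powder EPR simulation and mixture quantitation

Randomly oriented S = 1/2 molecules resonate at
B(θ,φ) = (h/μ_B)·ν / g_eff(θ,φ) with
g_eff² = g_x²sin²θcos²φ + g_y²sin²θsin²φ + g_z²cos²θ. The powder
pattern is the solid-angle average of unit-area Gaussian lines at those
fields; the spectrometer records the field derivative, taken
analytically per orientation (no modulation-broadening model). The
per-orientation FWHM interpolates the three per-axis widths as
√(Σ w_i² ℓ_i²) with direction cosines ℓ — the simplest strain-free
convention. Orientations are averaged on an equal-area midpoint grid in
cosθ × φ over one octant (rhombic symmetry), default 200 × 200, which
agrees with a 4× finer grid to well below the linewidth. Because each
species' underlying absorption integrates to exactly 1 (analytic
Gaussian areas), non-negative least-squares amplitudes of simulated
components against an observed spectrum are directly proportional to
populations — equivalent to double-integration quantitation — and are
renormalized to fractions. Near-collinear component sets trigger a
conditioning warning.

Defaults: microwave frequency 9.40 GHz (X band; it is metadata on every
spectrum, never assumed silently), per-axis FWHM 1.5 mT, field grid
260–380 mT with 1024 points, 77 K. These are representative acquisition
settings for frozen-solution low-spin ferric proteins.

## pKa inference

A single ionization obeys the Henderson–Hasselbalch relation; a lone
(pH, fraction-protonated) observation inverts exactly to
pKa = pH + log10(f/(1−f)), and a titration series is fit by least
squares to f(pH) = 1/(1+10^(pH−pKa)). Points with fractions at 0 or 1
carry no information and are rejected (single point) or dropped (fit).
A series lying entirely on one side of half-protonation within a span of
< 0.5 pH units warns of ill-conditioning.

## Optical band deconvolution and C/D ratios

Absorption and MCD spectra are modelled as sums of Gaussians
A·exp(−4 ln2 (ν̃−ν̃₀)²/FWHM²) on a wavenumber axis, non-negative
amplitudes in absorption and signed in MCD. Fits use `lmfit`
least squares with optional per-band center windows, global FWHM bounds
(default [800, 6000] cm⁻¹, initial 2500 cm⁻¹ — band widths for these
systems are not published), an optional single shared width, and
optional center-linking of the MCD fit to the absorption fit.
Absorption and MCD are fitted independently by default.

For a paramagnet in the linear (Curie) response regime, the C-term to
dipole-strength ratio of a band follows from peak intensities as
|C/D| = (k_B·T/(μ_B·B))·|Δε/ε| with k_B = 0.6950348 cm⁻¹ K⁻¹ and
μ_B = 0.4668645 cm⁻¹ T⁻¹, tabulated as |C/D|×10⁴ rounded half-up to an
integer. At 5 K and 7 T the prefactor is 1.0634. The 5 K/7 T regime is
close to magnetic saturation, where the strict Curie proportionality
bends over; the linear formula is nevertheless the convention used for
published tables of this enzyme and is applied uniformly.
`detect_pseudo_a` flags every pair of bands with opposite MCD signs and
both |C/D|×10⁴ at or above a threshold (default 200) as pseudo-A
candidates, nearest-in-energy first; confirming a pseudo-A term needs
polarization information the optical data alone do not contain, so the
output is a candidate list, not an assignment.

Band tables pair absorption and MCD bands by nearest center within a
tolerance (default 1500 cm⁻¹); unpaired bands become explicit rows, not
silent drops. Transition assignments (thiolate π→dπ*, amidate π→dπ*,
sulfinate σ→dσ*, …) are caller-supplied labels from resonance Raman or
computation — this package does not compute them.

## Synthetic data: what it emulates, and what it does not

No deposited spectra exist for these enzyme forms, so the generators
build inputs from the published parameters: EPR mixtures from the
published g values of the butyrate-bound species and the major/minor
aqueous species, with fractions such as 74/26 at pH 7.5; titration
fractions from the published pKa values 6.1 and 8.5; optical pairs from
the published band energies, ε and Δε of both forms (presets `NHaseBA`,
8 bands, and `NHaseAq`, 7 bands) with a common 2500 cm⁻¹ width. Noise is
additive white Gaussian scaled to the maximum absolute intensity (2% for
EPR tests, i.e. SNR 50; 1% for optical; 0.02 absolute for fractions);
real spectra additionally contain baseline drift, g-strain, modulation
broadening and heteroscedastic noise that the generators deliberately
omit. Passing recovery tests therefore demonstrates the correctness and
statistical calibration of the estimators under the stated noise model,
not instrument-grade robustness.

Recovery tolerances: two-component mixture fractions are recovered with
bias < 0.01 and RMSE < 0.02 over 100 seeds at SNR 50. Gaussian-band
recovery on the preset fixtures is assessed on per-band means over 20
seeds (≤ 100 cm⁻¹ in center, ≤ 5% in amplitude, achieved at ≈17 cm⁻¹
and ≈1.4%): the weakest bands (ε ≈ 310–350 under spectra peaking near
4000) buried between strong neighbours have a single-realization
uncertainty floor of ≈7–9% in amplitude at this noise level whatever the
constraint protocol, so a worst-case single-seed criterion would test
the noise draw, not the fitter. The band fits for these tests use the
shared-width constraint (the generator uses one width) and ±500 cm⁻¹
center windows.

## Numerical and interface choices

- Degenerate Taylor denominators raise structured errors
  (`DegenerateAssignmentError`) instead of returning infinities; Δ = 0
  maps to rhombicity 0 (V = 0) or ∞.
- Transition prediction enforces |Δ| ≥ |V|/2 (`OrderingError`
  otherwise); grids that miss the EPR turning points or an optical
  band ± 2 FWHM raise `GridCoverageError`.
- Resampling is linear interpolation only; extrapolation is forbidden.
- Energies are cm⁻¹ throughout (nm converted as 10⁷/nm at load), EPR
  fields in mT, MCD fields in T.
- Spectrum files are two-column text with `# key = value` headers; MCD
  files must carry temperature and field. Instrument formats (JCAMP-DX
  etc.) are out of scope.
- The pipeline report is a pydantic model; `report_schema.json` is
  generated from it and shipped so consumers can validate reports
  without importing the package.
- All generators are pure functions of (parameters, seed) via
  `numpy.random.default_rng`.

## Known limitations

- No hyperfine structure, g-strain distributions, or
  saturation/relaxation effects in the EPR model.
- The Curie C/D formula is used at 5 K/7 T without a saturation
  correction (matching the published convention for these tables).
- No moment (C₀/D₀) analysis, VTVH-MCD fitting, or B-term treatment.
- The Taylor inversion assumes a pure t2g hole; quantitative accuracy
  degrades for sites with significant t2g–eg mixing or where the
  orbital reduction factor deviates strongly from 1.
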
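# Methods

This note records the models implemented in `memtool`, their assumptions,
the defaults and why, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Monolayer elasticity and transition detection

The elastic compression modulus is implemented as `Cs⁻¹ = −A (∂π/∂A)_T`
(units mN m⁻¹): a stiff condensed film has a large modulus and a
first-order phase transition, where π is nearly flat in A, appears as a
minimum. Raw isotherms are noisy and differentiation amplifies noise, so
π(A) is smoothed with moving-window polynomial fits (default window 11
points, order 3) and the derivative is taken analytically from the local
fit. Windows are index-centred and clipped at the series ends, which
reduces to one-sided fits there; the windowed fit handles the non-uniform
area grid that a π-gridded isotherm produces. Both window and order are
exposed because the appropriate smoothing depends on the instrument's
noise and sampling.

`detect_transition` returns the π of the interior minimum of Cs⁻¹ within a
search range, with ties broken toward lower π for determinism. A minimum
only counts if it undercuts both range edges by at least 5 % (the
`min_prominence` parameter): without a prominence requirement, a flat or
merely noisy modulus curve would always yield a spurious "transition" at
whatever point the noise happens to dip. Transitions shallower than the
prominence threshold are therefore reported as absent — a deliberate
trade-off favouring specificity.

## Insertion kinetics and exclusion pressure

Constant-area insertion traces are fit to Δπ(t) = Δπ_max (1 − e^{−βt}) by
unweighted least squares including the t = 0 point (no weighting scheme or
dead-time correction is applied; an injection dead-time, if present in a
given instrument, should be trimmed before fitting). Initial guesses come
from the tail mean (plateau) and the initial slope divided by that plateau.
The fit warns when the trace spans less than 2/β, where the plateau is
poorly constrained. Parameter standard errors from the covariance matrix
are reported so recovery can be judged in units of the fit's own
uncertainty.

The exclusion surface pressure is the abscissa intercept −c/m of the
ordinary-least-squares line Δπ_max = m·π₀ + c. It is only meaningful for
m < 0 (insertion must decline with film pressure); a non-negative slope is
flagged as undefined rather than extrapolated.

## ATR interface optics and orientation

Penetration depth follows d_p = λ/(2π√(n1²sin²β − n2²)). Field amplitudes
use the standard two-phase thick-film approximation (Harrick) for a film
much thinner than d_p:

    Ey² = [2cosβ/√(1−n21²)]²
    Ex² = [2cosβ·√(sin²β−n21²)]² / [(1−n21²)((1+n21²)sin²β−n21²)]
    Ez² = [2cosβ·sinβ]²          / [(1−n21²)((1+n21²)sin²β−n21²)]

with n21 = n2/n1. An optional three-phase thin-film mode rescales the
normal field amplitude by (n2/n_film)² — continuity of the normal
displacement across a film of index n_film — i.e. Ez² by (n2/n_film)⁴.
Which variant (and which film index) best represents a given cell is an
experimental question, so both are exposed rather than one being chosen
silently. Defaults n1 = 3.42 (silicon prism), n2 = 1.42 (dilute-electrolyte
D₂O), β = 60°; all overridable. With these defaults and R = 1 both modes
give θ_dip ≈ 73°.

Converting a dichroic ratio to an order parameter assumes uniaxial symmetry
of the film about the interface normal; S_dip then reports an *effective*
dipole angle — a delta-function orientation and a broad distribution with
the same ⟨cos²θ⟩ are indistinguishable. S_dip rises from −0.5 at
R = Ex²/Ey² (dipole in-plane) toward 1 as R → ∞ (dipole along the normal);
ratios below Ex²/Ey² are physically inconsistent with the supplied optics
and raise an error, while values outside [−0.5, 1] by less than 10⁻⁶ are
clamped with a warning as numerical noise. Angles are kept in degrees at
full precision internally and rounded only for presentation.

The chain tilt uses the mutual orthogonality of the two CH₂-stretch
transition dipoles and the chain axis: cos²θ_tilt = 1 − cos²θ_sym −
cos²θ_asym, with a negative radicand (beyond 10⁻⁹) rejected as
non-orthogonal inputs.

## Band deconvolution

Both polarizations are fit jointly to a shared set of pseudo-Voigt bands —
same centers, FWHMs and Gaussian/Lorentzian mixing, since p and s probe the
same vibration with different projections — with independent amplitudes and
an independent polynomial baseline (order 0–2) per polarization. Band areas
follow analytically from amplitude, width and mix. Seed centers come from
known band assignments, so centers are bounded within ±8 cm⁻¹ of their
seeds and widths within 3× their seeds; without these bounds a weak
shoulder band can migrate under a strong neighbour into a spurious local
minimum. Unseeded amplitudes start from the local baseline-corrected
signal. Non-convergence raises an error carrying the final residual, and a
band collapsing onto the minimum-width bound (default 0.1 cm⁻¹) is
reported as an error rather than returned. Note that Lorentzian wings
extend beyond any finite fit window, so integrated areas of strongly
Lorentzian bands carry a window-truncation bias of order 1–2 %; analyses
that need 2 % area accuracy should use wide windows or near-Gaussian bands.

## Pseudocapacitance and the dielectric model

The measurement model is a series-RC element at a single frequency:
C_ps = 1/(2πf·|Z″|), reported in μF cm⁻². No equivalent-circuit fitting is
attempted because only the single-frequency imaginary component is modelled.
The thickness model assumes a parallel-plate dielectric with unchanged
dielectric constant, so Δd/d = (C_ref/C_new − 1)·100 %. Only the *relative*
change is computed: an absolute thickness change would require an assumed
absolute layer thickness or dielectric constant, which the measurement does
not provide. Potentials are carried as labels (V vs SCE) with no
reference-electrode conversion.

## Trajectory observables

The bilayer normal is fixed to the box z-axis (planar-bilayer convention)
and all periodic geometry uses the minimum-image convention under the
per-frame orthorhombic box. Coordinates are in Å, charges in e, energies
in kcal mol⁻¹; atom indices are 0-based internally, 1-based in messages.

- **z-distance distribution:** per frame, the signed z-separation between
  the mass-weighted centers of the probe selection and of the N closest
  reference molecules (default 6, re-ranked every frame by minimum-image
  center-of-mass distance; `None` uses the whole selection). Histograms are
  normalized to a probability density.
- **Hydrogen bonds:** a bond exists when the donor-heavy–acceptor distance
  is ≤ 3.5 Å and the D–H···A angle ≥ 135°. These geometric cutoffs are
  conventional trajectory-analysis defaults, not measured quantities, and
  are configurable. Each bond increments both the donor atom's and the
  acceptor atom's group; a group's time fraction is its total bond count
  over frames divided by the frame count, so simultaneous bonds push it
  above 1 (one full-time plus one half-time bond = 1.5). Donor–hydrogen
  pairing comes from the topology's explicit `parent` column rather than
  name conventions.
- **SCD:** per acyl carbon (identified by the numeric suffix of the atom
  name within each residue), SCD = ⟨(3cos²θ_CH − 1)/2⟩ over lipids, frames
  and the carbon's C–H bonds. Carbons without explicit hydrogens raise an
  error unless ideal tetrahedral reconstruction from the neighbouring
  carbons is requested (terminal carbons are then skipped). An
  absolute-value presentation flag is provided since order profiles are
  often plotted as |SCD|.
- **Tilt:** the chain vector runs from the first to the last tail carbon of
  each residue. Unfolded angles span [0, 180]° and show the two leaflets as
  two peaks mirrored about 90° (both leaflets are measured against the same
  +z normal); folding maps θ → min(θ, 180−θ).
- **Interaction energy:** molecules (residues) of the partner selection
  with any atom within the cutoff (default 12 Å) of the probe selection are
  retained whole, and the full cross-pair sum is evaluated — hard
  truncation at the molecule level, no switching function, no
  intra-selection terms. Coulomb uses k = 332.0636 kcal·Å·mol⁻¹·e⁻² and
  Lennard-Jones uses Lorentz–Berthelot combining (arithmetic σ, geometric
  ε), consistent with Amber-family force fields.

## Synthetic generators: what they emulate, and what they do not

All generators draw from a single `numpy.random.default_rng(seed)`; the
same parameters and seed reproduce output byte-for-byte, and every
generator returns a machine-readable truth record.

- **Isotherms** use a piecewise constant-modulus model A(π) = A_i
  exp(−(π−π_i)/C_i), continuous at the joins, with default moduli
  (100, 5, 200) mN m⁻¹ and a plateau centred at 20 mN m⁻¹ — the pressure
  region where saturated-chain films show their LE/LC minimum. The plateau
  π-width defaults to 1.0 mN m⁻¹ (transition minima are narrow in π) and
  pressure noise to 0.05 mN m⁻¹ (Wilhelmy-plate scale). Real isotherms have
  curvature within phases and collapse behaviour that this model omits.
- **Insertion traces** are exact first-order curves with Δπ_max linear in
  π₀ (defaults: slope −0.2, intercept 10.5 mN m⁻¹, hence an exclusion
  pressure of 52.5 mN m⁻¹, above typical collapse pressures; β = 0.01 s⁻¹,
  600 s traces). Real traces can show mixing transients at injection.
- **Spectra** are forward-generated from the same orientation model the
  analysis inverts: A_p ∝ Ex²(1−⟨c²⟩)/2 + Ez²⟨c²⟩ and A_s ∝ Ey²(1−⟨c²⟩)/2
  per band, with ⟨c²⟩ = cos²θ_dip by default (delta orientation) or the
  solid-angle-weighted average of a Gaussian orientation distribution to
  probe the effective-angle interpretation. The default six-band CH-stretch
  fixture places oriented methylene stretches at 2850/2921 cm⁻¹ (67°/62°)
  and magic-angle methyl/Fermi bands at 2873/2898/2936/2958 cm⁻¹, noise
  10⁻⁴ AU. Passing the round trip shows the inversion is self-consistent,
  not that the optical model matches a given instrument.
- **Impedance sweeps** invert Z″ = −1/(2πf·C(E)) for a prescribed smooth
  C(E) (parabolic in potential, default minimum 1.44 μF cm⁻², optional
  Gaussian defect peak), 25 Hz, 1 Ω noise.
- **Trajectories** are idealized, not physical: all-trans zig-zag chains
  with exact tetrahedral geometry (C–C 1.54 Å, rise 1.257 Å per carbon,
  explicit hydrogens perpendicular to the chain director) on a square
  lattice in two mirrored leaflets. Tilt magnitudes are redrawn per lipid
  per frame from a reflected Gaussian (default 33° ± 5°, the
  liquid-crystal-phase range); the tilt *direction* is drawn per leaflet
  per frame — chains tilt collectively, as in a gel phase, which also
  keeps neighbouring chains parallel and clash-free — and each chain
  additionally spins uniformly about its own axis so C–H bonds sample the
  azimuth about the director uniformly (this is what makes the analytic
  SCD limits exact on average). The carbon count per chain must be odd so
  the first-to-last carbon vector lies exactly along the director and the
  tilt truth is exact. A rigid hydroxyl probe floats above the membrane
  with per-frame z drawn from a prescribed distribution, and acceptor
  atoms satisfy the default hydrogen-bond geometry on a deterministic
  schedule (default: one always-on bond plus one on every other frame,
  giving the OH group a known fraction of 1.5). Charges and LJ parameters
  are plausible round numbers, not a force field. Consequently, passing
  tests demonstrates the correctness of the observable code on geometry
  with known ground truth — not membrane physics, solvation, or realistic
  electrostatics.

## Problem sizes

Defaults were chosen so the full validation suite runs in seconds on one
core: 8 lipids per leaflet, 9 carbons per chain, 100–300 frames for
distribution recovery, 1500–2000 frames for the Monte-Carlo SCD limits,
and ≤ 500-atom systems for the brute-force energy cross-checks. All sizes
scale up through the generator parameters.

## Known limitations

- The ATR inversion reports effective angles under uniaxial symmetry; no
  Kramers–Kronig or anisotropic optical-constant modelling.
- Band areas of strongly Lorentzian bands carry finite-window bias (above).
- The transition detector intentionally ignores dips shallower than the
  prominence threshold.
- The energy operation assumes disjoint selections and computes no
  intra-selection or bonded terms.
- Absolute membrane thickness (and hence an absolute thickness change in Å)
  is out of scope for the capacitance model.
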
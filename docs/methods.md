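# Methods

## Model and estimator

The conformational state of a tetrameric helix bundle is reduced to two
reaction coordinates: the Euclidean Cα–Cα distances ζ₁ = |Cα(A) − Cα(C)| and
ζ₂ = |Cα(B) − Cα(D)| between marker residues of the two diagonally opposed
chain pairs. The diagonal pairing is identified as the perfect matching of
the four chains with the largest total inter-marker distance (opposing
chains are farther apart than adjacent ones); if all matchings are
equivalent — a degenerate geometry such as a regular tetrahedron of markers —
a warning is issued and the lexicographic pairing (first+third,
second+fourth chain by ID) is used. Which diagonal is called ζ₁ is a
convention (the one containing the first chain by ID); the exchange symmetry
F(ζ₁, ζ₂) = F(ζ₂, ζ₁) of a symmetric tetramer makes the choice immaterial to
the free-energy surface.

Umbrella sampling restrains the system near chosen reaction-coordinate
values with the 2D harmonic bias

    V(ζ₁, ζ₂) = ½ [ k₁ (ζ₁ − ζ₁⁰)² + k₂ (ζ₂ − ζ₂⁰)² ],

k₁ = k₂ = 3 kcal/mol/Å² by default. Windows are laid out on a square lattice
with 0.5 Å spacing over the domain (8.0, 13.5) Å — 12 points per axis, hence
144 full-grid windows. The domain is chosen so the lattice brackets both the
closed (≈9.6 Å) and open (≈12.5 Å) states; the bounds themselves are a
package default, not a measured quantity.

Three window plans are supported. `full_grid` keeps all n² lattice points.
`symmetric_half` exploits the exchange symmetry: it keeps the strictly-lower
triangle (66 windows for n = 12) plus every second diagonal point (6),
⌊n²/2⌋ = 72 in total, and the upper triangle is recovered by reflection at
analysis time. Exact unordered-pair counting would keep all n(n+1)/2 = 78
representatives; `pair_count=True` selects that variant. `diagonal` keeps
only the n points with ζ₁⁰ = ζ₂⁰, appropriate when the off-diagonal surface
rises steeply and only the symmetric opening profile is needed.

WHAM combines the per-window histograms n_im (shared 0.1 Å bins, bias
evaluated at bin centers) through the self-consistent equations

    p_m ∝ Σᵢ n_im / Σᵢ Nᵢ exp(β(fᵢ − V_im)),
    exp(−β fᵢ) = Σ_m p_m exp(−β V_im),

iterated from fᵢ = 0 with probabilities renormalized every iteration, until
the largest change in any window free energy fᵢ falls below 10⁻⁴ kcal/mol
(max 1000 iterations; non-convergence is flagged, not fatal). All sums are
evaluated with `logsumexp`, so windows restrained high on the surface cannot
underflow. The PMF is −kT ln p, zero-referenced at its sampled minimum;
unsampled bins are masked (NaN), never zero-filled, and excluded from all
searches. With a single zero-strength window the equations collapse to
direct Boltzmann inversion of the histogram — an exact identity used as an
oracle in the tests.

State analysis reads the diagonal profile (sampled bins with
|ζ₁ − ζ₂| < half a bin width): the closed state is the global minimum, the
barrier is the highest interior local maximum between the minimum and the
*declared* open-state coordinate (default 11.5 Å; deliberately a parameter,
not auto-detected), and ΔG_open = F(open) − F(min).

## Synthetic study system

The sampler draws Boltzmann samples from exp(−(F + V)/kT) on analytic model
surfaces at 300 K (k_B = 0.0019872 kcal/mol/K, kT = 0.5961 kcal/mol):

- `harmonic_well` — isotropic paraboloid; per-axis variance kT/k in closed
  form (the equipartition oracle).
- `plateau_barrier` — a closed minimum, an optional barrier, and a flat open
  plateau along the diagonal, assembled from C¹ cubic smoothstep segments,
  plus harmonic confinement transverse to the diagonal (default
  3 kcal/mol/Å²). The diagonal profile, and hence the constructed ΔG_open,
  is known in closed form; smoothsteps rather than splines keep the
  Metropolis inner loop cheap and the exchange symmetry exact.
- `double_well_diagonal` — quartic double well along the diagonal.
- `tabulated_grid` — bilinear interpolation of an arbitrary grid.

Two Metropolis proposal schemes are provided. The default `walk` is a
random walk with isotropic Gaussian steps (default 0.15 Å, mimicking the
small correlated moves of an MD trajectory) and reflecting domain
boundaries; reflection is a symmetric proposal, so the stationary
distribution on the domain is unaffected. Its integrated autocorrelation
time is bounded below by a few steps at any proposal scale (measured 7–15
over steps 0.3–1.5 Å on a biased flat-surface window), which inflates
histogram noise roughly √IACT-fold over independent counts. The `bias`
scheme is an independence sampler: proposals are drawn fresh from the
window's own bias Gaussian, truncated to the domain, and accepted with
probability min(1, exp(−βΔF_surface)) — both the bias and the truncation
constant cancel from the Metropolis ratio. On a flat surface every proposal
is accepted and the frames are exactly independent; this is the scheme to
use whenever an error budget (e.g. a Poisson/binomial noise bound on
histogram counts) presupposes independent samples. On steep surfaces its
acceptance drops and the local `walk` scheme mixes better; the PMF-recovery
runs on the plateau surface therefore use `walk` with a 0.5 Å step, of
order the window width √(kT/k) ≈ 0.45 Å — the standard proposal-scaling
choice for random-walk Metropolis.

Per-window trajectories are 50,000 steps in the recovery experiments — a
statistical-power choice, since the sampler has no physical clock — with the
first 20% discarded as burn-in. Per-window seeds derive deterministically
from the master seed, so a whole umbrella campaign is bit-reproducible.

The pore-occupancy generator emulates per-frame water z-coordinates: each
1 Å slice receives a Poisson count with mean ρ·π r(z)²·1 Å and uniform
positions, and an optional dewetting zone flips between bulk-like and empty
as one collective unit with a per-frame switching probability (symmetric
switching ⇒ stationary occupancy ½ regardless of the initial state, which
is configurable). The hydration module closes the loop: its density profile
divides the mean slice count by the cylinder volume π r_ref²·1 Å with the
radius fixed at the reference (T112-equivalent) position for every slice —
the pore is not cylindrical, but this is the stated volume convention — and
slices below 0.5× bulk density (threshold a package default; the phenomenon
is qualitative) merge into dewetted intervals. Bulk water density is
0.03343 molecules/Å³, computed from first principles as
ρ[g/ml]·N_A/M_water with M_water = 18.0153 g/mol at 1.000 g/ml; the
conversion g/ml = ρ·M/N_A·10²⁴ is exactly invertible. (Printed constants of
the form "0.003345 molecules/Å³ ≈ 1.3 g/ml" that circulate for this kind of
analysis are off by a factor of ten from the physical conversion; the
package uses only the first-principles value.)

The toy 4-chain bundles place chains A/C on the x axis at ±ζ₁/2 and B/D on
the y axis at ±ζ₂/2, markers exactly in the z = 0 plane, each chain a short
glycine pseudo-helix whose non-marker atoms are decorative. Structure
interpolation translates each chain rigidly: a linear guess along the
chain's closed→open displacement, then an exact in-plane correction along
the marker-pair separation (projected onto the plane normal to the pore
axis — the line through the marker centroid perpendicular to the markers'
best-fit plane) that pins each diagonal distance to its target; intra-chain
geometry is untouched by construction.

The non-polar solvent starts from rigid SPC water (O −0.82 e, H +0.41 e,
r_OH = 1.0 Å, ∠HOH = 109.47°, σ_O = 3.166 Å, ε_O = 0.1554 kcal/mol; computed
dipole 2.27 D). The oxygen ε is replaced by an aliphatic-carbon well depth —
a configuration input with a documented stand-in default of 0.12 kcal/mol,
a typical lipid-tail carbon value — and the dipole is reduced by uniformly
scaling all charges: the unique linear, geometry-preserving realization,
which conserves neutrality exactly and scales the dipole by exactly the
charge factor.

## What the synthetic data does and does not show

The synthetic surfaces are two-dimensional by construction: the sampler
*is* the model. Passing recovery tests therefore demonstrates that the
umbrella/WHAM/projection/state-analysis chain is a correct estimator of a
known F(ζ₁, ζ₂) at realistic force constants, window spacings and sample
sizes — not that a real bundle's free energies are reproduced. Real MD adds
orthogonal slow degrees of freedom, correlated frames with a physical
timescale, force-field error and anharmonic coupling between the reaction
coordinates and the environment; none of these is emulated. Headline
free-energy values (e.g. the 5.3 kcal/mol opening cost used throughout the
examples and tests) enter only as construction parameters of the reference
surfaces.

## Numerical choices and edge cases

- WHAM tolerance 10⁻⁴ kcal/mol on max|Δfᵢ|; fᵢ initialized to zero (no
  special initial values needed); the well-conditioned 12-window flat
  problem converges in ~55 iterations.
- Windows whose sampled bins share no bin with the rest of the set raise a
  disconnected-windows error before iteration.
- Histogram frames outside the domain are counted and reported per window,
  never silently dropped.
- Symmetrization averages mirror bins where both are sampled, copies the
  sampled one where only one is, re-zeroes the minimum; it is idempotent.
- Degenerate interpolation (endpoints sharing a diagonal distance but a
  different target requested) is an error; coordinate comparisons use a
  10⁻⁶ Å tolerance because PDB-derived coordinates are float32.
- The chi-square uniformity test of the flat-surface sampler thins the
  chain (every 10th frame at a 3 Å proposal step) so the counted samples
  are effectively independent, as the test statistic requires.
- `locate_states` on a monotone segment reports no barrier; noise-level
  local maxima on a flat plateau can register as a shallow "barrier", so
  barrier heights near the noise floor (≲ 0.1 kcal/mol above the plateau)
  are not meaningful.

## Limitations

- 2D reaction coordinates only; no MBAR/TRAM estimators and no bootstrap
  uncertainty bands (the convergence trace is the only diagnostic).
- The hydration volume convention uses one fixed radius for all slices.
- The symmetric-half plan's ⌊n²/2⌋ window count follows the halving
  convention rather than exact unordered-pair counting (78 for n = 12);
  both are available, and under the exchange reflection both cover the full
  grid.
- No MD engine integration: the solvent parameter table is tool-agnostic
  text, and sampling real systems is out of scope.
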
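# porepmf

Free-energy analysis of ion-channel helix-bundle opening by 2D umbrella
sampling and WHAM, with pore-hydration profiling and a non-polar model-solvent
parameterization — exercised end-to-end on synthetic Boltzmann samplers that
stand in for all-atom MD.

## The problem

Tetrameric K⁺-channel pores such as KcsA gate at a hydrophobic *bundle
crossing*: four pore-lining M2 helices converge near the intracellular
membrane face, and the closed (associated) and open (dissociated) bundle
conformations are separated by a free-energy difference of a few kcal/mol.
The conformational state is summarized by two reaction coordinates — the
Cα–Cα distances ζ₁ and ζ₂ between the marker glycines (G116-equivalent) of
the two *diagonally opposed* chain pairs across the pore. A closed bundle
sits near (9.6, 9.6) Å; an open, water-filled one near 11.5–12.5 Å.

`porepmf` implements the analysis layer of such a study as a reusable
library:

- **umbrella windows** — the 2D harmonic bias
  V(ζ₁, ζ₂) = ½[k₁(ζ₁−ζ₁⁰)² + k₂(ζ₂−ζ₂⁰)²], with k = 3 kcal/mol/Å² and
  windows every 0.5 Å (144 full grid / 72 after exchange-symmetry halving /
  12 diagonal-only);
- **WHAM** — self-consistent unbiasing of the window histograms into a 2D
  potential of mean force F(ζ₁, ζ₂) = −kT ln p(ζ₁, ζ₂), with convergence
  monitoring, optional symmetrization, projection onto the symmetric-opening
  diagonal ζ₁ = ζ₂, and extraction of the closed minimum, barrier and
  opening free energy ΔG;
- **structures** — reading 4-chain PDB bundles, extracting (ζ₁, ζ₂) from
  marker-Cα geometry, and generating intermediate structures along the
  opening pathway by rigid-body radial interpolation;
- **hydration** — water number-density profiles in 1 Å slices along the pore
  axis (cylinder volume fixed at the reference pore radius) and
  classification of wetted/dewetted intervals, the signature of hydrophobic
  gating;
- **solvent model** — SPC water with an aliphatic-carbon Lennard-Jones well
  depth and a dipole halved by uniform charge scaling: a non-polar,
  water-shaped probe of the hydrophobic contribution;
- **synthetic system** — analytic model free-energy surfaces, a seeded
  Metropolis sampler of exp(−(F+V)/kT), pore-occupancy series with two-state
  wetting flicker, and toy 4-chain bundles with exact marker geometry, so
  every stage is testable with no external data.

## Worked example

`examples/02_wham_pmf.py` samples 12 diagonal umbrella windows
(50,000 Metropolis steps each, k = 3 kcal/mol/Å², 300 K) on a constructed
opening surface whose closed minimum sits at 9.5 Å and whose open plateau
lies 5.3 kcal/mol higher, then unbiases and analyzes them:

```text
WHAM converged in 256 iterations (tolerance 0.0001 kcal/mol on max |df_i|)
closed-state minimum : 9.45 A
delta-G of opening   : 5.47 kcal/mol at 11.5 A (constructed: 5.30)
RMS recovery error   : 0.059 kcal/mol over 55 diagonal bins
```

The recovered minimum is the constructed closed state (nearest 0.1 Å bin
center), the opening free energy read at the declared open coordinate
11.5 Å reproduces the constructed 5.3 kcal/mol to within the sampling noise,
and the pointwise RMS error against the analytic surface is well below kT.
The other scripts in `examples/` cover window planning and single-window
statistics, structure interpolation, hydration profiling, the non-polar
solvent, and the full config-driven pipeline (`pore-pmf run --config
run.yaml` on the command line).

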
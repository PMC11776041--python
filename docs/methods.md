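# Methods

This note documents the models, parameter choices and known limits of
`modetrap`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Elastic network model and normal modes

A structure is reduced to point nodes (all heavy atoms by default, or the
Cα trace under the `calpha-*` presets) joined by harmonic springs. Two
spring rules are provided:

* `inverse-power` (default): every node pair within `rc = 10 Å` gets a
  spring with `k = c/d²` (`c = 1`). Distance weighting makes the spectrum
  insensitive to the exact cutoff, and the model is parameter-free in the
  sense that relative eigenvalues are what matter — ENM spectra are
  meaningful only up to a global scale.
* `cutoff`: uniform `k` inside `rc` (the classic anisotropic network
  model), kept for comparison and for analytic fixtures.

The Hessian is assembled from the standard pairwise super-elements
(`±k·u uᵀ` blocks with `u` the unit bond vector) and fully diagonalized
(`scipy.linalg.eigh`). Trivial modes are counted as eigenvalues below
`1e-8 ×` the largest eigenvalue — a relative threshold, so it is robust to
the model's arbitrary energy scale. A connected, non-linear network has
exactly six; a linear (collinear) network has seven, because the two
bending modes of a *central-force* network carry no harmonic restoring
force — the linear-triatomic fixture documents this with its closed-form
spectrum (zeros ×7, then `k` and `3k` for unit masses). Eigenvector signs
are fixed (largest-magnitude component positive) so that direction labels
downstream are reproducible; mass weighting is off by default, as is
conventional for ENMs.

## Displacement

`R_d = R + λ·v`, with `v` the unit-norm (possibly multi-mode) combination
and one scaling factor `λ` for the whole combination. λ is solved exactly
against one of three amplitude conventions: `rms-all-atom` (default),
`rms-calpha`, `max-atom`. The conventions differ precisely when the mode
is spatially concentrated (the interesting, hinge-like case), and
published displaced-structure RMSDs depend on which atom set the authors
used; the switch exists so users can probe that rather than inherit a
hidden choice. Displacement is linear, so + and − conformers are exactly
equidistant from the input, and projection of any conformer difference
onto the orthonormal mode basis recovers coefficients exactly
(machine-precision identities asserted in the tests).

## Restrained relaxation

Linear displacement distorts local geometry, so before design the
conformer is brought to a nearby minimum of

```
E(x) = w_b Σ_bonds (d − d_ref)² + w_c Σ_{d<r_clash} (d − r_clash)²
       + w_r Σ_atoms |x − x_anchor|²
```

with bonds inferred from the original structure (covalent radii + 0.4 Å
slack, plus consecutive same-chain Cα pairs < 4.2 Å so bare Cα traces get
a chain topology; overlapping pairs < 0.5 Å are treated as clashes, not
bonds). Defaults: `w_b = 1`, `w_c = 1`, `w_r = 0.1`, `r_clash = 2.8 Å`,
gradient tolerance `1e-4`. Minimization is steepest descent with Armijo
backtracking, so the energy trace is non-increasing by construction; the
anchor is the displaced geometry, and the result reports (never assumes)
whether it stayed closer to the displaced than to the original
coordinates. In the `w_r → ∞` limit the output converges to the anchor;
the minimizer is rotation-equivariant. This stage plays the role a
full-atom relaxation protocol plays in heavier pipelines: its contract
here is only "a local minimum near `R_d`", which this transparent model
fulfils verifiably.

## Contact energy and the shipped matrix

`U(R|M) = Σ_{i<j} ε(a_i,a_j)·w(d_ij) + Σ_i μ(a_i)` over residue
representative atoms (Cβ with Cα fallback; cutoff 6.5 Å with a 1 Å cosine
switch by default). The shipped 20×20 matrix
(`data/contact_hydrophobic_synthetic.txt`) is a **synthetic** rank-two
statistical potential constructed from the Kyte–Doolittle hydropathy
scale and formal side-chain charges:

```
ε(a,b) = −hw·φ_a φ_b + cw·q_a q_b ,   μ(a) = bc·φ_a
φ_a = (KD_a/4.5 + 1)/2 ∈ [0,1],  defaults hw=1.0, cw=0.5, bc=0.6
```

so hydrophobic burial and salt bridges attract, like charges repel, and
exposed hydrophobics pay a reference cost. It is *not* a
knowledge-based matrix derived from structural statistics; any user
matrix in the same whitespace-delimited format (header row of one-letter
codes, optional `REF` row) can be loaded instead, and
`build_rank2_contact_model` exposes the weights. Energies are in
dimensionless model units throughout.

## Monte Carlo design

Single-position substitution proposals (uniform over the 19 alternatives),
Metropolis acceptance over a staged temperature schedule, incremental ΔU
over precomputed neighbor lists (exact whenever the 10 Å neighbor radius
is at least the contact cutoff — the per-move re-evaluation radius is the
coarse-grained analogue of repacking side chains within 10 Å of a
mutation), best-so-far tracking, and a final deterministic greedy quench
from the best state. The quench makes degenerate cases reproducible: ties
resolve to the lexicographically first letter. Because the wild type is
always reachable, the defining inequality `U(target|M_eng) ≤
U(target|M_wt)` holds for every run by construction; the suite verifies
100% over 20 seeds. "Two designs per conformer" is realized as two seeds.

### Trap / smoothing classification

The two design outcomes are separated by configurable inequalities on the
four energies (see README). The boundary conditions are an adopted
interpretation of "deeper displaced minimum" vs. "leveled landscape", with
a tolerance `tol` for "level"; `tol` defaults to 0.5 model units and must
be scaled with the energy model in use (the toy model at `scale = 0.04`
calls for `tol ≈ 0.05`). Classification uses the sequence-dependent
contact energy only; the backbone elastic term is sequence-independent, so
it cancels in engineered-vs-wild-type comparisons at fixed conformation,
but it does contribute to the depth of a displaced basin — the sampler
(which includes it) is the arbiter of actual dynamics.

## Synthetic systems

`make_helix` — ideal α-helix Cα trace (rise 1.5 Å, 100°/residue, radius
2.3 Å), the geometry and connectivity fixture.

`make_two_domain` — the desk-scale hinge protein: two compact Cα lattice
clusters (spacing 3.8 Å) bridged below an open cleft by two y-offset,
z-zigzag linker strands (the zigzag prevents collinear-neighbor floppy
modes, keeping the zero-mode count at six). One probe bead per domain
leans into the cleft on a short stalk, with the resting probe separation
kept just above the ENM cutoff so the probes never get a direct spring
across the very hinge they report on. The in-plane scissor motion is the
softest genuine mode; construction verifies this by projecting the
probe-separation direction onto modes 7–12 and records the sensitivities.
The cleft width adapts to the linker length (longer linkers brace a wider
cleft); with fewer than four linker beads the network stays connected with
six zero modes, but hinge dominance of mode 7 is only guaranteed for
linkers of four beads or more. Wild-type letters cycle through neutral
polar residues (no formal charges, no strong hydrophobics) except the two
cleft faces, which are leucines — giving the wild type a genuine, mildly
populated closed state, the analogue of a bimodal cleft coordinate.
`jitter` adds seeded Gaussian coordinate noise (0.35 Å in the validation
family) to generate structurally distinct systems.

`toy_contact_model` re-weights the rank-two potential for Cα beads:
cutoff 6.5 Å/1.5 Å switch, charge weight 1.2, burial cost 1.5, overall
scale 0.04. The burial cost is set high enough that a sparsely contacted
cleft probe genuinely prefers a polar identity when it touches nothing —
the regime where redesigning a cleft face can either create a salt bridge
across it (closed-state design) or armor it with like charges (open-state
design). The scale converts one contact into a few sampler kT, keeping
both basins thermally accessible.

## Mode-space sampler

Metropolis in the coefficients of modes (7, 8, 9) with isotropic Gaussian
proposals (σ = 1.5 Å), kT = 0.01 model units, energy
`½Σκ_k c_k² + U(x(c)|M)`. The sampler is the desk-scale replacement for
molecular dynamics: the trap/smoothing predictions are claims about
equilibrium conformational *populations*, testable in any correct
equilibrium sampler over the same energy. On a pure harmonic landscape it
reproduces the exact Gaussian (KS < 0.02 at 10⁵ steps) and equipartition
`var(c_k) = kT/κ_k` within 10% at 2×10⁵ steps (measured ≈ 1–2%). What it
deliberately omits relative to MD: solvent, inertia and time scales,
anharmonic backbone couplings outside the mode subspace, and side-chain
degrees of freedom. Passing its tests therefore demonstrates the *logic*
of landscape-trap design — sequence changes reshape equilibrium
populations along the target mode in the intended direction — not force
field realism.

## Validation experiment sizes

The directional-shift experiment uses five jittered two-domain systems
(12 beads/domain, 8 linker beads), displacement amplitude 3 Å for the
design template, cleft-face-only design (the interface-redesign setting;
whole-protein design is exercised separately by the trap-inequality test),
and 30 000 sampler steps per sequence (1 400 frames after burn-in and
thinning). These sizes give rank-sum p-values many orders of magnitude
below the 10⁻³ criterion while keeping the whole suite inside a few
minutes. The acceptance script runs the same experiment seeded from its
`--seed` argument.

## Numerical choices and degenerate inputs

* Trivial-mode threshold `1e-8 × λ_max`; orthonormality asserted to 1e-8.
* Altloc → first conformer; hydrogens/waters/HETATM excluded on read;
  author residue numbering preserved, insertion codes part of residue
  identity.
* PDB coordinates quantized to 3 decimals exactly once (write→read→write
  is byte-stable).
* RMSF superposition: two-pass mean structure, seeded from frame 0 so the
  result is invariant under arbitrary per-frame rigid motions.
* Mann–Whitney U: exact enumeration when min(n,m) ≤ 8 with no ties,
  otherwise normal approximation with tie and continuity corrections
  (delegated to `scipy.stats.mannwhitneyu` under exactly this rule).
* KDE peaks: Silverman bandwidth by default, 512-point grid over the data
  range ± 3 bandwidths, prominence floor 5% of the maximum density;
  an all-equal series degenerates to a single peak at that value.
* Ties in greedy/argmin contexts: lexicographic by one-letter code.
* Coincident atoms (< 0.5 Å) are never inferred as bonds; the minimizer
  jitters them once (0.01 Å, seeded) if the energy is non-finite.

## Limitations

* The contact potential is a two-parameter synthetic model; mutation
  *identities* it proposes (e.g. R/D salt bridges at a cleft) are
  illustrative, and only the *patterns* — conformation-specific vs.
  globally convergent substitutions, directional population shifts — are
  meaningful claims.
* Linear mode displacement distorts geometry at large λ; the restrained
  minimizer repairs local geometry but curvilinear displacement schemes
  are out of scope.
* The classification tolerance couples to the energy model's scale and
  must be chosen with it.
* Real-protein workflows (crystal structure in, MD trajectories in via
  the multi-model PDB reader or the mdtraj adapter) use exactly the same
  code paths, but the shipped validation is entirely desk-scale and
  synthetic.
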
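# Methods

## Model class and assumptions

`synchropat` analyzes ODE models of a homogeneous cell array in which

- each cell is a well-mixed compartment described by s chemical
  concentrations (s ∈ {1, 2} for the classifiers; arbitrary s for
  spectrum assembly and simulation);
- all cells obey the *same* smooth rate function f(u, v̄, λ) of their
  own state u and a symmetric function of their input-cells' states
  (admissibility) — the package enforces the symmetry structurally by
  accepting only the arrow-weighted *sum* of input states;
- the communication network is regular (equal in-degree ν), has no
  self-arrows, and for classification is strongly connected with a
  real adjacency spectrum (symmetric adjacency tables always qualify;
  a non-real spectrum is detected and refused, not approximated);
- the bifurcation parameter λ varies slowly compared to the state
  (quasistatic ramp), so the tissue tracks the synchronous equilibrium
  until it loses stability, and the first crossing decides the pattern.

Under these assumptions the Jacobian at a synchronous point decomposes
into the reduced matrices Q + μᵢR over the adjacency eigenvalues μᵢ,
and the first bifurcation is classified from the root locations of
p₁(μ) = tr Q + μ tr R and (when det R = 0) p₂(μ) = det Q + μB,
B = tr Q tr R − tr(QR).  The classifier encodes the full fifteen-case
enumeration as the cross product of root-location categories of the
two lines (nowhere / at μ₁ / at μₖ / identically); rows beyond the
first four are reported with `degenerate=True` and matched by exact
sign conditions only — the package does not attempt to quantify "how
degenerate" an instance is.  Nondegeneracy is certified either by the
valence inequalities (det Q > |νB| excludes real crossings;
tr Q < −|ν tr R| excludes Hopf pairs) or by direct numeric evaluation
of the other line's values; the result notes say which was used.

## Key tunable parameters

| parameter | default | meaning |
|---|---|---|
| `cluster_tol` | 1e-8 (relative to spectral radius) | merging adjacency eigenvalues into clusters with multiplicities; near-integer eigenvalues of integer tables are snapped to integers (1e-6) first, so exact lattice spectra do not split |
| criticality tolerance | 1e-7 · max(1, ρ(Q + μₖR)) | band within which an eigenvalue real part counts as zero; bifurcation points are only ever located to finite precision |
| `vec_tol` (eigenvector → coloring) | 1e-6 (relative) | entries closer than this share a color; unbalanced candidate colorings are repaired by partition refinement and flagged |
| continuation grid / refinement | 200 points, bisection to 1e-9 | first-crossing location; the fixtures are smooth and cheap |
| finite-difference step | 1e-6 · (1 + \|x\|), central | Q, R on the synchronous branch when analytic blocks are absent; admissibility lets us difference the single-cell rate only |
| ramp rate | 1e-3 · (λ range) per unit time | quasistatic default; an explicit knob because "slow enough" is model-dependent |
| integrator | LSODA, rtol 1e-7/1e-8, atol 1e-9/1e-10 | stiff-capable adaptive integration |

## Built-in models

`delta_notch` (alias `collier`) is a two-species lateral-inhibition
model carrying the canonical Notch sign structure: Delta decays and is
Hill-inhibited by Notch within the cell; Notch decays and is
Hill-activated by neighbour-averaged Delta, with λ scaling the
activation strength.  Hill exponents default to 2 and both thresholds
to 0.5, the scale of the synchronous equilibrium — chosen once as
biologically unremarkable saturating kinetics.  The theory depends
only on the sign structure (Q upper-triangular with negative diagonal
and negative (1,2) entry; R a single positive (2,1) entry; hence
det R = 0, tr R = 0, B > 0), so any model in this sign class makes the
same prediction.  Neighbour input is the arrow-weighted sum divided by
the valence (cells average the ligand they see); the linear
`example1` fixture overrides this with a raw sum to reproduce its
textbook equations literally, and `cross_coupling` / `single_chem`
provide linear cross-chemical and one-species lateral-inhibition
variants.

## Simulation protocol and what it shows

`run_pattern_experiment` starts at the synchronous equilibrium of the
ramp's start, adds a single uniform perturbation of amplitude 1e-3
drawn from a seeded generator (`numpy.random.default_rng(seed)`, so
identical seeds give bitwise-identical perturbations), ramps λ
linearly, then holds at the final λ until the state is stationary
*and* the deviation amplitude has stopped changing.  The second
condition matters: just past the crossing the synchronous equilibrium
is still a stationary point, only unstable, and a decayed perturbation
needs time to regrow before the pattern can be scored.  The hold loop
therefore refuses to stop at a near-synchronous state unless the
synchronous branch is linearly stable at the final λ (or the run was
noiseless, in which case the invariant subspace argument applies
exactly).

Because the dynamics are deterministic between the single noise
injection and the crossing, a sweep started far below the crossing
lets the perturbation decay exponentially toward the solver's noise
floor before it can seed the pattern.  The bundled experiments
therefore use ramp windows that bracket the predicted crossing (the
6-cell line: 0 → 1.3 across λ₀ ≈ 1.0; the 16×16 torus: 2.5 → 2.85
across λ₀ ≈ 2.705).  This is the faithful deterministic surrogate for
slow passage with persistent small noise; with sustained stochastic
forcing the window would not matter.

Patterns are scored spectrally: the final deviation from the tissue
mean is decomposed over the adjacency eigenspaces, and for symmetric
adjacency tables the projection fractions sum to one (the
decomposition is orthogonal).  For non-symmetric tables (the 6-cell
line) the fractions remain a useful dominance score but are not an
orthogonal partition.  The matched coloring is derived from the
deviation of the most-deviating species at a 10% relative tolerance
and repaired to the coarsest balanced refinement; a deviation below
1e-8 of the state scale is reported as the monochrome (no-pattern)
coloring.

### What the synthetic fixtures do and do not show

The generators emulate the study conditions: clean lattices, identical
cells, a single slowly ramped parameter, one small perturbation.  They
do not model cell-to-cell parameter heterogeneity, sustained noise,
growth or rearrangement of the lattice, delays, or morphogen
gradients.  Passing tests therefore demonstrate the internal
consistency of prediction and simulation under the stated assumptions,
not robustness of real tissues to their violation.

## Inverse analysis

`infer_signs` enumerates all sign assignments to unknown entries of
the (Q, R) skeleton, keeps assignments for which some numeric
instantiation (200 draws with magnitudes in [0.1, 3]) jointly
satisfies synchronous-branch stability and the observed outcome's
necessary conditions, and intersects the survivors.  Monte Carlo
satisfiability is adequate here because all conditions are open sign
conditions (strict inequalities) or structural zeros; no thin
feasibility region exists.  Degenerate (multi-eigenvalue) crossings
are excluded by default — they are unlikely in biological systems —
and `include_degenerate=True` restores the first-order degenerate
cases (simultaneous or mixed extreme-eigenvalue crossings), which
weakens the conclusions; the deeper identically-degenerate cases
(p₁ ≡ 0 or p₂ ≡ 0) are not offered as observable outcomes.  Forced
conclusions are reported as entry signs, and as pairwise product signs
(x·y > 0, sgn(x) ≠ sgn(y)) between entries whose individual signs stay
free.  When several balanced colorings intersect a multi-dimensional
critical eigenspace one-dimensionally, the search prefers fewer colors
(ties broken lexicographically) and reports that a repair occurred
rather than silently guessing.

## Numerical design decisions

- Eigenspaces and generalized eigenspaces are computed as
  rank-revealing kernels of (A − μI) and its powers (up to the
  algebraic multiplicity), not via Jordan-form routines: numerically
  safer, and all worked networks are diagonalizable.  Eigenvectors are
  normalized to unit norm with the first significantly-nonzero
  component positive so integer textbook vectors compare after
  rescaling.
- Equality of the reduced-matrix spectrum with the dense Jacobian
  spectrum is asserted as backward error (σ_min(J − wI) ≤ 1e-8·‖J‖ per
  reduced eigenvalue, plus exact count and trace): a dense eigensolve
  of a non-normal matrix with repeated eigenvalues is itself only
  accurate to about the square root of machine precision, so a naive
  multiset comparison at 1e-8 would test the oracle, not the claim.
- Complex adjacency eigenvalues are ordered by real part with ties
  broken by imaginary part; nothing downstream depends on the tie
  rule because classifiers refuse non-real spectra outright.
- Networks violating the no-self-arrow or strong-connectivity
  assumptions are refused by classifiers with a diagnostic naming the
  violated assumption; spectrum assembly still works for them (the
  three-cell worked example has a self-arrow and is accepted through
  an explicit permissive flag).
- The torus builder assigns weight 3 to the nearest-neighbour shell
  and weight 1 to the diagonal shell; this is the assignment under
  which the minimal adjacency eigenvalue (−8 at valence 16) is simple
  with a checkerboard eigenvector — the swapped assignment produces a
  multiplicity-2 stripe mode instead, which the test suite records.

## Known limitations

- Classification covers s ∈ {1, 2} node dimensions; the two-species
  det R ≠ 0 case is bounded (extreme-eigenspace restriction for
  det R ≤ 0) but not enumerated.
- The package locates and classifies the *first* bifurcation only; it
  does not continue the patterned branch, compute normal forms, or
  analyze secondary bifurcations.
- Constructing an admissible ODE realizing an arbitrary prescribed
  interior pattern space is an existence fact the package relies on in
  the inverse direction but does not implement.
- Long-range coupling kernels beyond the two bundled shells can be
  assembled by hand from the adjacency table, but no builder or test
  covers them.
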
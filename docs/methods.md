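# Methods

## Model

A protein conformation is coarse-grained to its ordered Cα positions
(internal unit nm).  The protein graph (PG) is simple, undirected,
unit-weighted and connected: backbone edges (i, i+1) are always present;
contact edges join residues with |i−j| ≥ 2 whose Cα distance is *strictly*
below the cutoff R (default 0.6 nm, the first-neighbor peak of Cα pair
distances in folded structures).  The strictness of the inequality matters
only for measure-zero geometries and is configurable in spirit by adjusting
R.

A connected graph on n vertices is mechanically equivalent to a linear
chain of n equal masses coupled by identical springs according to the
adjacency matrix: the graph Laplacian is the force-constant matrix up to a
constant, its eigenvalues λ_l (sorted ascending, λ_1 = 0) are squared
normal-mode frequencies in units of c/m, and equipartition turns
mean-square thermal fluctuations into dimensionless stiffnesses:

* local: 1/k_i = Σ_{l≥2} e_l(i)²/λ_l = L⁺_ii
* nonlocal: 1/K_ij = Σ_{l≥2} (e_l(i) − e_l(j))²/λ_l = Ω_ij (Randić
  resistance, from the Moore–Penrose pseudoinverse L⁺)
* global: 1/K = Σ_{l≥2} 1/λ_l = Kf (Kirchhoff index) = tr L⁺

The temperature/spring-constant scale γ = k_BT/c is absorbed throughout;
no dimensional force constants are exposed (no consumer in this package
needs them).  Three sum rules tie the constants together and are enforced
as tests at 1e−8 absolute tolerance on random connected graphs:

    1/K = (1/2n) Σ_i Σ_{j≠i} 1/K_ij = Σ_i 1/k_i,
    1/k_i = (1/n)(Σ_j 1/K_ij − 1/K).

Note that eliminating the double sum with the ordered-pair mean resistance
⟨Ω⟩ gives Kf = (n−1)⟨Ω⟩/2.  A factor (n−1)⟨Ω⟩/4 is sometimes quoted for
this relation; that form is consistent only with an unordered-pair mean
taken over n(n−1)/2 pairs combined with an extra factor of two, and does
not follow from the sum rule above.  The exact double-sum identity is what
is implemented and tested; the /2 form is the one the implementation
satisfies.

Shortest paths are edge counts (PG adjacency is binary) computed by
breadth-first search per source; a Dijkstra route exists for weighted
graphs but is unused for PGs.  The Wiener index is the ordered-pair double
sum, and ⟨l0⟩ = Wiener/(n(n−1)).

## Closed forms and the (K, ⟨l0⟩) envelope

The PG of a fully extended chain is the path graph, with spectrum
λ_l = 4 sin²((l−1)π/2n), hence 1/K = (n²−1)/6 and ⟨l0⟩ = (n+1)/3 — the
soft/long extreme over all PGs of length n (any contact only stiffens the
graph and shortens paths; Rayleigh monotonicity, asserted as a property
test under random edge addition).  The complete graph is the opposite
extreme: 1/K = 1 − 1/n, ⟨l0⟩ = 1.  Eliminating n between the two
path-graph formulas yields

    1/K = ⟨l0⟩ (3⟨l0⟩ − 2) / 2,

implemented in `K_from_l0`.  The printed form of this relation is
typographically ambiguous in places; the polynomial above is the unique
one consistent with the two generating formulas (check: n = 20 gives
1/K = 66.5 = (400−1)/6 at ⟨l0⟩ = 7).  Applied to arbitrary conformations
the curve is an upper limit for K at given ⟨l0⟩.

The (n, j) model chains — backbone plus contacts at the single stride j,
*not* all strides up to j — realize that upper boundary: a (20, j) chain
mimics a completely unfolded chain of ≈ 20/j residues.  Tests pin
(20, 2) to within 10% of the half-length chain value 6/(10²−1) and the
j ≥ 3 family to within 10% (relative, on 1/K) of the envelope curve.  The
j = 2 point sits ~15% off the curve — the finite-size corrections of its
effective 10-residue chain are still visible — which is why it is tested
against the half-length chain rather than the curve.

## Einstein model

Each vertex is an independent harmonic oscillator with reduced frequency
z_i ∝ √k_i.  Per-vertex quantum internal energy (z/2)coth(z/2) (in k_BT,
ground state excluded) and entropy z/(e^z−1) − ln(1−e^{−z}) (in k_B) are
provided with their classical limits (1 and 1 − ln z; verified at relative
error < 1e−6 for z = 1e−4).  In the classical limit the free-energy
difference between two conformations of the same chain reduces to

    ΔF = (ϵ/2) Σ_i (d_i − d_i⁰)  +  entropic term,

with the entropic (−TΔS, k_BT units) term per model:

* local       (1/2) Σ_i ln(k_i/k_i⁰)
* nonlocal    (1/4) Σ_{i≠j} ln(K_ij/K_ij⁰)
* global      (1/2) ln(K/K⁰)
* collective  (1/2) Σ_{l≥2} ln(λ_l/λ_l⁰)

Interpretation choices, made once and recorded here:

* The 1/2 prefactor applies to *both* the degree term and the log term —
  the only reading consistent with the per-vertex classical free energy
  ΔE_i − (k_BT/2) ln(k_i⁰/k_i).
* The nonlocal double product runs over ordered pairs, hence the extra 1/2
  (1/4 total); this is forced by requiring ΔF(A, A) = 0 and consistency
  with the ordered-pair sum-rule convention used throughout.
* The enthalpic term realizes a potential-energy minimum proportional to
  contact count, each edge split between its two vertices:
  ΔE_i = (ϵ/2)(d_i − d_i⁰).  ϵ < 0 (an edge lowers the energy) is a free
  energy scale; no attempt is made to calibrate it, default ϵ = 0 (purely
  entropic), with −1, −3, −5 as conventional illustration values in the
  CLI.
* The reported "entropic" term is the entropic free energy (−TΔS): it is
  positive when the target is stiffer than the reference, e.g. for folded
  frames referenced to a native structure.

Properties enforced by tests: antisymmetry under exchanging target and
reference, exact ϵ-linearity, zero at identity, and nonnegative entropic
terms for all four models when edges are only added (stiffening).

## Trajectory pipeline

Per frame: PG → descriptor set → ξ (|snapshot ∩ native| / |native|,
counting contacts only, never backbone edges) → four ΔF records per ϵ.
The native reference defaults to model 1 of the supplied reference file.
Frames with ξ ≥ 0.6 are folded, the rest unfolded; state means, Pearson
correlations and 2D probability densities (25 bins per axis by default,
density normalized to unit integral) are always computed from the raw
per-frame series.  The moving mean (display only) is centered and
truncated at the edges, window specified in frames — users convert a time
window via their trajectory timestep, which keeps the operation
format-agnostic.

## Synthetic structures: what they emulate, and what they do not

The generators provide controllable contact topology, not physics: no
dihedral statistics, no excluded volume beyond a hard minimum separation,
no solvent.  Defaults are fixed once:

* extended chain — 0.38 nm Cα spacing (trans peptide); PG = path graph
  exactly, since the second neighbor sits at 0.76 nm.
* helix — rise 0.14 nm, radius 0.28 nm, twist 100°/residue: an idealized,
  slightly compressed alpha helix chosen so that exactly the classic
  helical offsets, strides 3 and 4, fall under the 0.6 nm cutoff.  (A real
  alpha helix puts stride 4 at ≈ 0.62 nm — just outside — and stride 2
  just inside; the idealized geometry keeps the fixture's contact pattern
  canonical and unambiguous.)
* self-avoiding coil — fixed 0.38 nm bonds, uniformly random directions,
  0.4 nm minimum nonbonded separation, seeded and reproducible; the
  disordered stand-in.  Ensemble mean K falls between the extended-chain
  and helix values.
* model_chain_3d / zipper_unfolding_trajectory — helical geometries with
  exactly j residues per turn, rise 0.75·R/j and radius set so every
  non-stride-j chord clears the cutoff by 20%; both verify the realized
  PG against the abstract (n, j) graph and fail loudly on mismatch.  The
  zipper trajectory unwinds the chain one residue per frame from the
  C-terminus, so each frame's PG is a truncated boundary-family graph.
* interpolated_folding_trajectory — linear coordinate interpolation plus
  seeded Gaussian jitter (frame 0 is exactly the start structure, so
  ξ(0) = 1).

A deliberate limitation worth knowing: linear interpolation passes through
unphysically compressed intermediate geometries that carry simultaneous
short-stride contacts denser than anything a thermal ensemble visits.
Such frames can exceed the 1/K = ⟨l0⟩(3⟨l0⟩ − 2)/2 envelope by tens of
percent, whereas the envelope is respected by realistic ensembles and,
provably within ~6%, by the zipper trajectories (their frames are partial
(n, j) graphs).  The envelope property is therefore asserted on zipper
trajectories (tolerance factor 1.1); the interpolated fixture is used for
order-parameter and state-ordering tests.  Passing tests consequently
demonstrate the machinery and the graph-level regularities, not the
statistics of molecular-dynamics ensembles.

## Numerical choices

* Dense symmetric eigensolver (`scipy.linalg.eigh`); protein-sized graphs
  are far below any need for sparse methods.
* Zero-eigenvalue tolerance |λ| < 1e−9·max(λ): scale-free, robust to a few
  thousand vertices.  λ_1 is clamped to exactly 0; a graph is declared
  disconnected when λ_2 falls below the tolerance, and all force-constant
  code then raises rather than divide by ≈0.  BFS connectivity and the
  spectral criterion are cross-checked in tests.
* Degenerate eigenvalues (complete graphs): no eigenvector tie-breaking —
  every exposed descriptor is basis-invariant within an eigenspace, and
  tests only assert basis-invariant quantities.
* The pseudoinverse is built from the spectral sum and symmetrized exactly;
  it is verified against the SVD route at 1e−9.
* K_ii (self nonlocal constant) is reported as +inf and excluded from all
  sums; Ω_ii = 0.
* The lower bound K ≥ 6/(n²−1) on trajectory frames is exact mathematics
  but holds only to the last ulp in floating point, so bound checks carry
  a 1e−9 relative slack.
* Vertex indexing is 1-based in all interfaces and documentation (residue
  convention), 0-based internally; the mapping is fixed at construction.

## PDB handling

Biopython parses (multi-model) PDB files; only Cα atoms are extracted,
coordinates converted Å → nm.  Policies the file format leaves open are
decided as: first alternate location wins (warning logged), duplicate
residues keep the first occurrence (warning), multi-chain models require
an explicit chain selection, and a residue without a Cα is an error naming
the residue.  The minimal writer emits Cα-only records and round-trips
coordinates to 1e−4 nm (PDB precision).

## Known limitations

* The PG is a topological object: it misses dihedral degrees of freedom,
  solvent, and all-atom contact detail; descriptors quantify graph
  rigidity, not full mechanical response.
* ϵ is uncalibrated; free-energy totals are comparative, not absolute.
* Weighted protein graphs, betweenness/community analysis and plot
  rendering are out of scope; outputs are tables designed for downstream
  plotting.
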
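# Methods

## Model

Each ring is a closed bead–spring chain of N beads of diameter σ (the
unit of length).  All bead pairs, intra- and inter-ring, repel through
the Weeks–Chandler–Andersen potential with amplitude ε set equal to the
thermal energy k_BT (the unit of energy); consecutive beads are bonded
by FENE springs, and every joint carries a bending energy κ(1 − cos θ).
Channel confinement is a purely repulsive cylindrical wall along x: a
bead at radial distance ρ from the axis feels the WCA potential of the
gap D/2 − ρ.  The channel is periodic along x; positions are stored
*unwrapped* at all times and periodicity enters only through
minimum-image pair distances, so the longitudinal span
s = max x − min x is always meaningful.  A sentinel D = ∞ selects free
space (no walls, no periodic box).

Parameters (reduced units; `linkedrings.params.ModelParams`):

| parameter | default | notes |
| --- | --- | --- |
| ε = k_BT | 1 | energy unit; the model convention ties them |
| FENE K, R₀ | 30 ε/σ², 1.5 σ | the standard bead–spring choice whose combination with WCA makes backbone crossings energetically prohibitive, preserving topology |
| κ | 5.4 ε | calibrated, see below |
| m, γ | 1, 1 τ_LJ⁻¹ | conventional bead mass and Langevin friction |
| Δt | 0.005 τ_LJ | τ_LJ = σ√(m/ε) |
| period_x | 4·(2Nσ/π) | far beyond any achievable span |

Integration is velocity Verlet with the Langevin force
−mγv + √(2k_BT mγ/Δt)·ξ evaluated once per step together with the
conservative forces (the same total force closes one step and opens the
next).  Drawing fresh noise in each half-kick instead would halve the
effective temperature; the implemented scheme holds the kinetic
temperature at the target within well under 1%.  With γ = 0 the
integrator is plain symplectic velocity Verlet (energy drift < 10⁻⁴
relative over 10³ steps).  A Verlet neighbor list (0.4 σ skin) is
rebuilt whenever any bead has moved half a skin.  Freshly constructed
idealized states may carry compressed bonds or tight contacts; they are
healed by a short overdamped push-off with a hard per-step displacement
cap before production dynamics (`dynamics.soft_relax`).

### Bending constant and persistence length

Only the persistence length l_p = 5σ is a primitive of the model; the
bending constant is derived from it.  Two conventions exist:

* the **ideal discrete worm-like chain** relation
  ⟨cos θ⟩ = coth(κ/k_BT) − k_BT/κ with l_p = −b/ln⟨cos θ⟩ at bond
  length b ≈ 0.965 σ gives κ ≈ 5.70;
* the **operational** definition — fit a·exp(−s/l_p) to the measured
  bond-orientation correlation ⟨cos θ(s)⟩ of a free self-avoiding chain
  over contour separations 1–10 σ (`calibration.measure_persistence_length`).

The two disagree because excluded volume slows the orientational decay
beyond about one l_p.  The package adopts the operational convention
(it is the one a measurement on the simulated chains actually produces)
with a generalized-least-squares fit: the seed-pooled ⟨cos θ(s)⟩ is
fitted by a·exp(−s/l_p) with each separation weighted by the inverse of
its across-seed standard error.  This matters because the
long-separation correlations fluctuate with the chain's slow modes and
would otherwise dominate the estimator variance (an unweighted fit over
ten 500 τ_LJ windows scatters by ~12% between seed pools; the GLS fit
scatters by ~3%).  The default κ = 5.4 yields l_p = 5.05 ± 0.11 σ under
this estimator.  Equilibration of the calibration chains (2500 τ_LJ)
starts from an ideal-WLC random sample rather than a straight rod: rod
starts leave slow global modes that bias the correlations upward unless
equilibrated for several Rouse times.

## Link catalog

The repertoire is organized by the crossing number n_c and the
decomposition of the minimal diagram into self- and mutual crossings:

| label | family | minimal diagram (self, mutual) | construction |
| --- | --- | --- | --- |
| 2₁², 4₁², 6₁² | torus | (0,2) (0,4) (0,6) | parametric (2, n_c) torus windings |
| 5₁², 6₃², 7₃² | twist-like | (1,4) (2,4) (3,4) | rational 4-plats C(2,k,2) |
| 7₁², 9₁² | one self-crossing | (1,6) (1,8) | rational 4-plats C(2m,1,2) |
| 6₂², 8₂² | other (all-mutual) | (0,6) (0,8) | rational 4-plats C(1,2,k) |

The non-torus entries are geometric plat closures of rational-tangle
twist words built by one template engine (`braidgeom`): lanes along x,
half-turn helices for twist regions, end caps and nested return frames
that provably add no crossings in the canonical projection.  The
canonical projection of each ideal embedding is therefore a **reduced
alternating diagram**, which by the Tait crossing-number property
realizes the minimal crossing number — this is asserted in the tests,
as are the printed (self, mutual) decompositions.  The rational words
were selected by an exhaustive search over small twist sequences for
the unique (or family-consistent) alternating diagrams matching each
target decomposition; their link determinants (2, 4, 6, 8, 12, 16, 14,
20, 10, 16) are consistent with 2-bridge theory throughout.  The
Rolfsen subscripts for 6₂², 7₁², 8₂², 9₁² follow this family/decomposition
identification; where several inequivalent links share a decomposition
the catalog documents the choice rather than claiming table-exact
naming.  Conformations at any N are produced by anisotropic scaling of
the templates (transverse strand gaps held at ≈ 1.7 σ, longitudinal
scale solved against the contour budget N·0.97 σ) followed by
arc-length resampling; infeasibly small N raises an error.  N = 120
realizations ship as XYZ fixtures, regenerable by
`scripts/make_catalog_data.py`.

Special systems: a single unknotted ring of 2N beads; and the
**deadlock** — two unlinked rings whose winding strands wind and then
unwind (a trivial braid word) in a taut double-hooked clasp, so Lk = 0
and the Alexander evaluations vanish, yet no separating plane exists
until one hook thermally slides out.

## Topological analysis

**Linking number.** The discrete Gauss double sum over segment pairs
(Klenin–Langowski solid-angle form), cross-validated against half the
signed sum of inter-ring crossings in generic projections.  A sum far
from an integer signals intersecting curves and raises.

**Projected crossings.** All transversal segment-pair intersections of
a projection, with over/under from depth and sign from the orientation
of the (over, under) tangent pair; degenerate directions are perturbed
and retried.  The average crossing number ⟨c⟩ averages the count over
directions drawn uniformly from the sphere (21 by default), freshly
sampled from a caller-provided seeded generator.

**Link identification.** From a projected diagram the Wirtinger
presentation is assembled (arcs split at under-passages; Fox calculus
rows with all generators abelianized to t) and the minor determinant
D(t) is evaluated at fixed points on the unit circle.  |D(t)| with
|t| = 1 is invariant under the ±tᵃ unit ambiguity; t = −1 gives the
classical link determinant.  Because the single-variable Alexander
polynomial depends on the relative orientation of the two components
while physical rings are unoriented, both orientations are evaluated
and canonically ordered.  The fingerprint (|Lk| plus the six Alexander
magnitudes), with consensus over three generic projections, separates
all shipped topologies pairwise (tested); unresolved fingerprints
return "unknown", never a wrong catalog label.  Split diagrams (a
component with no under-passage) evaluate to zero, matching the
vanishing Alexander polynomial of split links.  The fingerprint is
mirror-insensitive, so a link and its mirror image share a label — the
study's observables do not distinguish chirality.

**Physical link ℓ_LK.** The shortest pair of subchains, one per ring,
whose independent closures reproduce the whole conformation's link
type.  The search is bottom-up in summed bead count, ties broken by
smaller arc-length imbalance then lower start index; candidate arcs are
restricted to beads near inter-ring crossings (three projections, ±4
margin, stride 2) and checked first by the Gauss linking number of the
closed pair (a numba kernel) and then by the full fingerprint.
Closures connect arc endpoints through a point far outside the system,
directed along the axis through the arc centroids (each arc away from
its partner), with a consensus second direction — the "minimally
interfering closure".  The default search resolution is 2 beads of
summed length (`coarse=2`); exactness at `coarse=1` is verified against
an exhaustive enumeration on a taut clasp in the tests.  For symmetric,
delocalized conformations (e.g. two rigid round circles) the minimum is
convention-dependent; the deterministic tie-breaks make the output
reproducible.  Unlinked input returns a no-link result, not an error.

**Linear separability.** Exact convex-hull disjointness via a linear
program maximizing the margin of a separating plane (HiGHS), with a
10⁻⁹ σ tolerance; cross-checked against dense sampling of candidate
normals in the tests.  Separability implies Lk = 0, never conversely —
the deadlock is the counterexample.

## Observables and estimators

* Out-of-equilibrium relaxation time: τ_A = ∫₀^{t₀.₀₂} f_A(t) dt by the
  trapezoid rule, where t₀.₀₂ is the first (interpolated) crossing of
  f_A = 0.02; for a pure exponential this returns 0.98 τ.  Series that
  never reach the threshold are flagged censored (lower bound).
* τ_TACF integrates the mean orientational autocorrelation of all N/2
  diameter vectors to the same 0.02 threshold (FFT-based ACF).  The
  integral convention (rather than an exponential fit) was chosen for
  robustness to non-exponential tails and internal consistency with
  τ_A; a stationarity heuristic flags drifting windows.
* Equilibrium averages use the last five samples of each trajectory;
  the standard error treats each trajectory as one block (samples
  within a trajectory are correlated, trajectories are independent).
* Deadlock survival S(t) is the fraction of trajectories not yet
  linearly separable (the event is absorbing).  The lifetime τ_surv is
  fitted on ln S over S ∈ [0.1, 0.9] (excluding the initial lag
  plateau); τ_surv = ∫S dt is available as an option and is used
  automatically when the window contains too little decay, in which
  case the result is a censored lower bound.
* In bulk, the span is measured along a fixed random axis per
  trajectory (seeded), emulating the projected span of unconstrained
  pairs.

## State preparation

Stretched states follow the study protocol: confine in a narrow channel
(11 σ at production scale), pull one bead per ring — by default the
outermost bead on each ring's pulling side — with constant opposite
longitudinal forces f = 20 k_BT/σ, and equilibrate under tension; t = 0
of a relaxation run is the instant the force is switched off.  Because
catalog embeddings can exceed a narrow channel transversally, the
channel is closed in stages (each stage shrinks the diameter by at most
10% and never below the current bead envelope plus a safe gap, with
capped displacements).  A stationarity diagnostic compares the span over
the two halves of the tension window and flags drifting preparations.

**Eyelet (threaded tip).** The decorated state is constructed directly
in the taut stretched geometry: the clasp is an antipodal double helix
of the two rings' winding strands, and one ring's external tip is
folded inward and threaded through the helix's free axial core, ending
in a loop wider than the core (a steric stopper), so the tip swaps
sides.  A folded hairpin retracts along its own tube, so the decoration
is ambient-isotopic to the plain link — verified via the invariant
fingerprint, and the construction needs N ≳ 90 for the hairpin's
contour.  Two deliberate deviations from the fully decorated picture:
only one tip is threaded (a doubly threaded state would place four
hairpin legs plus the winding in one core; no routing with ~1 σ
clearances preserves the topology there), and the tension pulse applied
before t = 0 is short (≈ 30 τ_LJ), because under sustained pulling the
single threading extracts on ~10² τ_LJ timescales rather than
entrenching like the reciprocally hooked double threading.  As a
consequence the scaled-down decorated runs reproduce the span
undershoot (an interior minimum below initial and late-time values) and
a transient excess of projected crossings that decays away, but the
crossing excess peaks at release rather than at intermediate times: the
interior ⟨c⟩ maximum of the production-scale doubly threaded states is
a loop-growth effect this construction does not capture.

**Deadlock preparation** uses the taut-built clasp with a very short
(≈ 15 τ_LJ) tension pulse — sustained pulling at f = 20 k_BT/σ slides
the hooks apart at the reduced sizes used here, whereas the study's
interest is the force-free survival of the entangled state.

## Scaled-down study conditions

The production conditions (N = 120, 200 trajectories × 2·10⁴ τ_LJ per
condition, channel set {12, 16, 20, 24, 30, ∞} σ) are far beyond a
desk-scale run; the pipeline exposes them but the shipped tests use
reduced conditions chosen once as follows: N = 40 beads per ring and 20
trajectories for the equilibrium and relaxation trends, channel
diameters {6, 9, 12, ∞} σ scaled to the smaller rings with the
preparation channel at 5.5 σ (narrower than every study channel, as in
the production protocol), equilibrium windows of a few hundred τ_LJ
(several terminal times at this size), relaxation windows of 400 τ_LJ;
the eyelet comparison runs at N = 100 (the threaded decoration's
contour requirement) in a D = 9 σ channel; deadlock survival runs at
N = 60 with D ∈ {10, 14, ∞} σ and a 2000 τ_LJ window — channels of 10
and 14 σ genuinely confine N = 60 rings while still admitting the taut
clasp (tighter channels disrupt it during insertion), and the lifetime
ordering uses the integral definition τ_surv = ∫S dt, whose variance at
16 trajectories is far below the exponential fit's.  Passing these
scaled-down trend tests shows the machinery reproduces the *direction*
of every reported effect at small size; it does not validate the
production-scale magnitudes (times, plateau values), which require the
full statistics.

## Synthetic fixtures

Every analysis stage is testable without the simulator: exact
parametric link embeddings (ground-truth invariants), rigid-rotation
trajectories (closed-form TACF), Ornstein–Uhlenbeck series generated by
their exact discretization (known autocorrelation time; replica
ensembles decay as x₀e^{−t/τ}), and i.i.d. exponential disengagement
times (known survival rate).  All fixtures are deterministic functions
of their parameters and seed.  What these fixtures do not emulate:
hydrodynamic interactions (absent from the model by design), sampling
correlations of real trajectories, and the non-exponential tails of
real relaxation curves — estimator robustness to the latter is covered
by the trend tests instead.

## Known limitations

* No hydrodynamic interactions (free-draining Langevin dynamics).
* The link-type fingerprint cannot distinguish mirror images, and its
  reference table covers the shipped repertoire only ("unknown"
  otherwise).
* ℓ_LK on delocalized conformations is convention-dependent (tie-breaks
  documented above); the default 2-bead search resolution trades
  exactness for speed.
* The eyelet decoration is single-threaded and its entrenchment under
  sustained tension is weaker than the production-scale doubly threaded
  state (details above).
* Catalog naming for 6₂², 7₁², 8₂², 9₁² rests on the family/decomposition
  characterization rather than a table-exact Rolfsen identification.
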
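# Methods

This note records the modeling choices, default parameters, synthetic-data
construction, numerical conventions and known limitations of the package.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure and assumptions

The plant is linear and time-invariant, valid for postural tasks and small
perturbations around a fixed posture (all DOF at 0° except 90° elbow
flexion and 90° pronation).  Muscle force generation is a cascade of two
unity-DC first-order lags scaled by the maximum force,
`f_i(s)/u_i(s) = C_i/((T1_i s + 1)(T2_i s + 1))`.  This form is chosen
because the model names exactly three per-muscle constants (T1, T2, C) and
the open-loop pole census (two real poles per muscle) requires exactly two
lags; whether the original block diagram carried feedthrough is not
documented, so the strictly proper form is adopted.  Force–length and
force–velocity muscle properties, gravity, joint limits and posture
dependence of `M` and `I` are out of scope.

Spindle feedback is type-Ia only (PD on elongation); type II afferents are
excluded because their slower conduction would need a separate delay
channel.  GTO feedback is homonymous only — no reliable heteronymous GTO
measurements exist for the human upper limb — so the inner loop is
diagonal.  Feedback gains are constant: no gamma modulation, gain
scheduling, or activity dependence.

Sign conventions: `Δλ = −Mᵀ q`, so rotation in the direction of a
muscle's moment arm shortens it; the spindle loop enters the summing
junction positively (`u = uCNS + u_MS − u_GTO`), which makes homonymous
positive gains act as stabilizing stretch resistance.

### Delay placement

Each muscle's feedback channel carries one lumped round-trip delay
`a_i + 1 ms + e_i` approximated by a single Padé block.  The reported
closed-loop order (89 = 44 + 3·15 at order 3) implies one third-order
block per muscle, not separate afferent and efferent blocks; the lumping
ignores delay differences along heteronymous paths (a signal from source j
to target i is delayed by target i's round-trip time rather than
`a_j + c_ij + e_i`).  This is an approximation, flagged here.

## Parameters

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| `r` (V = rL) | 0.1 (admissible 0.06–0.14) | s | mid-range of the ratio that produces realistic joint damping |
| `k` (GTO) | 1.27 (stable range 0 < k < 2.7) | – | bandwidth-versus-oscillation tradeoff of the muscle/GTO loop |
| `c` | bounded above by the system-wide gain margin | MVC·s/m | stability of the full interconnection |
| Padé order | 3 | – | matches the reported closed-loop order; all-pass and DC-exact at any order |
| ECD threshold | 0.5 ms (configurable) | ms | midpoint between monosynaptic (≈0 ms) and interneuron-mediated (1–2 ms) excess central delay |
| bisection tolerance | 1e-4 relative on `c` | – | two margins can be compared at 1e-3 relative |

Out-of-range `r` and `k` require an explicit override flag; `k = 0`
(feedback off) is always allowed.  Constructing `L` and `V` never fills
missing gains implicitly: `GainMatrix.filled(0.0)` is an explicit step,
and the unmeasured lateral-deltoid homonymous gain is filled with the mean
of the other two heads' gains only at closed-loop construction.

Matrix orientation: gain tables are stored rows = source, columns =
target; feedback formulas index (target, source).  The transpose happens
in exactly two accessors (`GainMatrix.formula_matrix`, the loop
assembler), nowhere else.

## Estimation pipeline details

* PSTH strengths `(n⁺−n⁻)/n_tot` are bounded in [−1, 1]; EMG-averaging
  strengths `p·b/s` are unbounded.  Both follow from assuming the afferent
  volley adds linearly to background activity in proportion to stimulus
  intensity.
* Proximal nerve stimulation: the observed strength is the sum over
  innervated muscles; components known from single-muscle observations in
  the same method group are subtracted, the remainder split equally.
* Cross-method scaling uses unweighted through-origin least squares
  (`slope = Σxy/Σx²`); within-cell averaging across methods is unweighted.
  Neither weighting scheme is documented for the source data, so the
  simplest is used.  Methods scale to the reference directly when they
  share cells with it, otherwise through the designated intermediate
  group; the reference is preferred when both chains exist.
* Sign-discordance between the two directions of a muscle pair requires
  both magnitudes above 0.01 (one unit of the coarsest printed decimal):
  near-zero strengths flip sign between measurement methods and carry no
  reliable sign, and exact zeros are likewise sign-neutral.

## Delay solver

The design matrix of `a_i + e_j = T_ij − c_ij` always annihilates the
direction (+1 on every afferent, −1 on every efferent unknown), so the
decomposition is determined only up to a common shift.  The minimum-norm
pseudo-inverse solution is reported; the solver flags the indeterminacy
and reports any null space beyond it.  An optional anchor (fixing one
afferent delay) removes the shift for synthetic recovery tests, which
demand exact recovery (<1e-9 ms) on noise-free full grids.  Central
delays are 1 ms homonymous, ECD + 1 ms where measured, and otherwise the
mean of measured excitatory or inhibitory central delays according to the
pair's gain sign (ECD-threshold fallback when no gain exists); pairs with
neither are excluded from the system.

Muscles appearing in no measurement (brachialis) get delays from the
delay-versus-innervation-length regression lines.  Innervation lengths
are an optional side table; length-dependent operations degrade with a
clear error when absent.

## Stability analysis

The authoritative margin is bisection on the largest real part of the
closed-loop eigenvalues, exploiting that the state matrix is affine in
`c`.  The alternative `disk_margin` method sweeps the broken-loop transfer
matrix `L(jω)` (loop broken at the spindle summing junction, GTO loop and
delays closed) over a dense frequency grid, tracks its eigenvalue
branches, and takes `c = 1/Re λ` at positive-real-axis crossings — the
multiloop condition `det(I − c L(jω)) = 0`.  The two methods are required
to agree within 5%.  The printed per-loop criterion
`real(1 − c S_i P_k) < 0` is exposed only as a diagnostic: taken literally
it is vacuous at `c = 0`, so it is documented as the single-loop
instability boundary, never used for the margin.

The sensitivity analysis scales one forward-path parameter at a time by
{½, 1, 2}.  Exact consequences of the loop structure — margin ∝ `1/M²`
(M sits in both the torque and elongation paths) and ∝ `1/C` (C sits in
the forward path only; the GTO loop is `C`-invariant because `k/C` cancels
it) — are asserted at 1e-3 relative tolerance; all other parameters must
move the margin sub-linearly.

## Response analyses

Step responses use exact zero-order-hold discretization, so sampled
trajectories carry no integration error for step inputs.  Stretch
classification inspects a 25 ms window per (DOF, muscle) starting at that
muscle's own lumped delay ("excluding delay"); lengthened/shortened comes
from the elongation sign, excited/inhibited from the activity sign, and
any sign change inside the window is "ambiguous".  Muscles receiving no
feedback are reported "silent" and excluded.  The concordance fraction's
95% CI is a seeded nonparametric bootstrap over cases (10,000 resamples);
the CI method for the original report is undocumented, so the bootstrap is
the package's own choice.

Random-gain experiments redraw every present element of `L` uniformly
within the largest absolute estimated element (a single global bound, per
the stated construction; per-element bounds were rejected as
unsupported), with `V` following proportionally and stability enforced by
rejection.  `preserve_sign` keeps each element's estimated sign and leaves
structural zeros at zero; `shuffle_all` draws every element freely.

## Synthetic data: what it emulates and what it does not

The numeric forward-path tables (M, I, D, K, T1, T2) of the published
model live in supplementary material that is not packaged; the fixture
generator (`armloop.fixtures.generate_fixture`) stands in for them.  It
reproduces their *structure*: anatomically signed moment arms with 1–3
DOF per muscle and proximal–distal blocks, coupled SPD impedance with
uniform modal damping 0.3 (every joint mode underdamped, hence the
30-real + 14-complex open-loop census), muscle time constants near
30/45 ms, and the published maximum forces (heads of grouped muscles
split the grouped force equally).  It does not reproduce their numbers,
so analyses whose outcome depends on the numeric parameter values — the
absolute gain margin, pole locations, the exact stretch-response
concordance — are reported for the fixture, not asserted against the
published values; structural properties and scaling laws are asserted.
Passing tests therefore show the machinery is correct, not that the
fixture equals the published arm.

The packaged precursor observation set is a synthetic reconstruction
(`reconstruct_precursor_observations`): seven method groups with distinct
unit scales, integer motor-unit counts, nerve-stimulation rows and
within-method repeats, built so the estimation pipeline reproduces the
packaged gain matrix exactly.  It demonstrates and regression-tests the
pipeline; it is not the historical study data.  Likewise the
innervation-length side table is a least-squares construction jointly
consistent with the packaged delays at afferent/efferent conduction
velocities of 56.8/29.1 m/s, and the synthetic round-trip delay table is
`T = a + c + e` over a 57-pair pattern (43 measured-ECD pairs, 6
homonymous, 8 sign-imputable heteronymous).

## Numerical choices

* Eigenvalue classification real-versus-complex uses a relative imaginary
  tolerance of 1e-9.
* Pole-summary statistics follow the printed-table conventions: Hz for
  real/imaginary parts, absolute imaginary values, real poles excluded
  from natural-frequency and damping statistics, sample SD.
* The frequency sweep uses 1200 log-spaced points to 2000 rad/s plus DC;
  eigenvalue branches are matched greedily between adjacent frequencies
  and crossings located by linear interpolation.
* Bisection brackets by doubling from `c = 0.5` and fails loudly if the
  GTO-closed plant is already unstable at `c = 0`.
* Serialization writes `%.17g`, so table round-trips are bit-exact.

## Known discrepancies

The packaged tables are faithful transcriptions of the published text,
which is internally inconsistent in places.  The package never silently
"fixes" data:

* The printed gain matrix contains 68 values, but the publication's own
  summary counts imply 70 (99/169 missing) and a 39-pair overlap with the
  excess-central-delay table.  The faithful table yields 101 missing and
  38 overlapping pairs (100% sign-consistent).  Two acceptance tests
  assert the printed counts and fail; all other printed statistics (20
  bidirectional pairs, R = 0.47, the 5 named sign-discordant pairs, 43
  ECD entries) are reproduced exactly.
* The printed GTO gains for ECR/FCR and for ECU/FCU are pairwise swapped
  relative to `k/C` computed from the printed forces.  Both columns are
  stored; the recomputed column is authoritative and the discrepancy is
  flagged per muscle.
* The printed mean ± SD of the GTO gains (2.85 ± 1.78 ·10⁻³ MVC/N) match
  neither the printed column nor the recomputed one; the acceptance
  script reports the recomputed mean and asserts nothing about it.
* The published round-trip delay table and the observation-level gain
  precursors are supplementary material unavailable here; both are
  replaced by labelled synthetic reconstructions (above), and counts that
  depend on them (e.g. 63 measured round-trip pairs) are not asserted.

## Limitations

Beyond the modeling exclusions above: the lumped per-target delay
misrepresents heteronymous timing by up to a few milliseconds; the
magnitude floor in sign-discordance (0.01) is a reading of the source's
stated "near zero" exclusion, not a documented rule; and all
closed-loop behavioral numbers depend on the synthetic plant fixture
until the published forward-path tables are supplied, at which point
`ForwardPathParams` can be constructed from them directly.
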
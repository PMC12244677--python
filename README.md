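# armloop

A closed-loop, multiple-input multiple-output (MIMO) linear model of the
human upper limb, together with the estimation pipelines that produce its
feedback parameters from published reflex measurements.

Large-scale models of the arm are usually either open-loop MIMO (many
muscles, no reflexes) or closed-loop SISO (reflexes, one joint).  Building
a model that is both requires feedback gains and neural delays for *every*
source–target muscle pair, and no such collection exists ready-made.  This
package assembles one for the 13 major superficial muscles (expanded to a
15-muscle plant by splitting the biceps and triceps heads) acting on the 7
main joint degrees of freedom (DOF) from shoulder to wrist, and wires it
into a linear state-space model suitable for stability analysis and
simulation.  Intended users are motor-control and neuromechanics
researchers who need a quantitative starting point for reflex feedback in
upper-limb simulations.

## The model

Forward path (44 states): descending neural drive `uCNS` (fraction of
maximum voluntary contraction, MVC) passes per muscle through two
first-order lags with time constants `T1`, `T2` and maximum force `C_i`
(Hill-type excitation–contraction dynamics), producing forces `f`.  Moment
arms `M` (7×15, the transpose of the muscle-to-joint Jacobian) map forces
to joint torques, and the coupled joint impedance `I q̈ + D q̇ + K q = M f
+ τ_ext` produces joint motion.  Muscle elongation is `Δλ = −Mᵀ q`.

Feedback path:

* **Muscle spindles** (type Ia): proportional-derivative feedback on
  elongation, `u_MS = L Δλ + V Δλ̇`, entering the summing junction as
  positive feedback.  The matrices share one structure `G` of *relative*
  gains compiled from 7 families of reflex measurements:
  `V = c·G`, `L = (c/r)·G`, with `r = 0.1 s` (admissible 0.06–0.14 s).
* **Golgi tendon organs**: homonymous linear force feedback
  `u_GTO = (k/C_i)·f_i`, negative at the summing junction, with
  `k = 1.27` (stable range 0 < k < 2.7).
* **Delays**: each muscle's feedback rides through a lumped round-trip
  delay `a_i + 1 ms + e_i` (afferent + central + efferent), realized as
  one third-order Padé block per muscle (+45 states, 89 total).

The scale factor `c` is bounded by stability: the *system-wide gain
margin* is the largest `c` for which every closed-loop pole remains in the
left half plane, computed by bisection on the dominant pole and
cross-checked by a frequency-sweep multiloop margin.  Two exact scaling
laws follow from the loop structure and are enforced in tests: scaling `M`
by `s` scales the margin by `1/s²`; scaling `C` by `s` scales it by `1/s`.

Relative spindle gains come from a three-step pipeline: per-study
extraction (PSTH strengths `(n⁺−n⁻)/n_tot`; EMG-averaging strengths
`p·b/s`; proximal nerve stimulation split between innervated muscles),
within-method averaging, and cross-method through-origin regressions that
chain every method onto a common reference scale.  Afferent and efferent
delays are decomposed from measured round-trip delays via the
least-squares system `a_i + e_j = T_ij − c_ij`, with central delays
imputed from excess-central-delay measurements and feedback sign.

## Worked example

```python
>>> from armloop import datasets
>>> from armloop.spindle import symmetry_stats
>>> G = datasets.spindle_gain_matrix()
>>> G.gain("Bi", "PT"), G.gain("PT", "Bi")
(-0.5, 0.43)
>>> n_pairs, R, n_disc, disc = symmetry_stats(G)
>>> n_pairs, round(R, 2), n_disc
(20, 0.47, 5)
```

Twenty muscle pairs have gains measured in both directions; their
correlation is moderate (R = 0.47) and five pairs — biceps–pronator teres
among them, shown above — even disagree in sign, i.e. the reflex is
excitatory one way and inhibitory the other.

```sh
$ armloop gto --k 1.27 | head -4
muscle,max_force_N,gto_gain_printed_e3,gto_gain_e3
Delt Ant,1218.9,1.04,1.0419230453687751
Delt Lat,201.6,6.3,6.299603174603175
Delt Post,1103.5,1.15,1.1508835523334844
```

GTO gains are `k/C` in units of 10⁻³ MVC/N: the anterior deltoid
(C = 1218.9 N) gets 1.04·10⁻³ MVC/N; smaller, more distal muscles get
proportionally larger gains.

```sh
$ armloop stability --method bisection
{
  "method": "bisection",
  "c_max": 0.10073089599609375,
  "dominant_pole_real": -0.000178550868484173
}
```

On the synthetic plant fixture the spindle gain matrix can be scaled by at
most `c_max ≈ 0.10` before a closed-loop pole crosses into the right half
plane (the margin's absolute value depends on the forward-path parameters;
its scaling laws in `M` and `C` do not).

## Layout

| Module | Contents |
| --- | --- |
| `armloop.muscles`, `armloop.units`, `armloop.tables` | vocabularies, unit conventions, typed tables with missing-value masks, CSV I/O |
| `armloop.datasets` | packaged parameter tables (published transcriptions and labelled synthetic reconstructions) |
| `armloop.spindle` | relative-gain estimation pipeline, symmetry and sign-validation statistics |
| `armloop.gto` | force-feedback gains `k/C` |
| `armloop.delays` | central-delay imputation, least-squares delay decomposition, length regression |
| `armloop.statespace`, `armloop.plant` | labeled state-space toolkit, Padé delays, the 44-state forward path |
| `armloop.loop` | closed-loop assembly, gain margins, sensitivity analysis |
| `armloop.responses` | step/frequency response grids, pole summaries, stretch-response classification, random-gain experiments |
| `armloop.fixtures` | deterministic synthetic generators (plant parameters, observation sets, delay tables) |
| `armloop.cli` | `armloop` command-line entry point |
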
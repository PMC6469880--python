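# Methods

## The model

`gfsim` implements a conductance-based compartmental model of the
*Drosophila melanogaster* giant fiber system (GFS), the four-cell circuit
that converts a descending giant-fiber (GF) action potential into an
escape jump (tergotrochanteral muscle, TTM) and flight initiation (dorsal
longitudinal muscle, DLM):

* **GF** — one active cylindrical axon, 400 µm × 8 µm, stimulated at its
  proximal (brain) end;
* **TTMn** — the jump motoneuron: active axon (50 µm × 6 µm) plus passive
  medial (60 µm) and lateral (30 µm) dendrites;
* **PSI** — the peripherally synapsing interneuron: active axon
  (90 µm × 4.5 µm) plus a passive 170 µm dendrite;
* **DLMn** — the flight motoneuron: active tapering axon (50 µm, 2→4 µm)
  plus a passive 100 µm × 2 µm dendrite.

The GF drives the TTMn medial dendrite (contact 12 µm from its proximal
end) from its own distal end and the PSI axon (contact at 45 µm) from its
360 µm point through *rectifying* electrical synapses: the postsynaptic
compartment receives the ohmic current `g_gap (V_pre − V_post)` while the
presynaptic cell is entirely unaffected by the postsynaptic side.  The PSI
axon (76.5 µm) drives the DLMn axon (12.5 µm) through a delayed
double-exponential chemical synapse (τ_rise 0.1 ms, τ_decay 1 ms, reversal
0 mV, delay 0.15 ms, peak conductance normalized exactly to `g_peak`).
Intra-cell attachment points are not constrained by the anatomy table, so
every dendrite attaches by its 0-end to the proximal end of its cell's
axon (star topology), the minimal consistent choice.

Each section is divided into 51 iso-potential compartments (the published
discretization; configurable only for convergence studies).  Compartment
areas use the frustum lateral-surface formula on the linearly interpolated
diameter profile; axial resistances integrate the local cross-section
resistivity exactly for a linear taper.  Specific axial resistivity is
35.4 Ω·cm (the table prints "Ω/cm", which is not a specific-resistivity
unit; 35.4 Ω·cm is the conventional value), specific capacitance
1 µF/cm².

Active sections (all axons) carry, at equal densities, transient Na
(300 mS/cm², gating m³h), persistent Na (0.11 mS/cm², first-order
activation) and delayed-rectifier K (10 mS/cm², n⁴) conductances with
HH-type kinetics; every section carries a 0.03 mS/cm² ohmic leak.
Reversals: E_Na 65 mV, E_K −74 mV, E_leak −85 mV.

## Unit reading of the point conductances

The published parameter table prints the gap-junction conductance as
135 µS (young) / 34.5 µS (old) and the chemical-synapse peak conductance
as 80 µS.  These cells have ~26–37 pF total capacitance and ~1 nS resting
input conductance; a literal 135 µS point conductance would clamp the
whole postsynaptic cell to the presynaptic trace with a sub-microsecond
time constant, making the response latency *independent* of `g_gap` —
contradicting the reported monotonic latency–g_gap relation, the
young/old latency shift, and the PSI-diameter reversion, all of which
hinge on the whole-cell charging time `C_cell / g_gap` (≈0.2 ms young,
≈0.8 ms old for the TTMn — precisely the scale of the observed latency
shifts).  `gfsim` therefore reads the printed numerals as nS.  All config
keys keep the printed values (135, 34.5, 80) with unit nS.

## Integration

Backward Euler on the voltage system, default dt = 0.0025 ms (the
stimulus itself lasts only 0.03 ms, so dt must be well below that).
Within each cell the compartment tree is solved exactly per step by
Hines-ordered Gaussian elimination.  Gating variables advance by the
exact exponential update `x ← x∞ + (x − x∞)·e^(−dt/τ)` at the pre-step
voltage (staggered scheme).  Inter-cell coupling is explicit in the
presynaptic voltage only: the postsynaptic conductance of each synapse is
folded into the post cell's implicit diagonal, so the scheme is stable
for arbitrarily large point conductances, and the first-order lag error
is controlled by dt (checked by the dt-halving and nseg-doubling
convergence tests, <1% latency change).

Stimulus charge is injected with exact fractional-step overlap, so the
delivered charge is independent of dt.  Chemical-synapse trigger events
are upward crossings of −20 mV on the presynaptic trace (any threshold
between −30 and 0 mV detects the full-height PSI spike; sensitivity is
covered by a test), with the crossing time linearly interpolated between
steps and the conductance activating at the continuous time
`t_cross + delay`.  Events superpose linearly.

Initialization: all compartments start at −85 mV with gates at steady
state, followed by 200 ms of implicit coarse-step (0.05 ms) settling
before the stimulus; at stimulus onset the residual drift is below
10⁻⁴ mV/ms (equivalently, net compartment currents below 10⁻⁷ mA/cm²).
Latency t = 0 is stimulus onset.  AP peaks are the global maximum of the
first voltage excursion above 0 mV, refined by three-point quadratic
interpolation; sub-zero depolarizations are never counted as spikes.

## Channel kinetics and calibration

The source anatomy/physiology table fixes all densities and reversals but
the gating rate functions of the underlying motoneuron channel models are
not printed.  `gfsim` uses a standard parameterization — sigmoid steady
states `1/(1+exp(±(v½−V)/k))` and bell-shaped time constants
`τ_min + τ_amp·exp(−((V−v_τ)/σ)²)` — exposed completely in the config so
any kinetics can be substituted.  The default parameter values were
fixed by a one-time deterministic calibration (mirroring the manual
adjustment used to construct the original model): the free kinetics
parameters were optimized so that, with every table parameter at its
printed value, the model reproduces the four recorded escape latencies
(young TTM/DLM 0.93/1.44 ms at g_gap = 135 nS; old TTM/DLM 1.22/1.85 ms
at 34.5 nS) and the ~0.3 ms direct-stimulation (thoracic) figure, subject
to constraints encoding the circuit's known sensitivity behaviors, which
an otherwise under-determined surrogate must share with the original
channel models: the active-section resting potential sits above E_K (a
standing outward K current at rest, so that lowering ḡ_K or depolarizing
E_K depolarizes the rest and shortens the latency), extreme ḡ_K reduction
inactivates Na and *prolongs* the latency (the non-monotone left flank of
the K dependence), and a ~5-fold PSI-diameter reduction in the old
circuit restores the young DLM latency.  The calibration is part of model
construction; no parameter of the anatomy/physiology table is touched by
it, and nothing is adjusted anywhere in the test or analysis code.

The `calibrate` operation exposed in the package is the same machinery in
generic form: a deterministic coordinate search over user-chosen override
paths against target latencies, used by the self-consistency tests
(perturb kinetics → recalibrate → targets restored within 2%).

## Protocols and analyses

* **Head stimulation** — 120 nA × 0.03 ms at GF position 0; latencies are
  measured at the distal ends of the TTMn and DLMn axons and reported
  with the fixed 0.35 ms neuromuscular-junction delay added (the NMJ is
  never simulated; the delay is a constant bias estimated from the
  recorded ~0.65 ms neuromuscular latency).
* **Thoracic stimulation** — a 0.03 ms pulse at the TTMn medial-dendrite
  proximal end, amplitude auto-escalated by doubling from 10 nA to the
  first suprathreshold value (the protocol's printed ~0.3 ms figure
  refers to intrinsic TTMn dynamics; the escalation rule makes the
  protocol reproducible without an arbitrary amplitude choice).
* **Grid scans** — 1D/2D scans over any override path; per-point
  failures (no spike) are recorded, never raised.  Iso-latency bands are
  the grid points within ±1% of a target latency; marching-squares
  contour polylines are available for plotting.
* **Reversion searches** — bisection of one parameter to a target
  latency (tolerance 0.5%), with monotonicity of the bracket verified by
  5-point sampling; unreachable targets are reported as such, which is
  the expected outcome for every conductance parameter within its
  physiological scan range.

## Numerical and design choices

* dt = 0.0025 ms, nseg = 51 defaults; halving dt or doubling nseg moves
  latencies by <1%.
* Equilibration uses 0.05 ms implicit steps — unconditionally stable, and
  >100× faster than equilibrating at the stimulus dt.
* The chemical-synapse delay queue is continuous-time (event time plus
  delay), not rounded to the step grid; delay increments therefore move
  the DLM latency by exactly the increment (within one dt).
* A single GF is modeled (the bilateral pair is symmetric; the published
  cell list has exactly four cells).
* Cell-level diameter overrides (e.g. `cells.PSI.diam`) fan out to all
  sections of the cell, matching the per-cell diameter rows of the
  anatomy table.
* Trace output is CSV; latencies and scan bands are JSON/CSV.

## Problem sizes

The full circuit is 408 compartments; a head-stimulation run is 200 ms of
coarse settling plus 6 ms at dt = 0.0025 ms and takes ~0.1 s on one CPU
core.  The test suite's scans use 4–8 point axes and a 0.005 ms scan dt
(convergence-checked); reversion searches take ~20 simulations each.

## Known quantitative deficit: the PSI-diameter reversion fold

In the old-fly circuit, shrinking the PSI diameter alone reverts the DLM
latency toward the young value because the PSI's charging time
C_PSI/g_gap collapses with its membrane area.  The reversal curve
(old-fly DLM latency vs PSI diameter) is, however, nearly flat below
~1.5 µm: once the PSI charges quickly, the residual latency is set by the
rest of the chain.  The diameter at which the curve crosses the young
experimental latency is therefore ill-conditioned — a 1% vertical offset
of the curve moves the crossing by more than one fold-unit.  With the
calibrated surrogate kinetics the package computes a ~3.7-fold reversion,
whereas the original model (with its own channel kinetics) reports ~5;
pushing the fold to 5 here would require the young DLM latency to sit
~2.5% above its recorded value, which the calibration refuses to trade.
The qualitative result — a several-fold PSI-diameter reduction is the one
single-parameter anatomic change that reverts the old-fly DLM latency —
is robust; the printed fold value is not, in either direction.

## Limitations

* The gating rate functions are calibrated surrogates, not measurements:
  quantities tied to AP *shape* (width, afterpotential) are not
  constrained, only threshold dynamics and peak timing are.
* Rectification is ideal one-way coupling; no voltage-dependent
  junctional conductance curve.
* No muscles, no NMJ biophysics (fixed 0.35 ms delay), no sensory input
  upstream of the GF, no temperature dependence, no channel noise, and
  no dendritic arborization beyond the published unbranched sections.
* The model is fully deterministic; there is no trial-to-trial
  variability to compare against experimental scatter.
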
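# Methods

This note records the models, numerical choices and design decisions
behind `lemslite`, in the spirit of a simulator's methods appendix.

## Scope of the supported subset

The interpreter covers the abstract-cell slice of the NeuroMLv2/LEMS
ecosystem: generic LEMS ComponentTypes with parameters, constants,
exposures, requirements, attachments and a Dynamics block (state
variables, expression- and select/reduce-valued derived variables, time
derivatives, OnStart, OnCondition with state assignments and event
output); NeuroML documents containing abstract cells, pulse-current
inputs, simple synapse and channel/concentration placeholders,
morphologically detailed cells (parsed and validated only, never
simulated), and networks of populations, projections and explicit
inputs.  Out of scope by design: cable-equation simulation, kinetic
schemes, dynamics regimes, code generation for external simulators, and
HDF5 serialization.

## Dimensions and units

Dimensional bookkeeping uses integer exponent vectors over the seven SI
base quantities.  The registry carries the core dimension vocabulary of
the ecosystem (voltage, capacitance, conductance, per_time, …, none);
units are power-of-ten scalings of each dimension's coherent SI unit
(`mV` = voltage × 10⁻³), with an additive offset only for Celsius.
Powers of ten are applied as exact exponent arithmetic at parse time,
never as accumulated float products, so `1 mS_per_cm2` converts to
exactly `10 S_per_m2`.

Quantity strings follow the attribute-value grammar: optional sign,
decimal or scientific numeral, optional whitespace, optional unit
symbol; a bare numeral is dimensionless, and a unit of the wrong
dimension for the attribute (e.g. `0.5 s` where a voltage is required)
is a validation error.  Exponents are restricted to integers; rational
dimension exponents are rejected as out of subset.

## Expressions

Dynamics value strings are parsed by a hand-written tokenizer and Pratt
parser (no grammar library is used).  Precedence, loosest to tightest:
`or` < `and` < `not` < comparisons < `+ -` < `* /` < unary minus < `^`
(right-associative).  Both symbolic comparisons and the dotted LEMS
dialect (`.gt. .lt. .geq. .leq. .eq. .neq. .and. .or.`) are accepted
and normalised to one internal form.  Booleans are represented
numerically (1.0/0.0), which lets threshold flags such as the spiking
state live in the ordinary state vector.  The function library is
fixed: `exp ln log sqrt sin cos tanh abs ceil floor random`; `log` is
the natural logarithm (LEMS convention) and `random(x)` draws uniformly
on [0, x) from the simulation's seeded generator, so runs are
reproducible bit-for-bit.  Unknown functions are parse-time errors.

Dimension inference rules: `+`, `-` and comparisons require equal
operand dimensions; `*` and `/` combine exponent vectors; `^` requires
a dimensionless exponent and allows a dimensioned base only with an
integer-literal exponent; transcendental functions require and return
dimensionless; `abs` and `random` preserve their argument's dimension.
One deliberate extension: comparing any quantity against the literal
`0` is allowed regardless of dimension, because zero is scale-invariant
— this is what lets the cell's threshold test `v .gt. 0` (v: voltage)
check cleanly without a dimensioned literal syntax.

In-expression literals are dimensionless by convention; dimensioned
constants (such as the 1 ms normaliser `MSEC`) are hoisted into
Constant declarations on the type.

Evaluation has two semantically identical routes: a recursive reference
interpreter (the definition) and per-expression compiled Python
functions used in the integration loop (~20× faster); a 1000-case
random-tree property test holds them to bit-identical agreement.

## Component types and flattening

Types may extend other types; resolution concatenates declarations
root-first and treats any name collision between levels as an error
(no shadowing).  Derived variables are topologically sorted by their
value-expression dependencies; cycles are errors.  A select/reduce
derived variable (`synapses[*]/i`, reduce add) aggregates an exposure
over an attachment collection, with the empty collection reducing to
the identity (0 for add, 1 for multiply) — an unconnected cell simply
sees zero synaptic current.

The bundled standard library defines `baseCellMembPotCap` (capacitance
parameter C, exposures v and iMemb), `basePointCurrent` (current
exposure i), `pulseGenerator` (square pulse, implemented as the single
derived expression `amplitude * (t ≥ delay) * (t < delay + duration)`,
i.e. a half-open window [delay, delay+duration)), and
`HindmarshRose1984Cell` as described in the README.  At exactly v = 0
neither threshold branch fires and the spiking flag retains its prior
value (tie-break decision).  Every library expression passes the
dimension checker using only declared dimensions; this instance-time
check runs again on every build, before the first evaluation.

## Validation

Validation is two-level and finding-based: nothing raises for a merely
invalid document, and level 2 runs even when level 1 fails so reports
are maximal.  The 7 structural checks are driven by an explicit grammar
table of the subset — allowed attributes (with the dimension of each
quantity-valued attribute taken from the resolved LEMS type, so schema
and dynamics cannot drift apart), required attributes and children,
cardinality, parent/child placement, and canonical child order.  The 20
semantic checks cover id uniqueness, morphology integrity, reference
resolution and population-size consistency; "defined before referenced"
for segment groups is evaluated in document order of sibling groups.

Severity policy: every check reports errors except
`numberInternalDivisions`, which is a warning — a missing
discretisation hint degrades simulation quality but does not make the
document ill-formed.  The check applies to segment groups whose
`neuroLexId` marks them as unbranched.  Unknown elements and attributes
are strict errors by default; `--lenient` demotes them to warnings.
Report ordering is deterministic (document order within each check,
checks in registry order).

## Runtime and integration

Building an instance binds parameters and constants to SI doubles,
dimension-checks all dynamics, applies OnStart, and attaches explicit
inputs into the target's attachment collection after verifying the
input's type extends the collection's base type.  The default
integrator is fixed-step forward Euler, matching the behaviour class of
the reference interpreters; classic RK4 is selectable.  Condition tests
are level-checked once after each completed step, in declaration order,
with assignments applied immediately; no sub-step root-finding is done.
The spiking-state guard in the cell's threshold rule makes event
emission edge-triggered, which structurally prevents chattering at the
threshold.  A non-finite state aborts the run with the instance id and
time.

Recording: the time loop covers t = 0, dt, …, length with an inclusive
endpoint; output columns are written in SI units (a documented choice —
entered units are not preserved through flattening), one tab-separated
row per time point with time first, using shortest-repr float
formatting so identical seeds give byte-identical files.  Event files
receive `time<TAB>selection-id` rows.  Recording paths use the
`population[index]/exposure` form with 0-based indices.

## The worked example and its parameters

The worked example is a network of one Hindmarsh–Rose cell driven
through its synapse attachment by a 5 nA pulse generator, simulated for
1400 ms at dt = 0.025 ms (56 001 time points, well under a second of
wall time).  Of its numbers, only the 5 nA amplitude and the 1 ms
`MSEC` constant are fixed by the model's published description.  The
remaining constants are repository choices made once for the
regular-bursting regime: a=1, b=3, c=−3, d=5, s=4, r=0.002, x1=−1.3,
started from x0=−1.1, y0=−9, z0=1.  The membrane scaling v_scaling =
35 mV and C = 28.57142857 pF are chosen so that C·v_scaling·(1/MSEC) ≈
1 nA, mapping the 5 nA pulse onto a dimensionless drive of ≈5, inside
the classic bursting window of this configuration; we verified
numerically (independently of this package, with an adaptive ODE
solver) that the frequently quoted variant with c=+1 and drive ≈5
spikes tonically instead of bursting, which is why the c=−3
configuration is used.  The pulse covers the full 1400 ms so the
bursting invariant is assessed under sustained drive.

Burst detection in tests clusters spike events by inter-spike interval:
a gap larger than 5× the median ISI starts a new burst.  With the
defaults this yields 27 spikes in 6 bursts.

## Synthetic fixtures: what they do and do not show

All test inputs are generated programmatically: the worked example, one
minimal single-fault document per validation check (engineered so that
exactly one finding fires — no cascades), seeded random valid networks
(one population of n cells, shared component with dimensionless
parameters jittered ±10%), and the analytic linear-decay cell
dv/dt = −v/τ used as the integrator oracle.  Its initial value is
1 mV — the natural scale of a membrane potential — and the convergence
study measures the global error at t = 5τ for dt ∈ {0.1, 0.05,
0.025}·τ.  Note that absolute error bounds on this oracle are
scale-dependent: Euler's *relative* error at dt = 0.025τ is ≈6%
regardless of scale, while its absolute error at the mV scale is
≈4×10⁻⁷ V; the scale-free statements are the convergence orders
(measured ≈1.0 for Euler, ≈4.0 for RK4).

Passing these fixtures demonstrates the interpreter's contracts —
grammar, dimension algebra, flattening, event semantics, determinism —
on the supported subset.  It does not demonstrate coverage of the full
NeuroMLv2 element set, multi-compartment electrotonics, or agreement
with other simulators on arbitrary published models, all of which are
outside this package's scope.

## Known limitations

- Fixed-step explicit integration only; stiff or discontinuity-heavy
  models need steps small enough for stability, and threshold times are
  resolved only to the step size.
- Condition handlers run per step in declaration order; simultaneous
  conditions are ordered, not resolved jointly.
- The unit registry covers the subset's symbols, not arbitrary unit
  algebra; temperature handling is limited to degC↔K.
- Requirements (externally supplied variables) are carried in the data
  model but unused by the bundled library.
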
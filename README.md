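# lemslite

A desk-scale interpreter for a subset of the NeuroMLv2/LEMS model
description framework, written for computational neuroscientists and
tool builders who want a small, fully inspectable implementation of the
whole pipeline: parse declarative XML model documents, validate them
structurally and semantically, dimension-check their dynamics, flatten
component hierarchies into runnable ODE/event systems, and simulate
them with fixed-step integration.

NeuroML describes *what* a model is (cells, inputs, populations,
networks) as data; LEMS ComponentType definitions describe *how* each
element behaves — its parameters with physical dimensions, its state
variables, derived variables, initialisation, and threshold rules.
`lemslite` implements both layers for an abstract-cell subset and
reproduces the classic single-cell workflow end to end: a
Hindmarsh–Rose bursting neuron driven by a 5 nA current pulse.

## The model at the core

The bundled `HindmarshRose1984Cell` type is the three-variable bursting
neuron. With the dimensionless proxy x = v / v_scaling:

    phi = y − a·x³ + b·x²
    chi = c − d·x² − y
    rho = s·(x − x1) − z

    iMemb = C·v_scaling·(phi − z)/MSEC + iSyn        (MSEC = 1 ms)

    dv/dt = iMemb / C
    dy/dt = chi / MSEC
    dz/dt = (r·rho) / MSEC

with initialisation v = x0·v_scaling, y = y0, z = z0, and a spiking
flag set by the threshold rule: spiking becomes 1 (emitting a `spike`
event) when v > 0 while spiking < 0.5, and 0 again when v < 0 — so
events are edge-triggered by construction.  Synaptic/input currents
enter through an attachment collection; `iSyn` is a reduce-add over the
`i` exposures of everything attached.

All expressions are dimension-checked over the seven SI base quantities
before the first evaluation: `iMemb/C` must come out as voltage/time,
condition tests as dimensionless, and a mis-typed parameter such as
`C="0.5 s"` is rejected at validation time.

## Worked example

```python
from lemslite import standard_library, validate_level1, validate_level2, run
from lemslite.fixtures import worked_example

doc, spec = worked_example()
report = validate_level1(doc)
report.extend(validate_level2(doc))
print("valid:", report.valid, "findings:", len(report.findings))

result = run(spec, doc, standard_library())
spikes = [t for t, _ in result.events]
isis = [b - a for a, b in zip(spikes, spikes[1:])]
med = sorted(isis)[len(isis) // 2]
bursts = 1 + sum(1 for g in isis if g > 5 * med)
v = result.columns["HRPop0[0]/v"]
print(f"spikes: {len(spikes)}  bursts: {bursts}")
print(f"first spike at {spikes[0]*1e3:.2f} ms; v range "
      f"[{min(v)*1e3:.1f}, {max(v)*1e3:.1f}] mV")
```

prints

```
valid: True findings: 0
spikes: 27  bursts: 6
first spike at 144.65 ms; v range [-54.3, 65.1] mV
```

The document validates with zero findings; 1400 ms of forward-Euler
integration at dt = 0.025 ms produces 27 spike events grouped into 6
regular bursts (clusters separated by quiescent gaps much longer than
the intra-burst inter-spike interval), and the membrane potential
swings over a physiological-looking ±tens-of-mV range because the
dimensionless Hindmarsh–Rose variables are scaled by v_scaling = 35 mV.

The same workflow is available from the shell:

```sh
lemslite fixture worked-example -o example/
lemslite validate example/worked_example.nml          # exit 0, "VALID"
lemslite simulate example/LEMS_worked_example.xml --outdir out/
lemslite summarize example/worked_example.nml
```

`out/hr_v.dat` holds tab-separated `time  v` rows in SI units, one per
time point; `out/hr_spikes.dat` holds `time  selection-id` rows, one
per spike event.  Identical seeds give byte-identical files.

## Validation

`lemslite validate` runs a two-level check suite: seven structural
checks against the supported-subset grammar (names, types, value
restrictions, required inclusion, cardinality, hierarchy, sequence
order) and twenty semantic checks (unique ids at every level,
morphology integrity — unique segment ids, a single root segment with
id 0, segment-group membership/definition/ordering — reference
resolution for populations, projections, synapses, ion channels,
concentration models and included files, and population-size
consistency).  Findings carry stable check identifiers
(`schema.*` / `semantic.*`) and the suite is exercised by one minimal
single-fault fixture per check.

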
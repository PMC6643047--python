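# synprop

Quantification of T-cell **synapse propensity (SP)** on micropatterned
stimulatory spots, and of the competition it drives between memory and
naive CD8 T cells.

## The problem

When a migrating T cell touches antigen, it may switch from fast scanning
motility to an adhesive, long-lived contact — an immunological synapse
(IS) or a motile-but-confined kinapse (IK). The propensity to make that
switch is a cell-intrinsic property. On substrates carrying discrete
stimulatory spots (microcontact-printed anti-CD3 in a field of ICAM-1 and
CCL21), SP is operationalized as the **on-rate of arrest**: the initial
slope of the attachment curve, in cells per imaging field (50,625 µm²)
per minute. Treating cell–spot interactions as a bimolecular reaction,

```
on_rate = encounter_rate × arrest_efficiency
```

where the encounter rate measures how fast cells locate spots and the
arrest efficiency is the probability that an encounter converts into an
arrest. Memory CD8 T cells combine a higher encounter rate (they are
~1.6× faster) with a much higher arrest efficiency (~40% vs ~1 in 10
encounters), so they arrest several-fold faster than naive cells and
monopolize spots — but their interactions are also less durable (shorter
dwell half-life *t*₁/₂). At steady state the occupancy advantage of
memory over naive cells is

```
(kon_m / koff_m) / (kon_n / koff_n),      koff = ln 2 / t1/2
```

a ~7-fold on-rate advantage combined with ~3.5-fold lower durability
yields a ~2-fold competitive advantage, which is what limits the
suppression of naive-cell activation over 10–12 h.

## What the package provides

- `synprop.arena` — square grids of circular spots with per-spot arrest
  capacity (e.g. 64 spots of 10 µm at 30-µm pitch per reference field),
  point-membership queries, CSV serialization.
- `synprop.simulate` — a synthetic-data generator: persistent random-walk
  cells (per-cell lognormal speed, wrapped-normal turning), stochastic
  per-encounter arrest, exponential dwell, finite spot capacity, optional
  open-field replenishment; emits track tables plus a ground-truth event
  log.
- `synprop.metrics` — the measurement pipeline: encounter detection,
  arrest calls from deceleration + confinement, attachment curves,
  initial-slope on-rates, arrest efficiency with censoring correction,
  bimolecular decomposition residuals, uniform-surface IS/IK fractions,
  bootstrap fold-changes.
- `synprop.competition` — the on/off-rate site-competition model:
  analytic steady state, mass-action ODE, exact Gillespie simulation with
  per-cell bound intervals, 2-h enrichment, and an activation readout (a
  naive cell is scored activated, as a CD62L-shedding surrogate, when a
  single bound interval reaches a threshold of continuous engagement).
- `synprop.studies` — canonical end-to-end study designs.
- `synprop.cli` — `synprop simulate | analyze | compete` with YAML/JSON
  configs and full provenance echoes.

## Worked example

```python
from synprop import studies

report = studies.decomposition_study(seed=1)
for label in ("naive", "memory"):
    sp = report.phenotypes[label]
    print(f"{label:>6}: on-rate {sp.on_rate:.2f} cells/field/min | "
          f"encounter rate {sp.encounter_rate:.2f} /field/min | "
          f"efficiency {sp.arrest_efficiency:.2f} | "
          f"decomposition residual {sp.residual:.1%}")
```

prints (600 cells per phenotype, 90-min movies on a 5×5-tiled reference
field):

```
 naive: on-rate 0.27 cells/field/min | encounter rate 2.73 /field/min | efficiency 0.10 | decomposition residual 0.2%
memory: on-rate 1.91 cells/field/min | encounter rate 4.50 /field/min | efficiency 0.41 | decomposition residual 4.4%
```

Naive cells arrest at 0.27 cells/field/min and convert ~1 in 10
encounters; memory cells arrest ~7-fold faster, driven mostly by a
4-fold efficiency advantage on top of a 1.6-fold encounter-rate
advantage — and the product of the two measured factors reproduces the
independently measured on-rate to within a few percent for both subsets.
The corresponding folds and the model prediction:

```
memory/naive folds: on-rate 7.2 (95% CI 6.2-8.4), encounter rate 1.6, efficiency 4.2
steady-state competitive advantage: 2.0-fold
```

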
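# cyclescale

Temperature scaling of the early embryonic cell-cycle oscillator.

Early embryos of ectotherms (frogs, zebrafish, nematodes, flies) divide
over a 15–25 °C span of temperatures, and the duration of their cell
cycle follows the Arrhenius equation remarkably well over most of that
span — with characteristic deviations at both thermal extremes.  This
package provides the computational machinery to study why: it couples a
two-ODE cyclin B–Cdk1 relaxation oscillator with per-rate temperature
scaling, and asks when the emergent period is Arrhenius, when it bows,
and when oscillations fail altogether.

It is aimed at quantitative biologists analyzing cell-cycle timing data
(embryo event timings, droplet-encapsulated extract FRET recordings,
in-vitro enzyme assays) and at modellers exploring temperature dependence
in oscillatory networks.

## The model and statistics at its core

The oscillator (cyc = total cyclin B, cdk1a = active Cdk1, Hill-type
responses deg, cdc25, wee1):

    d cyc/dt       = ks − kd · deg(cdk1a) · cyc
    ε · d cdk1a/dt = ka · cdc25(cdk1a) · (cyc − cdk1a) − ki · wee1(cdk1a) · cdk1a

Temperature enters through per-rate scaling laws.  Durations Δt(T) are
described by the Arrhenius form ln Δt = ln(1/A) + Ea/(R·T) and its
generalizations (double exponential, quadratic exponential, power-law
exponential).  The temperature sensitivity is summarized either by the
apparent activation energy Ea or by Q10 = Δt(T)/Δt(T+10).

Key mechanistic results reproduced by the package:

* all four rates sharing one Ea ⇒ the period is exactly Arrhenius with
  that Ea (so is the pairwise-equal case, following the
  synthesis/degradation pair);
* an Ea imbalance between synthesis and degradation ⇒ a bowed
  (concave-up) Arrhenius plot and finite thermal limits, with
  interphase-like arrest past the cold limit and M-phase-like arrest past
  the hot one;
* a biphasic synthesis rate ⇒ a high-temperature upturn with
  Arrhenius-like behaviour at low temperature;
* lowering the synthesis rate narrows the viable temperature range from
  both sides.

Modules: `scaling_laws` (laws, Q10, Ea summaries), `fitting` (binning,
four fitters, bootstrap), `oscillator` (model, nullclines, fixed points,
temperature maps), `periods` (period detection, sweeps, titration scans),
`abc` (ABC-SMC inference of activation energies), `timeseries` (droplet
FRET and assay pipelines), `synth` (seeded generators with known ground
truth), `cli` (command-line entry points).

## Worked example

Simulate the reference oscillator, measure its period, and fit the
activation energy of a temperature sweep in which all rates share
Ea = 75 kJ/mol:

```python
import numpy as np
from cyclescale import oscillator as osc, periods as per
from cyclescale.scaling_laws import KELVIN_OFFSET, R, q10_from_ea

p = osc.reference_params()
ts = osc.simulate(p, t_end=1000.0)
r = per.detect_period(ts)
print(f"period {r.period:.1f} min, rising {r.rising_duration:.1f}, "
      f"falling {r.falling_duration:.1f}")

pmap = osc.TemperatureParameterMap.arrhenius(
    p, 20.0, {k: 75e3 for k in ("ks", "kd", "ka", "ki")})
grid = np.arange(14.0, 27.0, 2.0)
curve = per.temperature_sweep(
    pmap, grid, per.SimOptions(t_end=400, rtol=1e-6, atol=1e-9, method="LSODA"))
tk = grid + KELVIN_OFFSET
ea = np.polyfit(1 / tk, np.log(curve.periods), 1)[0] * R
print(f"period-curve Ea {ea / 1e3:.1f} kJ/mol, Q10(20C) {q10_from_ea(ea, 20.0):.2f}")
```

Output:

```
period 30.8 min, rising 23.4, falling 7.4
period-curve Ea 74.9 kJ/mol, Q10(20C) 2.76
```

The reference set oscillates with a ~30 min period dominated by the
rising (interphase) phase; with identical per-rate energies the emergent
period inherits exactly the common 75 kJ/mol, corresponding to a Q10 at
20 °C of about 2.8.

The same analyses are scriptable from the shell, e.g.

```sh
cyclescale synth embryo --ea 75 --noise-cv 0 --seed 1 --outdir out/synth
cyclescale fit-scaling --input out/synth/timings.csv --outdir out/fit
```

Every run writes a `manifest.json` (options, seed, version) beside its
outputs.

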
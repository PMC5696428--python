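# flightfit

Inference for seabird flight-duration distributions observed through
saltwater immersion (wet/dry) loggers.

Leg-mounted immersion loggers record, per aggregation interval of length
τ (10 s on recent devices, up to 1 h on early ones), whether the bird
touched water.  A flight — a continuous dry period — is therefore observed
only as the number *j* of *completely dry* intervals it covers: the two
intervals containing take-off and landing are contaminated, and flights
shorter than the grid can vanish entirely.  Comparing movement behaviour
across logger generations (e.g. wandering and black-browed albatross
deployments from 1992–2004) requires knowing what each observation scheme
can and cannot resolve about the underlying flight-time law.

`flightfit` provides the full pipeline:

* **Candidate flight laws** — shifted exponential, gamma, q-exponential and
  Pareto (the Lévy-flight step law), all with a 30 s biological lower limit
  on flight duration (`flightfit.distributions`).
* **Logger emulation** — the uniform-phase observation kernel
  K(j | t) and two synthetic-data emulators (per-flight kernel sampling and
  a full alternating wet/dry timeline) (`flightfit.emulator`).
* **Inference** — the exact multinomial likelihood
  ℓ(θ | r) = Σⱼ dⱼ log p(j | θ), where p(j | θ) integrates the flight
  density against the observation kernel and conditions on observability,
  alongside the naive likelihood that ignores the observation process
  (`flightfit.inference`).
* **Model selection** — AIC/BIC and numerically stable BIC-approximate
  model probabilities p(Mᵢ) ∝ exp(−ΔBICᵢ/2) (`flightfit.selection`).
* **Identifiability studies** — parameter- and model-recovery experiments
  across a 4 families × 4 scales generator grid observed at 10 s and 1 h
  (`flightfit.experiments`).
* **Real-data workflow** — parse wet/dry CSVs, extract flights by merging
  consecutive dry intervals, and run the fit/rank/Q-Q analysis
  (`flightfit.immersion`).

## Worked example

Fit all four families to a synthetic 10 s record and rank them:

```python
import flightfit as ff

params, _ = ff.solve_params_for_scale("gamma", 1.0, fixed={"shape": 0.7})
truth = ff.make_distribution("gamma", params)          # mean 1 h, shape 0.7
flights = ff.sample_flights(truth, 3000, seed=42)
record = ff.emulate_record(flights, ff.SCHEME_10S, seed=43)

analysis = ff.analyze_dataset(record)
print(analysis.comparison.table[["family", "dBIC", "prob"]])
print(analysis.gamma_report)
```

Output:

```
         family         dBIC          prob
0         gamma     0.000000  1.000000e+00
1  qexponential   147.354888  1.005293e-32
2   exponential   292.201630  3.541786e-64
3        pareto  3965.662612  0.000000e+00
```

```
{'shape': 0.6943, 'rate': 0.6901, 'mean_h': 1.0061, 'variance_h2': 1.4578}
```

The gamma wins decisively (ΔBIC ≈ 147 to the runner-up, model probability
1), and the fitted shape/rate recover the generating values (0.7, 0.706)
within a few percent; `mean_h = shape/rate` is the conventional summary of
the fitted law (the 30 s shift excluded).

The numbered drivers under `analysis/` run the complete studies and write
their tables to `results/`:

```sh
python analysis/01_simulate_records.py [--full]     # study bookkeeping
python analysis/02_parameter_identifiability.py     # estimates vs truth
python analysis/03_model_identifiability.py         # BIC recovery
python analysis/04_reference_tables.py              # published summaries
python analysis/05_immersion_workflow.py            # wet/dry pipeline
```

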
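# avpipe

Quantitative analysis of **autophagosome biogenesis** in live-cell
time-lapse microscopy of neuronal axon tips — for cell biologists who
record multi-channel videos (e.g. GFP-LC3B together with mCh-ATG13/ATG5,
SNAP/Halo-ATG9 or WIPI2B) and want the event-level quantification done
reproducibly instead of by hand in FIJI.

Autophagic vesicles (AVs) form at the axon terminal: an initiation-complex
marker such as ATG13 appears transiently (~100–150 s) and, in a
*productive* event, hands over to LC3B, which rises over ~3 min as the
punctum grows to a ~1 µm autophagosome. In *stalled* events the early
marker persists (≥ 5 min), LC3B is never recruited, and ATG9 is aberrantly
retained. The pipeline measures:

* **Biogenesis rate** — de-novo LC3B puncta per minute per neuron
  (puncta present at t = 0 count only with a significantly increasing
  intensity/area trend);
* **Event classes** — stalled (marker visible ≥ 300 s, no LC3B),
  productive (marker < 300 s, LC3B recruited), with right-censored and
  ambiguous events reported separately;
* **Aligned intensity profiles** — event-triggered averages (mean ± SEM)
  anchored at the LC3B half-maximum crossing;
* **Residence times** — track spans capped at the 600-s recording with
  censoring flags;
* **Statistics** — exact two-tailed Fisher (point-probability
  convention), Mann-Whitney U (exact for small n, midrank ties), Wilson
  proportion CIs, percent change, 2^ΔΔCt expression and phospho/total
  fraction ratios.

Because real recordings are scored manually and rarely published, the
package includes a first-class **synthetic video generator**
(`avpipe.simulate`) that renders multi-channel stacks with the event
kinetics above — Poisson arrivals, confined spot mobility, shot + read
noise — plus exhaustive ground truth, so every stage is validated end to
end. See `docs/methods.md` for the models and conventions.

## Worked example

Simulate a 5-neuron cohort at the young-adult preset (0.47 events/min,
85% productive) and run every stage:

```python
import avpipe
from avpipe.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(sim=avpipe.young_adult_config(), n_fields=5, seed=1)
results = run_pipeline(cfg, "out/")
```

writes `detections.csv`, `tracks.csv`,
`events.csv`, `summary.csv`, `profiles.csv` and `stats.json` under
`out/`; `results` is the stats dict:

```json
{
 "config_hash": "900b50610354",
 "mean_rate_per_min": 0.4,
 "n_ambiguous": 2,
 "n_fields": 5,
 "n_productive": 20,
 "n_stalled": 2,
 "productive_fraction": 0.9090909090909091,
 "productive_fraction_ci95": [0.7218505315839417, 0.9747045710090046],
 "seed": 1,
 "sem_rate_per_min": 0.07745966692414832
}
```

Read: the five videos yielded a mean biogenesis rate of 0.40 ± 0.08
LC3B puncta/min (the generating rate was 0.47; at 5 fields the Poisson
sampling error is this large), 20 productive and 2 stalled classified
events (90.9% productive, Wilson 95% CI 72–97%) and 2 ambiguous events
excluded from the proportion. Every output carries the config hash and
seed, and re-running the same config is bit-identical.

The same stages are available from the shell:

```sh
avpipe simulate --config sim.yaml --out sim/ --seed 4
avpipe detect --video sim/video.tif --channel LC3B --out det.csv
avpipe track --detections det.csv --video sim/video.tif --out tracks.csv
avpipe run-all --config pipeline.yaml --out out/
avpipe stats fisher 52 101 45 11
```

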
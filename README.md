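# flocknet

Social-network inference and dietary-decision modelling for RFID
feeder-visit data from wild birds that forage in fission–fusion flocks.

Automated feeding stations record a timestamped stream of antenna reads
of tagged individuals. Birds arrive in flocks, so the stream consists of
dense bursts separated by quiet gaps. `flocknet` implements the complete
analysis chain from that raw stream to statistical inference:

1. **Flocking-event detection.** Each site-day's detection times are
   modelled as a one-dimensional Gaussian mixture; the number of
   components is chosen by BIC and each detection is assigned to its
   maximum-responsibility component. The result is a binary
   group-by-individual (GBI) matrix: rows are flocking events, columns
   are birds.
2. **Social networks.** Dyadic association is the Simple Ratio Index,
   `SRI(A,B) = F_AB / (F_A + F_B − F_AB)`, where `F_A` is the number of
   flocking events containing A. Per-bird centrality metrics: weighted
   strength (row sum of SRI weights), average edge weight (mean of
   non-zero weights), eigenvector centrality (leading eigenvector of the
   weight matrix, scaled to max 1), plus the simpler social measures
   mean flock size and number of unique flock-mates.
3. **Dietary-decision models.** In experimental trials each site offers
   a novel-food and a familiar-food feeder. Per bird, detections on the
   novel feeder are binomial "successes" and detections on the familiar
   feeder "fails"; a quasi-binomial (logit link, Pearson-dispersion
   scaled) GLM relates this preference to the bird's centrality in the
   period *before* the trial, controlling for site, sex, age, immigrant
   status and prior feeder usage. Companion models cover neophobia
   (whether the first arrival was at the novel feeder; two
   Gaussian-family latency measures) and post-first-use preference.
4. **Permutation inference.** Network positions are not independent
   across birds, so each coefficient also receives a permutation p-value
   (`p_rand`): the response is reassigned among birds of the same site
   and period, the model refitted, and the observed coefficient placed
   in the resulting null distribution (two-tailed, add-one corrected).
5. **Synthetic studies.** A generator simulates the whole design — two
   sites, a multi-day baseline, two trials with colour-swapped novel
   food, bursty flock visitation driven by a latent per-bird sociality,
   and a configurable sociality → novel-food-use effect — with full
   ground truth, so every stage can be tested for parameter recovery.

## Worked example

```python
from flocknet import (SimConfig, GMMParams, simulate_study, segment_stream,
                      build_gbi, sri_network, node_metrics, typical_group_size)

cfg = SimConfig(seed=1)                      # 2 sites x 40 birds, 12+4+4 days
population, stream, truth = simulate_study(cfg)
events, assignment = segment_stream(stream, GMMParams(seed=1))
print(len(events), float(typical_group_size(events)))
# 1175 6.56  -> ~1200 flocking events, typical group size ~6.6 birds

gbi = build_gbi(events[events.site_id == "S1"])
net = sri_network(gbi)
metrics = node_metrics(net, gbi)
print(metrics["strength"].describe().round(2).loc[["mean", "min", "max"]])
# mean 2.67, min 1.31, max 4.27 — strength tracks the latent sociality
```

The full analysis is a sequence of numbered drivers:

```bash
python analysis/01_simulate.py --seed 1          # study fixtures -> scratch/study/
python analysis/02_detect_flocks.py --seed 1     # events + recovery ARI
python analysis/03_build_networks.py             # SRI networks + metrics
python analysis/04_fit_models.py                 # GLM estimates
python analysis/05_permutation_tests.py --seed 1 # adds p_rand
python analysis/06_replicate_properties.py       # calibration & power
```

With the default generator (a positive sociality effect of 0.5 logits
per sociality SD on novel-food use, and first-arrival choice independent
of sociality), step 05 prints, for example:

```
 trial                 model    coef     se      t      p  p_rand
trial1        usage~strength  0.5942 0.0924 6.4318 0.0000  0.0010
trial1 neophobia_…~strength  -0.0541 0.6942 -0.0780 0.9381  0.9330
trial2        usage~strength  0.3633 0.0817 4.4478 0.0000  0.0045
```

i.e. prior network strength predicts novel-food usage in both trials,
while first-arrival neophobia shows no sociality signal — the
dissociation the pipeline is designed to resolve.

There is also a CLI (`flocknet simulate|validate|detect|network|fit|permute|run|report`)
wrapping the same functions, and `run_pipeline(RunConfig(...))` for
single-call end-to-end runs.

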
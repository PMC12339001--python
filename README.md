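# mitoquant

Quantification of mitochondrial redistribution, clustering and partitioning
in early (mouse) embryos from two-channel fluorescence images, plus a
stochastic model of organelle inheritance at cleavage.

During the first embryonic division, mitochondria must be divided between
the two daughter blastomeres. Because they are inherited as discrete
clusters, the *fragmentation state* of the network controls how even that
division can be: many small, dispersed clusters concentrate the random
split near 1:1, while a few large aggregates (as after loss of the fission
GTPase Drp1) make strongly biased inheritance likely. `mitoquant` provides
the image measurements used to characterize this system and the
partitioning model that links them:

- **Image primitives** — Gaussian smoothing, rolling-ball background
  subtraction (grayscale opening by a disk), automatic histogram
  thresholding (Yen and moment-preserving/Tsai criteria over a 256-bin
  histogram), binary dilation, 8-connected particle analysis with areas in
  µm² and equal-second-moment ellipse axes, maximum-intensity Z projection.
- **Quantifications** — perinuclear/perispindle accumulation ratio (mean
  intensity in a 10-px ring around the nucleus/spindle mask over the mean
  outside); mitochondrial cluster count/size (Yen threshold, particles
  > 0.15 µm²); angular non-uniformity (SD of mean intensity over six 60°
  polar sectors anchored to the spindle long axis); symmetry index
  (greater/smaller) and inheritance ratio (smaller/greater) of totals split
  across a cleavage plane; ROS enrichment inside vs outside mitochondria;
  masked Pearson pixel correlation; centroid-track projection.
- **Partition model** — each of *n* clusters with masses *m₁…mₙ* goes
  independently to daughter A with probability *p* (default 0.5); the
  per-division inheritance ratio is min(M_A, M_B)/max(M_A, M_B). Exact
  enumeration is provided for *n* ≤ 20 equal clusters (binomial law).
- **Synthetic scenes** — a generator of two-channel zygote/two-cell images
  with planted ground truth (punctum positions, clump labels, perinuclear
  enrichment, angular concentration, partition fraction, Poisson+Gaussian
  noise) so every stage is testable without microscopy data.

## Worked example

```python
import mitoquant as mq
from mitoquant.partition import ClusterPopulation, simulate_partition

# a dispersed, noise-free synthetic zygote: 200 puncta of ~0.3 µm²
scene = mq.generate_zygote_scene(mq.SceneParams(seed=1).noise_free())
stats = mq.cluster_stats(scene.mito)           # Yen threshold + >0.15 µm² filter
print(stats.n_clusters, round(stats.mean_area_um2, 3))
# -> 200 0.277

# the same mass aggregated into 5 clumps (fission-deficient phenotype)
aggr = mq.generate_zygote_scene(mq.SceneParams(seed=1, n_clumps=5).noise_free())
print(mq.cluster_stats(aggr.mito).n_clusters)
# -> 5

# feed measured cluster sizes into the inheritance model
for s in (stats, mq.cluster_stats(aggr.mito)):
    pop = ClusterPopulation(s.regions["area_um2"].to_numpy())
    print(round(simulate_partition(pop, n_rep=10_000, seed=3).mean_ratio, 3))
# -> 0.895   (200 dispersed clusters: near-symmetric inheritance)
# -> 0.492   (5 large clusters: strongly biased inheritance)
```

The printed numbers mean: the dispersed scene is segmented into exactly
its 200 planted clusters with mean area 0.277 µm² (planted footprint
≈ 0.3 µm²); aggregation collapses the same mitochondrial mass into 5
clusters; and partitioning those cluster populations at cleavage yields a
mean inheritance ratio near 0.9 (symmetric) for the fragmented state but
only ≈ 0.49 for the aggregated one.

A CLI mirrors the library: `mitoquant accumulation|clusters|angular|ros|
partition|correlate|track|simulate|synth …` reads TIFF/CSV inputs and
writes CSV rows (see `mitoquant --help`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the pipeline from scratch under the given seed: it generates
dispersed, aggregated and two-cell scenes, measures cluster statistics,
angular non-uniformity and the cleavage-plane split, feeds the measured
cluster sizes into the partition simulator, prints the resulting summary,
and writes the JSON result map to `--out`.
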
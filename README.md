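# replicomb

Single-molecule DNA-combing analysis of replication-origin firing in fission
yeast, as a tested, reproducible pipeline.

DNA combing stretches individual chromosomal DNA molecules (here, megabase
fragments of the 13.6-Mb *Schizosaccharomyces pombe* genome) on glass so that
nucleotide-analog labels (a BrdU pulse followed by a short EdU chase) mark
where replication was active.  From the labeled tracks one can read off
replication origins (track midpoints), inter-origin distances (IODs),
origin clusters, fork velocities, and the rate of origin firing as S-phase
progresses.  `replicomb` provides both the measurement stack for such track
tables and the stochastic generators needed to test it against known ground
truth.

## The model

S-phase is modeled as one-dimensional nucleation and growth (KJMA): origins
fire at a rate *r(f)* per minute per megabase of **unreplicated** DNA
(a linear ramp from 2 at the start of S-phase to 8 at *f* = 0.5, then
constant), are placed uniformly on unreplicated territory, and launch two
forks moving at *v* = 2.8 kb/min that annihilate when they meet.  For a
constant rate *I* the replicated fraction follows the closed form
*f(t) = 1 − exp(−I v t²)*, which the simulator is tested against.

On the measurement side:

* the IOD exceedance curve *S(x)* = fraction of IODs larger than *x* is a
  straight line on semilog axes when origin placement is random;
* clustered placement produces two semilog regimes, formalized as a
  two-component exponential mixture
  *S(x) = w e^(−λ₁x) + (1−w) e^(−λ₂x)* fitted by EM, with model preference
  decided by a parametric-bootstrap likelihood ratio;
* departure from a single exponential is tested with a Monte-Carlo
  Lilliefors (KS-with-estimated-rate) test;
* clusters are maximal chains of ≥ 5 origins with adjacent spacings
  ≤ 40 kb;
* fork velocity is the terminal EdU segment of a progressive fork divided
  by the chase duration, and the firing rate divides newly fired (EdU-only)
  origin counts by the chase time and the unreplicated DNA.

## Worked example

```python
import numpy as np
import replicomb as rc

genome = rc.GenomeSpec()                      # three chromosomes, 13.6 Mb
sim = rc.simulate_genome_sphase(genome, rc.KineticProfile(), seed=1)
print(f"S-phase duration: {sim.duration_min:.1f} min, origins fired: {len(sim.events)}")

timing = sim.timing_map()                     # 2-kb replication-timing map
mols = rc.label_pulse_chase(timing, t0=0.0, pulse=4.0, chase=3.0)
frags = rc.fragment_and_stretch(mols, rc.CombingNoise(), seed=2)
records = [r for m in frags for r in rc.classify_replicons(m)]
vel = rc.estimate_fork_velocities(records, chase_min=3.0)
print(f"progressive forks: {vel.n_forks}, mean velocity {vel.mean_kb_min:.2f} kb/min")

cl_mols, truth = rc.generate_two_regime_molecules(
    rc.ClusteredPlacementParams(), genome, seed=3)
iods = rc.eligible_distances(rc.measure_iods(cl_mols))
fit = rc.fit_exponential_regimes(iods, n_bootstrap=199, seed=4)
lil = rc.lilliefors_exponential(iods, n_null=10000, seed=5)
print(f"model preferred: {fit.preferred}; steep/shallow medians "
      f"{fit.two_regime.median_steep_kb:.1f}/{fit.two_regime.median_shallow_kb:.1f} kb")
print(f"Lilliefors exponentiality p = {lil.p_value:.2e}")
```

prints

```
S-phase duration: 21.4 min, origins fired: 573
progressive forks: 399, mean velocity 2.75 kb/min
model preferred: two-regime; steep/shallow medians 19.1/108.5 kb
Lilliefors exponentiality p = 1.00e-04
```

The simulated S-phase fires ~570 origins in ~21 minutes.  The pulse/chase
readout recovers the generative fork speed (2.8 kb/min) to within a few
percent.  The clustered cohort's IODs are decomposed into a steep
(~19-kb-median, within-cluster) and a shallow (~110-kb-median, between-
cluster) regime; the mixture is preferred over a single exponential, and the
Monte-Carlo Lilliefors test rejects exponentiality at its resolution
(p = 1/10001): origin spacing is random *within* each regime but not
globally — the signature of origin clustering.

A command-line interface wraps the same pipeline:

```sh
replicomb simulate --generator clustered --seed 1 --outdir run1
replicomb report run1
```

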
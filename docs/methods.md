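# Methods

## The S-phase model

Replication is modeled as nucleation and growth in one dimension.  Origins
fire at a rate *r(f)* expressed per minute per Mb of unreplicated DNA, are
placed uniformly on unreplicated territory only (no "phantom" origins inside
replicated DNA — this is what "per Mb of unreplicated DNA" means), and send
out two forks at constant velocity *v* that annihilate pairwise on meeting.
Chromosome ends replicate passively.

The simulator (`simulate_genome_sphase`) is time-stepped with Δt = 0.1 min:
per step the number of new origins is Poisson with mean
*r(f)·U(t)/1000·Δt* (U in kb), and unreplicated gaps shrink by *v·Δt* per
moving boundary.  At the default rates, per-step firing probabilities per
gap are ≪ 1, so the discretization error is negligible against run-to-run
noise.  Because forks move at constant speed and annihilate on meeting, the
replication time of a position is the first-arrival time
*T(x) = minᵢ (tᵢ + |x − xᵢ|/v)* over the fired origins of its chromosome;
the timing map is computed from the event list on a regular grid (2 kb by
default, the resolution of DNA combing).

Two analytic identities anchor the implementation and are enforced in the
test suite for constant rate *I*:

* *f(t) = 1 − exp(−I v t²)* (matched within 3 SE of the Monte-Carlo mean);
* total origins fired per kb → ½ √(πI/v) (e.g. ≈ 644 per 13.6 Mb at
  I = 0.008 /kb/min, v = 2.8 kb/min).

Two useful corollaries used throughout: the density of unreplicated gaps
per kb is *(1−f)·A(t)* with *A(t) = ∫₀ᵗ I ds*, and the fork density per
unreplicated kb is *2A(t)*.

### Default kinetic parameters

| parameter | default | units | meaning |
|---|---|---|---|
| r0 | 2 | origins·min⁻¹·Mb-unrepl⁻¹ | firing rate at S-phase onset |
| r_mid | 8 | origins·min⁻¹·Mb-unrepl⁻¹ | plateau rate from f = 0.5 |
| f_knee | 0.5 | — | end of the linear ramp (ramp is linear in *f*) |
| v | 2.8 | kb/min | fork velocity |
| chase | 3 | min | EdU chase duration |
| genome | 5600 + 4500 + 3500 | kb | three chromosomes, 13.6 Mb total |

Whether the rate ramp is linear in *f* or in time is not identifiable from
the readouts modeled here; linear-in-*f* is assumed.  Total S-phase duration
is emergent (≈ 21–24 min at the defaults), not imposed.

## Labeling and combing measurement model

`label_pulse_chase` marks grid cells replicated in [t₀, t₀+pulse) as BrdU
and in [t₀+pulse, t₀+pulse+chase) as EdU; DNA replicated before t₀ or not
at all is unlabeled and indistinguishable.  Maximal same-channel runs become
tracks; tracks below the 2-kb detection minimum are dropped.

`fragment_and_stretch` emulates combing: exponential inter-breakpoint
distances (mean 1600 kb) with fragments under 200 kb discarded, so *kept*
fragments average 1800 kb, matching the molecule-length law used by the
static generators (200 kb + Exp(1600 kb)).  Each fragment carries one
multiplicative stretch factor — stretching is a molecule-level phenomenon —
drawn from a truncated normal with mean 146/150 and CV 15/146, calibrated
so a 150-kb interval measures 146 ± 15 kb across molecules.  Coordinates
are snapped to the 2-kb grid after merging same-channel gaps below 2 kb on
physical coordinates.

## Static generators and their ground truth

`generate_two_regime_molecules` plants clustered origins: cluster sizes are
5 + Poisson(7) (mean 12, minimum 5, the cluster-defining minimum); spacings
within clusters follow an exponential truncated at 40 kb whose rate is
solved numerically so the *truncated* median is 17 kb; sparse origins
between clusters follow an exponential of median 160 kb.  Cluster anchors
follow a renewal process with an exclusion gap of one mean cluster span
plus 40 kb: purely uniform anchors frequently overlap under the cluster
definition, which would make the planted clusters-per-genome count
(default 25) unrecoverable by any caller.  The nominal 0.60 in-cluster
origin fraction is recorded but cannot hold jointly with the other
defaults on a 13.6-Mb genome (25 clusters × 12 origins with 160-kb sparse
spacing leaves far fewer sparse origins than 40% of the total); the
achieved planted fraction is ≈ 0.85–0.9 and recovery is always judged
against the planted truth.

Each origin is dressed as a track of length *extent·L/n* so the molecule
reaches the requested replication extent (default 0.15).  The default
extent is the calibrated operating point of the dressing: tracks must stay
well below the 17-kb within-cluster spacing or neighboring tracks merge,
midpoints shift, and planted clusters fall below the caller's five-origin
minimum.  At 0.15 the 20-seed recovery experiment gives in-cluster
membership within 6 percentage points, cluster count within 4%, and
per-origin precision/recall of 0.999/0.91; at 0.30 merging destroys a third
of the origin calls.  Tracks that would fall below the 2-kb detection
minimum on origin-dense molecules are clamped to it.

`generate_uniform_molecules` and `place_uniform_origins` provide the
stochastic null (and the histone-modification-mutant-like condition in
which clustering is lost): i.i.d. uniform origins whose spacings are
asymptotically exponential.  Note that *track-dressed* molecules never
yield exactly exponential measured IODs — merging truncates the short-gap
tail — so exponentiality calibration experiments run on origin-position
spacings, which is also what a matched simulated null contains.

`generate_rdna_array` models tandem rDNA repeats: 100 × 10-kb repeats, one
potential origin per repeat midpoint, fired independently with probability
*p*, dressed with a short (1-min) pulse so adjacent fired repeats remain
distinct tracks.  The idealized mean spacing is *repeat/p*; on a finite
100-repeat array the interior gaps are length-biased against long gaps, so
the measured mean at p = 0.2 is ≈ 47.7 kb rather than 50.0 — a real
edge-censoring effect of finite molecules, reproduced rather than
corrected.

`generate_successive_sphases` simulates two consecutive S-phases and
returns their early-firing origin sets, either independent or with a
configurable re-firing probability, for the epigenetic-memory overlap test.

## Estimators

**Origin calls and IODs.**  One call per contiguous labeled block (a
BrdU+EdU block is a single replicon), at the exact block midpoint.  IODs
are adjacent-midpoint distances; molecule-end intervals are censored and
excluded; a record is eligible only if both flanking tracks are < 20 kb
and the molecule is < 50% replicated (strict inequalities).  Extent bins
(0–5, 5–20, 20–50%) are closed on the right.

**Two-regime decomposition.**  The "two straight lines" of a clustered
survival curve are formalized as a two-component exponential mixture
fitted by EM (initialized by a median split; 500 iterations max;
convergence on relative log-likelihood below 1e-10).  The steep/shallow
order is enforced after convergence.  The two-line rendering takes the
initial tangent of the log-survival (slope −(wλ₁+(1−w)λ₂)) and the tail
line (log(1−w) − λ₂x); their crossing is the reported breakpoint.  Model
preference uses a parametric-bootstrap likelihood ratio (mixture vs single
is non-regular, so a χ² reference would be wrong): default 500 replicates,
α = 0.01, with a guard that 1/(B+1) < α, and a degeneracy rule preferring
the single model when λ₁/λ₂ < 1.5.

**Lilliefors exponentiality test.**  KS distance to the exponential with
rate 1/mean; because the rate is estimated, the null is built by Monte
Carlo with per-draw re-estimation (default 10,000 draws, vectorized in
chunks); p is reported as (1+#{D* ≥ D})/(n_null+1), i.e. with resolution
1/(n_null+1).  Calibration (type-I error ≈ α, uniform p-values) is part of
the test suite, alongside a cross-check against an independent
implementation of the same statistic.

**Fork velocity.**  Terminal EdU segment length of a progressive fork
(EdU distal edge bordering unlabeled interior DNA) divided by the chase.
At the 2-kb instrument grid the *mean* is inflated a few percent because
sub-grid gaps ahead of a fork (chase-fired origins about to merge) fuse
EdU runs; on a fine grid the estimator recovers the generative velocity
within ~1–3%, which is how the recovery property is tested.

**Firing rate.**  The naive estimator — newly fired (EdU-only) blocks per
chase minute per unreplicated Mb — has two large opposing biases at a
3-min chase: the unreplicated denominator shrinks substantially during the
chase (inflation), and chase-fired origins merge into advancing forks
before the chase ends (deflation).  `kinetic_point` therefore supports
three observable-based corrections, enabled per call: (i) mid-chase
unreplicated length U_end + EdU/2 (the EdU total equals the DNA made
during the chase); (ii) a detection dead time min_track/(2v) subtracted
from the effective chase; (iii) a merge-survival factor from KJMA
geometry — with exponential holes of observed density λ (holes per
unreplicated kb), the clearances around a new origin are i.i.d. Exp(λ)
and close at 2v, giving a mean survival of (1 − e^(−4vλc))/(4vλc) over a
chase of length c.  With all three, binned recovery of the generative
ramp is within 15% (tested at a 1-min chase on a 0.5-kb grid, where the
corrections' assumptions hold); at the 3-min/2-kb instrument settings the
naive estimator underestimates mid-S rates roughly two-fold, which should
be kept in mind when reading such profiles.

**Clusters.**  Maximal left-to-right chains with adjacent gaps ≤ 40 kb
(inclusive) and ≥ 5 origins; calling is deterministic, idempotent, and
monotone in both parameters.  The transition-point scan reports clusters
per genome (scaled by genome/analyzed length) as the minimum cluster size
varies from 2 to 10; the elbow is the boundary of the steep-then-shallow
two-segment least-squares fit, and the elbow *strength* is the one-line to
two-segment SSE ratio on log1p counts, where the geometric decay of
spurious chains in unstructured data is a single straight line (ratio ≈ 1).
On the calibrated generator the transition lands at 3–4, one step below
the minimum cluster size, where spurious sparse chains die out.

**Replicon classification.**  Each contiguous labeled block is one record:
EdU-only → newly fired; BrdU-containing with ≥ 1 progressive fork →
active; otherwise terminated/ambiguous (both edges merged, stalled, or
truncated by the molecule end).  Genome scaling multiplies per-molecule
counts by genome length over molecule length (molecules vary in length, so
length-ratio scaling, not molecule counting).

## Emergent counts and a known limitation

The island identity pins what the calibrated model can produce: the number
of simultaneously active replicons per genome is ≈ (1−f)·A(t)·G, which at
r: 2→8 /min/Mb and v = 2.8 kb/min peaks near 240–260 (the acceptance script
measures ≈ 240 through the full pulse/chase + combing readout), with
≈ 500–520 forks at peak, ≈ 90–150 distinct labeled blocks on ≥ 85%-
replicated molecules, and ≈ 7 active replicons per 100 kb of unreplicated
DNA late in S.  Experimental single-molecule reports for fission yeast of
350–400 simultaneous replicons, 700–800 forks, ~500 tracks on nearly
complete molecules, and ~10 replicons per 100 kb unreplicated are mutually
consistent with one another but not with these rate/velocity parameters:
reaching a 375-replicon peak at v = 2.8 kb/min would require a mid-S rate
near 18 /min/Mb, while the *integral* calibration is right — the model
fires ≈ 560 origins per S-phase, matching the ~500-origin scale of such
experiments.  The corresponding acceptance checks are therefore expected to
fail at the default parameters, and the parameters are deliberately not
adjusted to chase those counts.

Similarly, the in-silico 500-kb cutting experiment compresses the shallow
regime (median ≈ 100 → ≈ 80 kb) and visually straightens the semilog
survival curve, but at cohort sizes of ~2000 IODs the bootstrap likelihood
ratio still detects the residual mixture in essentially every replicate:
shortening molecules degrades but does not erase the two-regime structure
under formal model selection.

## What the generators do and do not emulate

They emulate: stochastic origin firing on unreplicated DNA, bidirectional
constant-velocity forks, pulse/chase labeling geometry, molecule-level
stretch noise, grid resolution, detection minima, fragmentation, and
planted clustering with known membership.  They do not emulate: sequence
context (no FASTA), chromatin state or a mechanistic cluster-feedback
loop (temporal cluster emergence is represented phenomenologically by
generating at a chosen replication extent), probe-detection errors
(false merges/splits of FISH signals), or inter-molecule heterogeneity in
stretch beyond a single factor per fragment.  Passing tests therefore
demonstrate correctness of the measurement stack on this generative
family, not the biological accuracy of the generative family itself.

## Numerical choices

* Coordinates are kb, 0-based, half-open [start, end); exactly two label
  channels.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.  Fixed seed ⇒
  byte-identical outputs (tested).
* Probe-signature matching tolerance defaults to 0.12 relative error
  (≈ 2× the stretch CV); two library matches within tolerance are
  ambiguous and unassigned rather than guessed.
* Zero-rate simulations terminate immediately rather than spinning (no
  firing and no forks means nothing can ever happen).
* Permutation and Monte-Carlo p-values use the (1+k)/(n+1) convention and
  report their resolution implicitly through n.
* Degenerate inputs: molecules with < 2 origins yield no IODs; survival
  curves require ≥ 2 values; the two-regime fit requires ≥ 50; the
  Lilliefors test requires ≥ 10; constant velocity vectors short-circuit
  the density correlation to 0.

## Problem sizes

Default study-scale computations: 131 molecules × 1.8 Mb for IOD cohorts;
10,000 Lilliefors null draws; 500 bootstrap replicates for model preference
(199 in the test suite); 20 simulated S-phases for kinetic summaries in the
acceptance script (8 in the test suite); 20 seeds for recovery experiments.
A full whole-genome S-phase simulates in ~30 ms, so the entire acceptance
computation completes in seconds.
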
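# Methods

This note documents the model implemented by `ahnet`, the design choices
made where the published description leaves the mechanism open, the
synthetic study conditions, and the known limitations.

## The AHN regression model

A saturated linear artificial hydrocarbon compound partitions a scalar
input axis [L_0, L_n] into n intervals, one per CH-molecule. Molecule j
carries a polynomial φ_j(x) = σ_j ∏_i (x − H_{ij}); the compound behaviour
ψ dispatches x to the owning molecule. Interval conventions: all
intervals are half-open [L_{j−1}, L_j) except the last, which is closed;
inputs outside [L_0, L_n] extrapolate with the nearest end molecule. The
chain is CH3–CH2–…–CH2–CH3, so outer polynomials are cubic and inner ones
quadratic (the valence bound k ≤ 4 is enforced but the saturated linear
family never reaches it).

The canonical parameterisation of a molecule is its **real coefficient
vector**; σ (leading coefficient) and the hydrogens (roots, possibly
complex-conjugate pairs) are derived views. Least-squares fitting is
linear in coefficient space, while roots are well-defined but unordered
and possibly complex; we sort them by (re, im) for reproducibility and
verify root-product vs. coefficient evaluation agree to 1e-9.

### Training loop

Per sweep:

1. bounds from the positive width shares r (cumulative shares mapped onto
   [min z, max z]; any positive rescaling of r gives identical bounds);
2. per-interval least-squares polynomial fit, with the degree reduced to
   (m − 1) on intervals holding only m ≤ degree samples; an *empty*
   interval inherits its previous molecule, or on the first sweep a
   constant equal to the nearest fitted neighbour's value at the shared
   edge;
3. molecule energies = per-interval mean squared error (MSE rather than
   summed error keeps the width updates comparable between unevenly
   occupied intervals);
4. global RMSE; the best compound seen so far is retained;
5. width update (below), with a collapse floor of 1e-3 of the total span
   and rescaling to preserve the total width.

Stopping: RMSE ≤ ε, or `max_iterations` sweeps (default 200). The
returned compound is the best encountered, so the result is never worse
than the first sweep even when the width dynamics oscillate. Identical
data and config give bit-identical results; the only randomness is the
seeded uniform(0.5, 1.5) initialisation of the width shares.

### The width update

The published update Δr = −η(E_{t−1} − E_t) relates a pair of adjacent
molecules but does not pin down *which* interval's width it moves — and
the choice matters. Implemented exactly on the right interval of each
pair, the rule widens whichever interval fits worse and training error
increases monotonically on noiseless piecewise data. We therefore apply
the printed step to the **left** interval of each pair and its opposite
to the right interval:

```
r_{t-1} ← r_{t-1} − η (E_{t−1} − E_t)
r_t     ← r_t     + η (E_{t−1} − E_t)
```

i.e. every shared bound hands territory from the worse-fitting molecule
to the better-fitting one, and equal energies leave the partition fixed.
The net per-interval step is r_t ← r_t − η((E_t − E_{t−1}) + (E_t −
E_{t+1})) with one-sided terms at the chain ends. At the true partition
of in-family data all energies vanish, so the true bounds are a fixed
point; empirically the loop recovers exact breakpoints of a noiseless
3-piece cubic/quadratic/cubic fixture from every initialisation seed we
tried, while both single-sided variants stall or diverge.

Clamping order: clamp to the floor, rescale to preserve the total, clamp
once more. After a hard clamp the total can exceed its previous value by
at most one floor width.

## The classifier

Labels are sorted deterministically and coded 1..J; the compound (n = J
molecules by default — an empirical, user-overridable choice) regresses
the projected feature axis onto the codes; ψ(z) decodes to the nearest
integer code with half-codes rounding down (2.5 → 2) and clipping to
[1, J]. Defaults η = 0.1 and ε = 1e-4 follow the benchmark configuration
(18 molecules, η = 0.1, ε = 1e-4).

**Projection.** The piecewise machinery is one-dimensional, so
multivariate features are reduced to the first principal axis of the
centered feature matrix, with the largest-magnitude loading forced
positive so the axis orientation is reproducible. Per-column
standardization before the axis extraction is available
(`standardize=True`, appropriate when features mix units) but is *not*
the default: when class clusters are isotropic, each column's standard
deviation is dominated by the between-class spread, so standardization
divides exactly the high-signal columns the hardest. On the 18-class
benchmark below it compresses the projected class separation from 6σ to
roughly 3.3σ and caps even a perfect piecewise fit near 90 % accuracy.
A single named feature can also serve as the axis by selecting it as the
only feature column.

## Evaluation protocol

* **Metrics** — confusion matrices are oriented rows = predicted,
  columns = actual. Sensitivity (recall) is diag/column-sum, precision
  diag/row-sum; macro averages weight classes equally, micro averages
  aggregate TP/FP/FN first. For single-label data micro sensitivity =
  micro precision = accuracy, a property the tests enforce. Classes with
  an empty row or column contribute 0 to macro means and are flagged.
  Cross-experiment summaries use the mean and the **population** (÷n)
  standard deviation; this convention is pinned by recomputing the
  published summary rows, which match ÷n and not ÷(n−1).
* **Noise protocol** — a fraction p of all feature cells of the *test*
  matrix (jointly, labels untouched) is deleted uniformly at random —
  exactly ⌊p·Q·N⌋ cells — then every missing cell is replaced by its own
  column's observed mean from the corrupted matrix itself. One corrupted
  matrix is fixed per (fraction, seed).
* **Windowed recognition** — fixed-rate streams are cut into
  non-overlapping windows (default 250 samples = 2.5 s at 100 Hz; a
  trailing partial window is dropped), every sample is classified, and
  each window reports the majority label, ties going to the smallest
  code. Ties are rare at 250 samples; the tie rule only matters for
  degenerate windows.

## Synthetic study conditions

The generators are pure functions of (spec, seed):

* `gen_piecewise` — scalar samples from a known piecewise polynomial in
  the model family; the recovery fixture is a 3-piece
  cubic/quadratic/cubic on [0, 3] with breakpoints at 1 and 2, 600
  noiseless samples.
* `gen_classes` — J = 18 Gaussian classes, 200 samples/class, N = 51
  features (the PAMAP2 feature-table shape), class means spaced
  `axis_separation` = 6 apart along a fixed latent unit direction u with
  isotropic unit noise (separation/noise = 6). u depends only on the
  spec seed; a `noise_seed` argument yields independent draws from the
  same distributions, which is how train/test pairs are made.
* `gen_streams` — one 30-s, 100 Hz stream per (subject, activity) from
  the same class distributions (same u, disjoint noise substreams keyed
  by subject and activity).

What passing these conditions shows — and does not. The synthetic
geometry places classes *in order* along one latent direction, which is
precisely the structure the numeric-label scheme assumes; real sensor
classes are not ordered on a line, class covariances are anisotropic and
features are autocorrelated in time. Synthetic results therefore
demonstrate the correctness and internal consistency of the machinery
(recovery, decoding, voting, protocol arithmetic), not field performance
on real IMU data. In particular the noise protocol degrades the
synthetic classifier much faster than the published benchmark classifier,
because here *every* feature carries signal and mean-imputation pulls
samples toward the global centre of the latent axis.

Problem sizes used by the test suite and the acceptance script (3600
training rows, 600 recovery samples, 2–8 simulated subjects) are the
package's default study sizes; all complete in seconds on one CPU.

## Published reference data

`ahnet.benchmarks` stores the published AHN benchmark results that the
consistency checks recompute from: the 315,000-sample confusion matrix of
the first-30-s experiment (accuracy 0.9845, macro sensitivity 0.9844
when recomputed from raw counts), the windowed confusion diagonal (12
windows per performing subject), and the per-experiment accuracy/F1
scores behind the summary means. The published micro-precision and F1
columns of those tables are not reproducible from their own confusion
matrices under the standard micro-averaging definitions (e.g. a printed
micro precision of 0.9991 alongside an accuracy of 0.9845, which standard
micro-averaging forces to be equal); the package implements the standard
definitions and anchors its checks only to the self-consistent quantities
(accuracy, macro sensitivity, the summary means and population standard
deviations).

## Limitations

* One compound only (c = 1): mixtures exist for evaluation but are never
  trained jointly; no branched or unsaturated chains.
* The scalar projection is this package's documented choice; the original
  multivariate mechanism is not specified in the source material and may
  differ.
* No overlapping-window feature extraction and no online operation; the
  windowed pipeline is batch.
* The width-update dynamics are a heuristic: they provably fix the true
  partition of in-family data but carry no general convergence guarantee;
  best-state tracking bounds the damage when they oscillate.
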
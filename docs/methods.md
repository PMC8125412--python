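# Methods

## The gaze-based measure

For each frame `t`, all valid gaze points of all observers within the
temporal window `[t − θt, t + θt]` (clipped to `[1, T]`) form an anonymous
bag `P_t`; the score is the fraction of unordered point pairs whose
Euclidean distance is strictly below `θs`. It is a normalised pair-count in
the spirit of Ripley's K statistic: it detects spatial aggregation without
clustering, and discarding observer identity makes it invariant to
permuting observers or points.

Assumptions worth stating:

- **Normalized coordinates.** Gaze is divided by frame width and height, so
  `θs` is comparable across videos. For non-square frames the induced
  metric is anisotropic (0.1 spans 192 px horizontally but 108 px
  vertically on FullHD); this is accepted as the price of scale-free
  thresholds.
- **Pair normalisation.** The sum runs over unordered pairs with the
  `2/(n(n−1))` factor, which is what keeps `s(t) ∈ [0, 1]`.
- **Degenerate windows.** A bag with fewer than two points carries no
  consistency evidence; it scores 0 and a warning is logged. Dividing by
  zero pairs is thereby avoided, and a video with no gaze data scores flat
  zero rather than failing.
- **Boundaries.** Windows are clipped, not padded, so the output has
  exactly `T` values; boundary frames simply pool fewer points.
- **Strictness.** The indicator is `d < θs` (strict), so coincident points
  always count and points exactly at the threshold never do.
- **Missing data.** Invalid samples (blinks, dropouts) are removed before
  windowing; no interpolation. The pair normalisation tolerates variable
  `n`. Off-screen gaze is retained by default — looking away is itself
  evidence of inconsistency — but counted, reported, and removable
  (`drop_off_screen`, `--drop-offscreen`).
- **Frame aggregation.** Raw tracker samples (e.g. 500 Hz against 25 fps
  video) are averaged per observer within each frame's half-open time
  interval `[(t−1)/fps, t/fps)`. Frames are 1-based throughout; one
  position stream per observer is ingested (no binocular fusion).

### Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `θs` | spatial scale, normalized distance threshold | 0.1 | ~10% of the frame: separates object-level agreement from background scatter; smaller values sharpen peaks, larger ones lift the whole curve |
| `θt` | temporal half-window, frames | 5 | 11-frame (~0.4 s at 25 fps) pooling; larger values smooth the score (total variation decreases monotonically in our tests) |
| `pmax` | subsets sampled per size in convergence analysis | 400 | caps the cost of the combinatorial protocol while keeping standard errors small |

### Implementation

The scorer caches close-pair counts within each frame and between each
frame pair up to lag `2θt`, then assembles every window score from the
cache, so each distance is measured once (O(T·θt·N²) overall). The cached
path is tested for exact equality against a literal double loop over all
unordered pairs on random small datasets — not approximate agreement.

## Map-based scorers

Given nonnegative per-frame maps `S(x, y; t)`:

- **MutualInfo** averages the mutual information between the map at `t`
  and each neighbour in the window, excluding the `k = 0` self-term: the
  self-MI equals the map's entropy and would inflate every frame by a
  content-independent amount, and excluding it makes the divisor equal the
  term count. MI is estimated from a joint histogram after linear
  quantization over the sequence's global value range; 64 bins per
  variable by default. The estimate is in bits.
- **MaxValue** is the global maximum of the map rescaled by its declared
  value scale (1.0 for float maps, 255 for 8-bit), so outputs are
  comparable across encodings.
- **Spread** weights the map by a Gaussian centred at its intensity
  centroid and normalises by total mass, giving the mass-weighted mean
  kernel value. The kernel peak is 1 (not unit mass) so a perfectly
  concentrated map scores exactly 1; it is evaluated over the whole map,
  with the conventional odd window side `ℓ = 2⌈2σ⌉ + 1` retained as
  metadata only. The bandwidth `σ = W·θs/2` ties the kernel to the same
  spatial scale the gaze measure uses. Zero-mass frames score 0 with a
  warning.
- **Points** thresholds each map (Otsu by default — parameter-free — or a
  fixed fraction of the maximum), takes the centroids of the 8-connected
  components, normalises them to `[0,1]²`, and feeds them to the same
  windowed pair-consistency scorer as surrogate gaze points. Centroids are
  normalised because `θs` is defined in normalized units.

## Comparison metrics

Length-normalized Euclidean distance `d`, mean pointwise Jaccard (IoU)
with the `0/0 → 1` convention (two signals asserting "no salience" at a
frame agree), soft precision/recall `I/S`, `I/R` with
`I = Σ min(s, r)` (reported as undefined when the corresponding mass is
zero), Spearman ρ with average ranks and Kendall τ-b (tie-corrected;
undefined for constant signals). Binary references are built from
changepoint lists by marking frames within a tolerance (default `θt`
frames; the choice is configurable since no canonical value exists) of any
changepoint. Signals from external sources can be min–max normalised to
[0, 1] before comparison. Bootstrap 95% intervals (frame resampling,
seeded) are available from the `compare` command.

## Observer convergence

For each subset size `k`, `min(pmax, C(N, k))` distinct k-observer subsets
are used — enumerated exhaustively below the cap (no sampling noise),
drawn uniformly without replacement above it — and the distance
`d(s_k, s_N)` to the full-panel score is averaged. Subsets are distinct
because the protocol counts combinations; standard errors are reported
alongside the means. At `k = N` the only subset is the full panel and the
distance is exactly 0.

## Synthetic data

The generator emulates the structure the measure is designed to detect: a
scripted attractor trajectory in `[0,1]²`, a per-frame attended fraction
`alpha(t)`, attended gaze = attractor + isotropic Gaussian jitter
(`cluster_sd`, clipped on-screen like fixed-display viewing), unattended
gaze uniform. Each observer's attending state is a two-state Markov chain
(kept with probability `1 − switch_prob`, else re-drawn as
Bernoulli(`alpha(t)`)), giving the per-observer temporal autocorrelation
real gaze has; this persistence is what reproduces the small-panel
overestimation tendency (`mean s_k ≥ mean s_N` for `k < N`). Matching map
sequences place a Gaussian blob (σ = `blob_sd` px) at the attractor,
scaled by `alpha(t)`, over nonnegative clipped Gaussian noise.

Defaults describe a mid-sized study: 20 observers, 200 frames at 25 fps,
`alpha = 0.7`, `cluster_sd = 0.03`, `switch_prob = 0.1`, 96×54 maps with a
4 px blob and 0.05 noise. What the generator does **not** emulate:
saccade/fixation dynamics, tracker noise spectra, centre bias, or any
dependence on video content. Tests passing on this synthetic structure
show the measure behaves as specified when its assumptions hold; they do
not certify behaviour on real recordings with systematic biases.

The analytic oracle for the no-attention regime is the closed-form
probability that two i.i.d. uniform points in the unit square lie closer
than `θs`: `π θs² − (8/3) θs³ + θs⁴/2` (valid for `θs ≤ 1`; the corner
regime `θs > 1` is out of scope). Under purely uniform gaze, the expected
score equals this probability; simulations agree within Monte-Carlo error.

## Numerical and design choices

- Uniform-limit checks use replicate simulations and compare the grand
  mean within 3 standard errors of the replicate means, because window
  overlap autocorrelates `s(t)` and a per-frame standard error would be
  too optimistic.
- The gaze-versus-Points consistency check uses a scenario whose attended
  fraction sweeps its range smoothly, so both signals traverse low and
  high salience regimes; with a constant or hard-switching `alpha`, rank
  correlations are dominated by within-plateau noise.
- Convergence trend assertions allow `2·stderr` slack between consecutive
  subset sizes, since adjacent means share sampling noise.
- Problem sizes in tests and the acceptance script (panels of 8–20
  observers, 40–300 frames) are chosen to make the statistical behaviour
  unambiguous while keeping runs fast; the measure itself is O(T·θt·N²)
  and handles full-scale recordings (58 observers, ~450 frames) without
  difficulty.
- Scores are written with 6 decimals; round-tripping a series through the
  CSV format is exact to 1e-6. PNG map export quantizes to 8 bits.

## Known limitations

- The measure says nothing about *where* attention is, only how consistent
  it is; two tight clusters far apart still score low (by design — the
  two-blob worked example scores 0.4, not 1).
- Few observers overestimate salience; the full-panel score is the
  conservative reference, and panels below ~5 observers should be
  interpreted with the convergence curve in hand.
- MI estimates carry upward histogram bias on small maps; shuffled-pixel
  controls bound it in the tests.
- The anisotropic normalized metric slightly favours horizontal proximity
  on wide frames.
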
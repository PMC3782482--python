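# Methods

## Scoring model

A frame is scored in chamber coordinates at 1 frame per second. The
analysis rate matters: all downstream metric definitions (block means,
cumulative indices, the per-fly maximum of 150 frames per 2.5 min) assume
1 fps, so `load_frame_sequence` down-samples any faster source by keeping
the first frame of each 1-s bin. First-frame selection (rather than bin
averaging or codec decimation) is a deliberate choice: it is deterministic,
idempotent, and avoids motion blur in the synthesized frame.

### Background

The static background is the pixel-wise mean of `n = 40` frames sampled
uniformly without replacement with a caller-supplied seed. The mean (not
median) is used; it converges to the empty chamber as long as flies keep
moving, and residual "ghosts" from lingering flies are tolerated because
Otsu's threshold is computed per frame on the difference image. If fewer
than `n` frames exist, all are used and a warning is logged.

### Segmentation

Flies are darker than the backlit chamber, so the foreground signal is
`background − frame` clipped at zero. Otsu's method binarizes this
difference image (not the raw frame: the raw image's bimodality is
dominated by chamber walls). 8-connected components within
`[min_area, max_area]` become silhouettes.

Area bounds derive from body statistics: a fly is ~2.27 mm long, i.e.
~19 px at the 0.12 mm/px scale, with a silhouette of roughly 110 px².
`min_area` defaults to 40 px² (debris rejection). `max_area` defaults to
1.6× the median component area of the frame. The multiplier must lie
strictly between one and two body areas, because a blob of two touching
flies is at most twice — and with overlap often only ~1.7× — a single
fly's area; 1.6 leaves headroom for segmentation noise on singles while
still catching substantially overlapping pairs. Blobs above the bound are
flagged merged and split by k-means on pixel coordinates into the number
of flies the chamber is known to hold but which are unaccounted for.

### Pose

Centroid and body axis come from image moments: the principal eigenvector
of the pixel-coordinate covariance matrix gives the (unoriented) axis, and
full axis lengths are `4·√λ`, exact for a uniform solid ellipse. A blob
whose eigenvalue ratio is below 1.2 is flagged degenerate — its axis
direction is numerically unstable — and is excluded from chain-region
construction for that frame (it can still be chased).

Head/tail disambiguation uses the Harris & Stephens corner response: the
abdominal tip is sharper than the head, so of the two major-axis endpoints
the one with the larger maximal response within a 3-px radius is the tail.
The response is computed on the binary silhouette smoothed with a Gaussian
of σ = 1 px, evaluated on a 3× block-replicated grid (σ scaled
accordingly). The supersampling step exists because the abdominal tip is
only a few pixels wide: at native resolution its corner response is
dominated by rasterization staircase, which costs roughly 7 points of
head/tail accuracy on the pose-recovery suite. When the two responses
differ by less than 10% and a previous-frame pose is available (nearest-
centroid matching), the assignment minimizing heading change wins; with no
history the corner rule decides. A degenerate blob with no history gets an
arbitrary assignment flagged unreliable.

Known limitation: for silhouettes rendered at exactly integer centres with
headings near ±30°/±60°, the tail tip can rasterize into a blunt end and
the corner rule inverts confidently. Random (sub-pixel) positions make
this a measure-zero event — accuracy on uniformly random poses is ~98.5% —
and in video the temporal tie-break suppresses isolated flips only when
the response gap is small, so occasional single-frame errors remain.

### Chain region and index

The chain region is a circular sector anchored at Q, the point on segment
TH at `q_offset` = 5 px (0.6 mm) behind the head: a point p is inside iff
`0 < |p − Q| ≤ q_offset + L` and the angle between `p − Q` and `H − T` is
at most `k·π/2`, boundaries inclusive. With the defaults `L` = 13 px and
`k` = 0.66 the fan extends exactly `L` beyond the head along the axis with
a ±59° half-angle. The region is implemented behind a single predicate
(`chain_region_contains`) so the parameterization can be swapped without
touching the graph logic.

Edges are directed: i→j iff any pixel of fly j's body (its silhouette
pixel set; the rasterized fitted-ellipse interior when no silhouette is
available) lies in fly i's region. A fly's own body is excluded; mutual
edges are allowed and each fly counts once. The chain index is the number
of distinct flies incident to at least one edge, so a single chasing pair
scores 2 — passive recipients count.

## Metrics

All metrics assume the 1-Hz series. Smoothing is non-overlapping 10-frame
block means (final partial block averaged over what it contains).
Cumulative indices sum over half-open windows `[start, end)`. The chain
probability divides the cumulative index by `n_flies × window_frames`
(150 per fly for 2.5 min), and the angular transform is
`arcsin(√p)` — the standard variance-stabilizing transform for
proportions; the package adopts it explicitly since proportions near 0
and 1 otherwise compress differences. Rates are `(AC₂ − AC₁)/AC₁`,
undefined (an error, not NaN) when AC₁ = 0.

Protocol windows: the suppression pair is `[311, 371)` vs `[1431, 1491)` s
— the minute starting 11 s after playback onset and the last full minute
of the first continuous playback — read as half-open 60-s intervals so all
five protocol phases are exactly one minute. Recovery and drop pairs are
the minutes immediately before/after the song shifts at 25 min
(continuous→intermittent) and 40 min (intermittent→continuous). The
three-phase trio for the 12-min assay is silent `[240, 300)`, immediate
`[311, 371)`, later `[660, 720)`; the later window is pinned to the final
minute of the recording since only the onset window is printed anywhere.

## Stimuli

A pulse is `cycles / carrier` seconds of sine (default 2 cycles; 11.98 ms
at 167 Hz) with a 10% cosine taper per end to avoid clicks. Pulse onsets
sit at multiples of the IPI starting at the burst start, and a pulse must
end within its burst. The 2-cycle convention is the unique simple pulse
length under which one counting rule yields 66, 29 and 10 pulses per 1-s
burst at 15, 35 and 105-ms IPI simultaneously; it is overridable
(`pulse_cycles`). Fixed-pulse-count mode stretches the burst instead
(29 pulses at 105-ms IPI span 2.95 s). The oscillating-IPI schedule
evaluates `mean + half_range·sin(2πt/period)` at each pulse time
(phase-continuous across bursts); sampling at pulse times slightly
oversamples short IPIs, so the sample mean sits ~1% below the sinusoid
mean — intrinsic to the construction, not a bug. WAV output is 16-bit PCM.

## Synthetic scenes

The generator emulates what the scorer actually consumes: dark teardrop
silhouettes (~19 × 8 px, the posterior half tapering to a point so the
corner rule has a real signal — tail:head Harris ratio ≥ 1.5) on a light
background (intensities 60 on 220) in a 417 × 83 px chamber (50 × 10 mm at
0.12 mm/px), up to 6 flies, optional Gaussian intensity noise from a
seeded generator. Scenarios: `idle` (separated, static), `dispersed`
(random walk at ~8 px/s, a walking fly's speed at this scale, with
rejection sampling to keep silhouettes apart), `chain_train(n)` (a
head-to-tail train with 10-px gaps, extras parked out of range).

It does **not** emulate: wings and legs (real silhouettes are noisier at
the body outline), occlusion by chamber walls, illumination gradients,
shadows, or realistic locomotion dynamics. Passing end-to-end tests
therefore demonstrates the geometry/scoring chain and robustness to
sensor-style noise, not performance on real video artifacts.

The ground-truth chain index comes from a brute-force oracle that
rasterizes every fan over the full chamber grid (whole-grid `atan2`
formulation) and intersects pixel sets with body masks — authored
separately from the analytic predicate precisely so the equivalence test
between the two routes is meaningful.

## Problem sizes in tests

The validation suite uses 200 random single-fly frames for pose recovery,
100 random 6-fly configurations for oracle equivalence, 60-frame dispersed
scenes for end-to-end agreement and 232-s songs (four oscillation periods)
for the IPI-oscillation spectral check — sizes at which the estimates of
interest (medians, proportions at the 95% level, autocorrelation peaks)
are stable across seeds.
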
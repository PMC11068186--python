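# Methods

This note documents the models and procedures implemented in `iotrack`,
the choices made where the design was genuinely open, and what the
synthetic tests do and do not demonstrate.

## Linked data

Both streams are aligned on a fixed epoch grid (default 5 s). GPS
timestamps are rounded half-up to the nearest epoch; when two raw fixes
round to the same tick the earlier raw fix is kept (deterministic and
order-independent). The linked track is *total*: one row per tick over the
union of both streams' spans, with explicit missing positions, so gap
handling is visible rather than implicit. The epoch length is a
configuration value; every duration threshold is stored in minutes and
converted internally, so other sampling rates work unchanged.

All geometry stays in WGS84. Metric distances use the haversine formula on
a 6,371,000 m sphere; cluster-scale computations use a local
equirectangular projection around the track's mean latitude. At the ≤30 m
scales involved and |lat| < 85° the two differ negligibly, which is why no
full geodesic library is pulled in.

## Preprocessing

Two device pathologies are repaired before clustering:

- **Teleports** (multipath throwing one fix far away): a fix is flagged as
  noise when the implied speed both into and out of it exceeds
  `max_speed_mps` (default 40 m/s — well above road speeds, so legitimate
  driving is untouched). The bidirectional test deliberately spares the
  single fast step created by a genuine relocation. The scan repeats with
  flagged fixes removed until no new flags appear, making the operation
  idempotent.
- **Dropouts**: runs of missing positions no longer than
  `max_gap_impute_s` (default 300 s) bounded by observed fixes are filled
  by linear interpolation of lat/lon against time and marked
  `source=imputed`. The 5-minute cap intentionally equals the clustering
  algorithm's temporal tolerance so that imputation and clustering agree
  about which interruptions break a dwell. Observed fixes are never
  altered.

Speeds are (re)computed after imputation so imputed fixes carry finite
speeds.

## Destination detection

ST-DBSCAN with a conjunctive space–time neighbourhood: points are
neighbours when within `eps_space_m` (30 m) **and** within `eps_time_s`
(300 s). A point is core when its neighbourhood, itself included, holds at
least `min_pts` (12) points — with the point itself counted, twelve
5-second points spanning 55 s yield a cluster of exactly one minute.
Expansion is standard DBSCAN, scanning points in time order; border points
join the first cluster that reaches them. The implementation is validated
against a brute-force evaluation of the density-reachability definition
(neighbourhood counts, core-graph connected components, earliest-component
border assignment) on randomized tracks.

Cluster `InstanceTime` is the closed span `t_end − t_start + epoch_s`, in
minutes, rather than the bare span — this makes the 12-point/one-minute
arithmetic exact. Clusters whose mean centres lie within `area_merge_m`
(default: the spatial radius, 30 m) of each other merge transitively
(single-linkage) into an area; the area centre is the unweighted mean of
member-cluster centres and `AreaTime` is the sum of member instance times.
Cluster mean centres are planar means of lat/lon, adequate at these
extents.

## Classification cascade

Filter inequality senses follow their plain reading: F1 inclusive
(≥ 30 min), F2 strict (> 15 min, > 30 min), F3 inclusive (≤ 10 m,
≥ 15 min), F4 inclusive duration with strict speed (< 0.9 m/s), F5 and the
park test strict majority (> 50 %) with the mean centre also required
inside. Point-in-polygon treats the boundary as inside, so points snapped
onto a footprint edge behave deterministically. The lux correction is
strict (> 240 lx) and runs before the park correction; the ordering is
observable only in rule provenance, never in labels. Clusters with no lux
data skip the lux check rather than failing it.

Vehicle detection aggregates per-epoch speeds into 60-s windows aligned to
the track's first epoch (alignment had to be fixed somewhere; the first
epoch is the only distinguished tick). A window's mean of non-missing
speeds strictly above 6.944 m/s (25 km/h) flags all of its epochs.
Bout bridging relabels a non-driving run strictly shorter than 3 min whose
flanking driving bouts include one strictly longer than 2 min; it iterates
to a fixed point so a bout grown by one bridge can support the next — a
single left-to-right pass would miss chained traffic-light stops.

Where an epoch qualifies as both indoor-cluster member and driving-minute
member, indoor wins (precedence indoor > vehicle > outdoor): a point dense
enough to sit in a 30-m dwell cluster for many minutes cannot be
mid-drive, whereas fast minutes frequently clip dwell edges. Every epoch
receives exactly one label and the rule that produced it
(F1–F5, LUX, PARK, DRIVE, DRIVE-BRIDGE, DEFAULT-OUT). With no building or
park layers supplied the pipeline still labels every epoch; the skipped
steps are recorded in the run manifest.

## Validation

Diary segments are half-open intervals `[start, next_start)`; the last
runs to the end of the track, and epochs before the first segment are
excluded with a warning. The confusion summary reports user's accuracy
(precision), producer's accuracy (recall), overall accuracy and unweighted
Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the matrix marginals.
Accuracies of empty classes are reported as undefined (NaN), never as 0.
Because driving is often excluded from indoor/outdoor exposure summaries,
a two-class view drops epochs that are vehicle in either truth or
prediction; the three-class matrix is always available alongside. The
implementation is cross-checked in the tests against scikit-learn's
`cohen_kappa_score`/`precision_score`/`recall_score` on random labelings.

## Synthetic worlds and protocols

`make_world` builds a campus-like scene: four rectangular buildings
(~30–45 m sides, one flagged glass-walled), an 80 m × 80 m park, an open
plaza, and a straight 6-km road kept > 50 m from the buildings. Geometry
is deterministic given the seed (small jitter on building placement).

`simulate_track` emulates a two-hour wear protocol of five activities
(indoor walk, outdoor stationary, indoor stationary, outdoor walk, drive),
each a diary segment with a truthful start time. Noise model, per epoch:

- isotropic Gaussian position jitter, σ = 3 m outdoors / 8 m indoors
  (defaults; the *low-noise* variant used for recovery benchmarks is
  1.5 m / 3 m with no multipath and 1 % dropout — open-sky conditions);
- indoor multipath excursions: with probability 0.02 a run of 2–6 fixes is
  displaced 25–70 m outside the building at high implied speed;
- indoor dropouts with probability 0.05 (fix absent, accelerometer epoch
  retained);
- GPS timestamps uniformly jittered ±1 s off-grid to exercise rounding;
- lux lognormal with median 100 lx indoors and 5000 lx outdoors
  (σ_log = 0.5), straddling the 240-lx ceiling; dwells in the glass-walled
  building draw the *outdoor* distribution, exercising the lux
  correction's false-positive path;
- activity counts Poisson by behaviour (ambulatory ≫ sedentary), not
  integrated from raw accelerations.

Walks move at 1.4 m/s along an exact-length two-leg detour: the turn point
lies on the ellipse whose foci are the segment's endpoints and whose major
axis is the distance walked, so arrival is exact and departure from
buildings is prompt. The first/last minute of a walk bordering an indoor
segment draws that building's lux (corridor/doorway), reflecting that a
"walking outdoors" diary segment physically begins inside the previous
building. Drives run out-and-back along the road at 12 m/s with one 90-s
2 m/s slowdown (a long traffic light) so bout bridging is exercised in
every scenario; the drive is placed last in the default protocol so the
track ends on the road. Segment durations are whole minutes, as diary
protocols are in practice.

The *sensitivity* protocol adds the configurations the optional filters
exist for: a 10-min dwell in a normal building and one in the glass-walled
building (both too short for the duration filters — only the footprint
overlay can catch them) and a 30-min stationary bout on the plaza, which
the duration filters wrongly mark indoor and only the lux correction can
rescue (the plaza is deliberately outside the park layer). Removing the
footprint filter loses the normal short dwell; removing the lux correction
loses the plaza bout (more epochs than the glass dwell it would win back);
removing the park correction changes nothing in this world — so the
sensitivity experiment reproduces the expected directions.

**What passing does not show.** The generator's GPS errors are isotropic
and memoryless; real multipath is street-canyon-structured and
autocorrelated. Lux is independent per epoch with clean indoor/outdoor
separation; real sensors are shaded by clothing and weather. Diaries are
exact by construction; real diaries carry entry errors. Recovery rates on
synthetic sessions are therefore an upper bound on field performance and
validate the *machinery* (clustering, cascade, metrics), not the field
accuracy of the method, which must come from wear studies.

## Problem sizes

Recovery and sensitivity benchmarks use ten seeded sessions each of 1,440
epochs (two hours at 5 s) — comparable to one participant-session of the
motivating protocol, and enough that every rule of the cascade fires on
every run. The clustering implementation is O(n²) in positioned epochs,
entirely adequate at this scale (a session clusters in well under a
second).

## Known limitations

- Only one vehicle class: buses, trains and cycling above 25 km/h all
  read as "vehicle".
- The noise/imputation rules are simple (bidirectional speed gate, linear
  interpolation); no Kalman smoothing or map matching. Both are
  config-exposed so stricter front-ends can replace them.
- Area merging uses mean-centre single linkage with a 30-m radius; two
  wings of a very large building can still land in different areas, which
  weakens F2/F3 for such venues.
- The lux correction uses the cluster mean; a per-point variant may suit
  devices with noisier light sensors.
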
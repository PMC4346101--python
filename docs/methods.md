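# Methods

## Detection model

The detector is a threshold state machine over a uniformly sampled (100 Hz)
triaxial acceleration stream expressed in g-units:

1. **CALIBRATE.** The trace must open with a stillness window — `still_window_s`
   = 0.5 s in which every sample's sum acceleration `|a|` lies in the gravity
   band `(0.7, 1.3) g` — before any sample reaches the impact threshold.  The
   mean axis vector over that window is **g**<sub>before</sub>.  A trace
   without such an opening raises a calibration error naming the required
   duration and band.
2. **MONITOR.** Watch for `|a| ≥ a_threshold` (2 g).
3. **IMPACT / SETTLE.** From the impact sample, search the next
   `t_threshold` = 2 s for the earliest stillness window (same criterion as
   calibration, fully inside the search span).  Its mean vector is
   **g**<sub>after</sub>; the running peak of `|a|` up to that window is the
   event's peak.  If no window appears the event is emitted as a non-alarm
   with `reject_reason = no_settle`.
4. **DECIDE.** θ is the rotation angle of **Q** = **Q**₃ ⊗ **Q**₂ ⊗ **Q**₁
   (below); alarm iff `|θ|` lies strictly inside `angle_band` = (60°, 120°),
   i.e. 90° ± 30°, the slack absorbing ground tilt and lying posture.
5. **REFRACTORY.** Monitoring resumes at the first sample after the settle
   window (or after the search span when none was found), so one impact's
   oscillation cannot be double-counted.  Events are therefore
   non-overlapping and time-ordered, and the whole detector needs only a
   bounded 2 s lookback — the same logic can run on-device.

"The fluctuation has stopped" is deliberately operationalised as the same
band criterion used for gravity capture: it is the only quantitative
definition the thresholds support, and it makes g-capture and settling one
primitive.  **g**<sub>before</sub> is captured once per trace; periodic
re-calibration during long upright stillness is a plausible extension but is
not enabled, because a detector that silently re-bases its reference would
be harder to audit.

The acceleration-only baseline shares the whole pipeline (impact
segmentation, settling, refractory behaviour) but alarms on the impact
threshold alone and never computes θ, so its event counts are directly
comparable.

## Quaternion decomposition

Gravity is treated as a pure quaternion `g = 0 + gx·i + gy·j + gz·k`.  With
ĝ<sub>b</sub>, ĝ<sub>a</sub> the unit before/after directions, elevation
`e = arctan(gz / √(gx²+gy²))` and azimuth `φ = atan2(gy, gx)`:

- **Q**₁ rotates by θ₁ = e<sub>b</sub> about the horizontal axis
  `(−gy, gx, 0)/√(gx²+gy²)` (direction cosines sin α, cos α), flattening
  ĝ<sub>b</sub> into the x–y plane;
- **Q**₂ rotates by θ₂ = φ<sub>a</sub> − φ<sub>b</sub> (wrapped to
  (−180°, 180°]) about k;
- **Q**₃ rotates by θ₃ = −e<sub>a</sub> about the corresponding axis of
  ĝ<sub>a</sub> (cosines sin β, cos β), tilting back up.

The composition maps ĝ<sub>b</sub> onto ĝ<sub>a</sub> exactly (property
tests verify a residual < 1e-9 over random pairs, and < 1e-15 is typical).
The total angle is `θ = 2·arctan(|q_vec|/q0)`, evaluated with signed q0 and
without canonicalising quaternion sign, so θ ∈ (−180°, 180°] and comes out
negative when q0 < 0 — backward/rightward falls typically report negative
angles.  q0 = 0 returns exactly 180°.  Inputs are normalised first (the
angles depend only on direction), which removes sensitivity to the ±0.3 g
capture tolerance.

**Degenerate inputs.** When gravity is within ~1e-8 of ±k the horizontal
norm vanishes and α (or β) is 0/0 in the formulas.  The axis is then taken
as j, the azimuth as 0, and a degeneracy flag is recorded instead of
raising: the limit rotation is well-defined up to azimuth and the composed
**Q** still maps ĝ<sub>b</sub> to ĝ<sub>a</sub>.

**Frame dependence — a real limitation.** θ is the angle of this particular
three-stage factorisation, not the geodesic angle between the two gravity
directions.  The two coincide when the standing gravity lies in the device's
x–y plane and the rotation is about k, but in tilted frames θ is inflated:
e.g. ĝ<sub>b</sub> = (0,0,1) → ĝ<sub>a</sub> = (0,1,0) is a 90° geodesic
move yet decomposes into 90° + 90° stages with total θ = 120°, and a true
90° rotation viewed from a uniformly random device orientation leaves the
(60°, 120°) alarm band roughly a quarter of the time.  Mounting
independence of the alarm decision therefore holds exactly only for shared
rotations about the k-axis (which the property suite verifies) and
approximately for the modest mounting tilts the detector is designed for.
This is inherent to the decomposition, and consistent with the inflated
angles (up to ~±115°) that waist-worn trials report for physically ~90°
falls; the ±30° alarm slack absorbs most of it.  The acceptance suite keeps
a strict random-rotation invariance check, which fails for fall traces in
extreme re-orientations — an honest measurement of this limitation, not a
detector bug.

## Signal features

- `sum_acceleration` — per-sample Euclidean norm; invariant to axis
  permutation, sign flips and any rotation of the device frame.
- `lowpass_gravity` — 2nd-order Butterworth low-pass, cutoff 1 Hz, applied
  forward-only (causal, as on-device), state initialised from the first
  sample.  Posture is quasi-static and voluntary-movement dynamics sit at
  ≥ ~2 Hz, so 1 Hz separates gravity; a 10 Hz component is attenuated by
  ~40 dB.  The first three time constants (3/(2π·f_c) ≈ 0.48 s at 1 Hz) are
  flagged as warm-up and excluded from capture.  The detector itself
  captures gravity as the stillness-window mean — equivalent to a low-pass
  at DC over a still segment and cheaper online; the filter is provided for
  stream-level feature extraction and analysis.
- `capture_still_gravity` — earliest contiguous window (default 0.5 s:
  long enough to average oscillation, short against the 2 s settle budget)
  with all samples' `|a|` inside the band; returns the mean axis vector with
  its source window, or None.  The stillness criterion is the band on `|a|`
  only; a variance cap was considered and rejected as a second, redundant
  knob at these noise levels.

## Synthetic waveforms

The generator emulates the waveform *structure* of waist-worn recordings —
it makes no claim of biomechanical fidelity, and its constants are design
choices collected in `CLASS_PARAMS`, not fits to any recording:

| class | peak `|a|` | rotation | shape |
|---|---|---|---|
| falls (4 directions) | 3–6 g | 75°–105° | still 2 s → free-fall dip to 0.3 g (0.2–0.4 s) → half-sine impact (30–80 ms) → damped 15 Hz ring (0.5 s) → lying still |
| jumping | 2.5–3.5 g | < 10° | two jumps: crouch dip, 0.3 g flight, landing spike, ring, still |
| walking | ≤ ~1.55 g | < 10° | 1 ± 0.45 g at 2 Hz plus a harmonic, ±5° sway |
| squatting | ≤ ~1.3 g | < 15° | two slow dip/overshoot cycles, tilt out and back |
| sitting | 1.5–1.9 g | 15°–25° | tilt transition, seat bump, small ring |
| resting | 1.4–1.8 g | 95°–115° | lying-down transition: fall-like rotation, sub-threshold bump |

Orientation changes are time-interpolated rotations of the gravity
direction along a fixed axis (a slerp), so intermediate samples are
physically coherent; white Gaussian noise of σ = 0.02 g per axis (above the
4 mg sensor precision, to be conservative) is added throughout; an optional
fixed `device_orientation` rotation re-expresses the whole trace and ground
truth in another mounting.

**Mounting geometry.** Standing gravity is drawn within 10° of the device
+x axis; fall rotation axes sit at ±45° azimuth from the device z-axis
(forward/backward share the simulated body-lateral axis, left/right the
body-anterior axis) with ±10° wobble.  Given the frame dependence above,
this emulates a realistic belt mounting in which the decomposition angle of
a true fall stays inside the alarm band ~99% of the time — the regime a
working deployment operates in.  The residual ~1% of falls whose θ inflates
past 120° is the synthetic analogue of the misses real trials report.
Resting rotations are drawn from the interior 95°–115° of the nominal
90°–120° range so that measured angles stay clear of both band edges under
noise.  Ground truth carries the *geodesic* angle between the true gravity
directions (orientation-invariant), the true noise-free peak, and the true
directions; fall traces are asserted at generation to exceed 2 g, and
walking/squatting never to reach it.

## Evaluation

A trial (one trace) counts as an alarm if at least one alarmed event
occurs.  Fall-class alarms are TP, fall misses FN, ADL alarms FP, ADL
rejections TN; sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP),
rounded half-up to one decimal.  Per-class counts are always reported next
to the two scalars.  On the reference trial's published counts this yields
97.1% / 98.3% for the two-feature design and 91.7% / 88.7% for the
acceleration-only design — the published baseline sensitivity of 91.6% is
0.1 points below the value its own counts give (220/240 = 91.67%),
apparently truncation; the counts are reproduced exactly and the
discrepancy reported rather than matched.

The default synthetic benchmark uses 60 traces per class (540 total,
mirroring the trial's 3 volunteers × 20 repetitions); it runs in a few
seconds, so no down-scaling was needed.  Typical seed-fixed results are
~99% sensitivity / 100% specificity for the two-feature detector and 100% /
80% for the baseline (every jumping trace false-alarms).  These are
regression snapshots of the synthetic world: real ADLs are messier (sitting
can exceed 2 g; walking can jolt), so real specificities are lower, and the
synthetic sensitivity says nothing about falls with atypical impact
profiles (syncope, slumps), which the generator deliberately does not model.

## Numerical choices

- Angles are degrees at every public surface; radians internally.
- atan2 convention with azimuth differences wrapped to (−180°, 180°].
- Unit-quaternion checks at 1e-9; algebraic identities at 1e-12; trace
  timestamp uniformity at 1e-6 s.
- The alarm band is open (strict inequalities); ties at exactly 60°/120°
  reject.
- On-disk traces are CSV `t,ax,ay,az` in g-units (every threshold is stated
  in g); g ↔ m/s² converters are provided.
- All randomness flows from explicit integer seeds; cohorts derive
  per-trace seeds from one generator, so any cohort member is reproducible
  in isolation.

## Known limitations

- Frame dependence of θ (above) — the main one.
- The state machine is reconstructed from the published prose description
  of the algorithm's flow; the exact original state set is not published,
  so refractory behaviour and the earliest-window tie-break are our
  choices.
- No gyroscope fusion, no SLERP orientation tracking, no resampling of
  irregular traces, no sensor calibration — out of scope by design.
- The generator's waveform constants are qualitative; none of the synthetic
  rates should be quoted as expected field performance.
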
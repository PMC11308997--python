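# Methods

## Model

The skeleton is a rooted tree of rigid segments. Each joint carries up to
three rotational generalized coordinates applied as intrinsic rotations
in the fixed order X → Y → Z about joint-local axes, with the axis-role
convention: positive X = long-axis rotation (pronation), positive Y =
extension, positive Z = adduction. A child segment's world placement is

```
X_child = X_parent · T(loc_in_parent) · R_x(q_x) R_y(q_y) R_z(q_z) · T(−loc_in_child) · F
```

with `F` the segment's fixed offset. Translational DOFs are not
modelled. The reference configuration gives every joint all three
rotational coordinates; the distal limb joints (elbow, wrist, wing
metacarpal, first wing phalanx, knee) are functionally hinge-like, so
the stand-in ships range-of-motion limits of ±0.25 rad on their off-axis
coordinates (±2.6 rad elsewhere). Where no range is supplied the full
circle is assumed. Range limits are configuration, not computed; angles
are radians internally and degrees only at file boundaries.

## Muscle paths and wrapping

An MTU line of action visits its origin, via points and insertion in
order; via points are always active. One cylindrical wrap object may act
between a consecutive point pair. The wrap test and tangent construction
happen in the cylinder's local frame, projected onto the plane normal to
the axis: if the projected chord's distance to the axis is below the
radius (and both endpoints lie outside the cylinder — otherwise the MTU
is reported unroutable by name), the chord is replaced by entry tangent
line, surface geodesic on the requested side, and exit tangent line.
`wrap_side` is an explicit flag ('+' = counter-clockwise travel about
the local +Z axis) rather than inferred, because quadrant semantics in
other dialects are under-specified. Lengths come from the closed-form
construction with the cylinder unrolled to a plane (so an out-of-plane
wrap contributes `sqrt(planar² + Δz²)`); the 32-sample arc in the output
polyline is for display only. Tangent points falling beyond the
cylinder's finite extent raise an error. Only cylinders are supported:
they cover pulley-style deflection and admit exact verification (a
brute-force shortest-path-around-a-circle oracle agrees to better than
1e-4 relative in tests). Wrap length converges to the chord as the
radius shrinks or the chord moves to tangency.

## Moment arms

The virtual-work (tendon-excursion) definition is used throughout:
`MA = −∂L/∂q`, positive when muscle tension generates positive
generalized torque. The derivative is a central finite difference with
default step 1e-4 rad (configurable); at a range boundary the difference
becomes one-sided and is logged. The step balances truncation error
against geometric noise: results with steps 1e-3–1e-5 rad agree within
1e-6 m on smooth configurations. Two independent checks constrain the
implementation: a perpendicular-distance oracle
`((p − c) × u) · â` for straight single-joint lines of action (agreement
< 1e-6 m over 100 random poses) and the pulley theorem (|MA| equals the
cylinder radius, to 1e-4 relative, while a coaxial wrap is in contact).
At wrap activation/deactivation boundaries the moment arm may jump;
values are reported as computed and adjacent frames are flagged, never
smoothed. MTUs that do not span a coordinate's joint get exact zeros.

## Kinematics

Each take-off style is a one-second sequence interpolated coordinate-wise
from key poses at fractional times (raw timings are affinely normalised
onto [0, 1]). The default interpolant is shape-preserving piecewise cubic
(PCHIP), which reproduces key poses exactly and cannot overshoot the
range spanned by neighbouring key values; linear interpolation is an
option. Interpolated angles are clamped to coordinate ranges with a
logged warning, never silently. Phase structure per style — burst:
crouch/ankle-lifted/launch; countermotion: countermotion/launch;
quadrupedal: crouch/vault/launch — must partition [0, 1] exactly.
The default interior boundaries (burst 0.40/0.70; countermotion 0.55;
quadrupedal 0.35/0.65 with hindlimb liftoff at 0.55) are package
defaults shaped on the extant profiles the styles are modelled after
(quail, starling, vampire bat); no published boundary numbers exist, so
they are explicitly configuration. Launch applicability follows the
styles' mechanics: hindlimb coordinates throughout both bipedal styles;
for the quadrupedal style the hindlimb until liftoff during the vault
and the forelimb from vault onset onward.

## Monte Carlo error model

Each computed moment-arm value v is perturbed multiplicatively,
v·(1 + u) with u ~ Uniform(−f, +f), defaults f = 0.20 and 1000 trials,
and the trial distribution is summarised by mean and (n−1)-denominator
SD. The perturbation acts on moment-arm values, not on model geometry.
Whether each time sample draws its own multiplier or one multiplier
spans a trial is genuinely ambiguous for this kind of error model; both
scopes are implemented (`per_frame_independent` is the default) and
neither is asserted as canonical. Bands for summed traces are obtained
by summing the per-trial perturbed member arms and summarising the trial
sums, which propagates the members' independent errors through the sum;
a pooled-variance shortcut is available behind a flag. All draws come
from seeded `numpy` generators; identical seed and configuration
reproduce byte-identical result files.

## Aggregation

Multi-line muscles are collapsed by frame-wise averaging of their MTU
lines before any summation. Per coordinate and frame, muscles partition
by the sign of their averaged arm into a positive and a negative group
(labelled from the axis role: extensors/flexors about Y,
adductors/abductors about Z, internal/external rotators about X), and
each side is summed; membership is re-evaluated every frame, so an arm
crossing zero switches sides. Exact zeros join neither side — a
measure-zero event under finite-difference noise. The identity
`positive_sum + negative_sum = Σ|MA|` holds to floating tolerance at
every frame and is asserted end-to-end. Mean-across-muscles divides each
side's sum by its member count, normalising away muscle number.
Launch-applicability masking annotates frames; it never alters values.
The extensors-only preset sums the positive (extensor) groups of the
flexion–extension coordinates over the frames where each coordinate is
launch-applicable.

## Synthetic stand-in data

The specimen-derived geometry behind the original model is not
redistributable, so the packaged model is a synthetic stand-in: a trunk,
one forelimb (shoulder, elbow, wrist, wing metacarpal, first wing
phalanx) and one hindlimb (hip, knee), dimensions loosely echoing a 5 m
wingspan animal (humerus ~0.25 m), carrying the full 43-row muscle
roster with its published multiplicities and inference grades attached
at plausible — but expressly non-anatomical — coordinates, with small
seed-controlled jitter and systematic line spread for multi-line
muscles. The triceps heads hook behind the elbow over a
trochlea-like wrap cylinder that engages in deep flexion and releases as
the elbow extends, exercising wrap transitions in every sequence. Two
muscles (SCM, SC) span no joint in the stand-in (their real courses
leave the modelled tree) and are the two rows flagged as not take-off
relevant. What passing tests show, therefore, is that the *pipeline* —
routing, differentiation, error model, aggregation, bookkeeping — is
correct and deterministic; they say nothing about fossil-specific
moment-arm magnitudes, which require the real geometry and remain out of
scope. Analytic toys (a single hinge with closed-form
`MA(q) = (a · Rz′(q) b)/L(q)`, and a pulley) carry their own
expectations used as oracles.

The roster's multiplicities sum to 38 pectoral MTUs (36 excluding the
two non-take-off rows) and 16 pelvic MTUs. The source table's
multiplicities genuinely sum to 16 for the pelvic group although an 18
is quoted alongside it in prose; the roster stores the rows verbatim and
does not resolve the discrepancy. Similarly, prose counts of "22 + 12
muscles" and "thirty-four key muscles" do not map cleanly onto table
rows (triceps and flexor tibialis heads are separate rows); the package
stores rows and multiplicities only.

## Problem sizes and numerical choices

Default runs use 101 frames per one-second sequence, 1000 Monte Carlo
trials and finite-difference step 1e-4 rad; the test suite uses smaller
grids (5–21 frames, 20–2000 trials) chosen to exercise every code path
with comfortable statistical margins. Rotation matrices are validated
orthonormal to 1e-9; path lengths are invariant under rigid relocation
of the whole model to 1e-12 relative. Tie-breaks and degenerate cases:
single-trial SD is reported as 0 with a warning; an empty muscle side
sums to 0 with empty membership; grazing tangency keeps the straight
chord.

## Known limitations

Sphere/ellipsoid/torus wraps, translational DOFs, inverse kinematics,
ground-contact detection, the ankle joint, and muscle force/moment/power
estimation are out of scope. The `.osim` importer covers a minimal
read-only subset (bodies, rotational CustomJoint axes, path points, wrap
cylinders) and warns on everything else; quadrant-to-side mapping is
approximate and flagged. Moment arms near wrap transitions are reported
raw; downstream smoothing is deliberately left to the user.
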
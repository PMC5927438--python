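# Methods

## Model

The package scores toothbrushing *systematics* — the degree to which a
brushing session is complete (all reachable areas brushed), isochronal
(time evenly distributed over areas) and consistent (the brush is not moved
back and forth between areas more often than necessary) — from timed-event
sequential data: a list of intervals, each carrying an onset and offset in
session-relative seconds and the (sextant, surface) area the brush acted on.
Non-brushing intervals (pauses, spitting out) are assumed to be excluded
from the record; gaps between events are therefore permitted and carry no
information beyond separating events.

From a session the summariser derives b (changes between areas: adjacent
event pairs with differing areas; a pause between two events in the same
area is not a change), x (sum of event durations, i.e. effective brushing
time), i (distinct areas reached) and the per-area durations d_a. The two
index components are

- C = max(0, 1 − b/x) · i/n, and
- I = max(0, 1 − n/(2(n−1)) · Σ over all n reachable areas of |d_a/x − 1/n|),

with TSI = C + I ∈ [0, 2]. The I denominator 2(n−1)/n² is the maximum of
the mean absolute deviation of relative durations, attained when all time
falls in one area, so the unclamped I is already ≥ 0 for any nonnegative
duration vector (verified by exhaustive enumeration for n ≤ 4 and random
simplex sampling for n = 16 in the test suite); the clamp guards only
against accumulation error. C's clamp is substantive: b can exceed x when
changes outnumber seconds. Both clamps apply to the final value, never to
intermediate terms. C and I weight into the TSI equally; no alternative
weighting is provided.

## Area schemes

The default scheme has n = 16 areas: vestibular and oral surfaces of all
six sextants plus occlusal surfaces of the four posterior sextants (1, 3,
4, 6). The incisal edges of the two anterior sextants are excluded by
default and available through the 18-area `all_incisal` scheme. The
vestibular/oral analysis condition drops occlusal (and incisal) events and
rescores against the 12-area `vo` scheme; all measures, **including x**,
are recomputed on the filtered event stream, and two events made adjacent
by the filter count a change only if their areas differ. Recomputing x on
the filtered stream is a deliberate choice (the alternative — keeping the
full-session x — is not expressible as a pure surface restriction); users
comparing against analyses that kept the full x should be aware of it.
Schemes are user-configurable for partially dentate subjects; the package
never infers a reduced dentition from data.

## Degenerate inputs and numerics

An empty session, or one emptied by surface restriction, raises an error
rather than scoring 0: "no data" is not "unsystematic". x ≤ 0 and n < 2
(I's denominator vanishes) are hard errors. All computation is double
precision; rounding (half-up, default two decimals — the convention index
values are reported in) is applied once at the reporting/CLI layer.
Durations are floating-point seconds, so frame-resolution codings are
accepted. I = 1 is attained exactly (not merely within tolerance) for
mathematically uniform durations because the deviation sum is exactly zero.

## Event-log dialect

Input is plain CSV with header columns `onset_s, offset_s, sextant,
surface` (codes V/O/OCC/INC or full names), optional `session_id` for
batch files and optional `non_brushing` truthy flag for rows to drop.
Rows may be unsorted; the reader sorts by onset and rejects overlaps
(naming both intervals) and duplicate rows. Exports from proprietary
video-coding software are mapped by renaming columns; the index depends
only on the derived measures, not the file format.

## Theoretical validation grid

The sweep crosses 16 area counts (1–16) × 5 repetition factors (k = 1–5)
× 8 durations × 2 allocation conditions = 1280 rows. Grid rows are
parameter tuples plugged into the formulas: the change count is tied to
the repetition factor alone, b = 16k − 1 ∈ {15, 31, 47, 63, 79},
independent of the area count, so that consistency and completeness are
probed independently (the extremes — C clamped to 0 at b = 79, x = 30 with
only one area reached — are only reachable this way). Physically
consistent sequences for a single parameter combination come from
`realize_session`, which visits i areas k times each in rounds (b = ik − 1)
with per-visit dwell equal to the area's share of x divided by k; its
round-trip through the summariser is tested, and grid rows whose b matches
the realizable ik − 1 (i.e. i = 16) are cross-checked against realized
sessions.

Default durations are {30, 60, 90, 120, 180, 240, 360, 480} s — eight
values spanning the 0.5–8-minute range that brackets observed and
recommended brushing times, denser at the short end where C changes
fastest; the set is configurable. In the isochronal condition I depends
only on i and equals (i − 1)/15 for n = 16 (closed form, verified against
the direct formula), giving mean 0.50 and sample SD 0.31 over the sweep
regardless of the duration set.

The non-isochronal condition allocates x over the first i areas by a
renormalised master weight vector. The default vector assigns raw
per-surface weights vestibular 2.0, occlusal 1.25, oral 0.75 — the pattern
habitual uninstructed brushing tends to show (lip/cheek surfaces
over-brushed, tongue-facing surfaces neglected) — normalised over the
16-area order. Any user vector (nonnegative, summing to 1, not all equal)
is accepted. Summaries report min/max/mean and sample (n − 1) SD per
condition at two decimals.

## What the synthetic data does and does not show

The grid and `realize_session` emulate idealised sessions: contiguous
events, exact durations, change counts tied to repetition structure. Real
coded sessions have ragged dwell times, pauses, returns to areas at
irregular intervals and coder-resolution noise; passing tests on synthetic
data demonstrate the correctness and range behaviour of the formulas, not
any property of real brushing populations. Clinical reference values for
observed groups (e.g. scores before and after instruction) require coded
video material and are explicitly out of scope, as is the agreement
analysis between coders.

## Problem sizes

The test suite scores ~10⁴ randomly generated sessions, enumerates all
event sequences of length ≤ 5 over 3 areas for the change-count oracle and
all integer duration compositions with x ≤ 8 for n ≤ 4 for the MAD bound,
and draws 3000 Dirichlet samples on the 16-simplex; the full suite runs in
a few seconds on one CPU.
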
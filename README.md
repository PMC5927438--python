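# tsi — Toothbrushing Systematics Index

`tsi` quantifies how *systematically* a person brushes their teeth from
timed-event sequential observation data — the kind of record produced when a
coded video of a brushing session is transcribed into intervals of
"the brush acted on area so-and-so from second a to second b". It is aimed at
researchers in oral-health behaviour and dental public health who need a
single reproducible score for brushing systematics instead of ad-hoc
descriptive parameters.

## The index

The dentition is divided into **areas**: (sextant, surface) pairs. By default
there are n = 16 reachable areas — vestibular and oral surfaces of all six
sextants plus the occlusal surfaces of the four posterior sextants; a 12-area
vestibular/oral scheme and an 18-area scheme including the incisal edges are
built in, and custom schemes (e.g. for partially dentate subjects) can be
configured.

From one session the behavioural measures are

- *b* — number of changes of the brush between areas,
- *x* — total effective brushing duration in seconds,
- *i* — number of distinct areas reached,
- *d_a* — brushing duration within area *a* (0 if unreached).

Two component values are computed:

**Consistency/completeness**

    C = max(0, 1 − b/x) · i/n

Few changes relative to the brushing time and high coverage give C near 1;
if the change count exceeds the duration in seconds the raw value is negative
and is clamped to 0.

**Isochronicity**

    I = max(0, 1 − n/(2(n−1)) · Σₐ |d_a/x − 1/n|)

One minus the mean absolute deviation of the relative per-area durations,
normalised by its maximum 2(n−1)/n² (all time in one area). I = 1 exactly
when every reachable area receives x/n seconds.

**TSI = C + I** ranges from 0 (unsystematic) to 2 (perfectly systematic
brushing).

## Worked example

The reference session reaches each of the 16 areas exactly once (15 changes)
in 210 s with equal time per area:

```python
from tsi import AreaScheme, realize_session, tsi

scheme = AreaScheme.all_areas()           # n = 16
session = realize_session(i=16, k=1, x=210.0)
result = tsi(session, scheme)
print(round(result.c_value, 2), round(result.i_value, 2), round(result.tsi, 2))
# 0.93 1.0 1.93
```

C = (1 − 15/210) · 16/16 ≈ 0.93 (one change per area visited, over a
3.5-minute session), I = 1.00 (perfectly even time allocation), so
TSI = 1.93 — highly systematic brushing. The order in which areas are
visited has no effect on the score.

The same computation from an event-log CSV via the command line:

```
$ tsi score complete.csv
session_id  scheme  b   x       i   C     I     TSI
complete    all     15  210.00  16  0.93  1.00  1.93

$ tsi score complete.csv --scheme vo   # vestibular/oral surfaces only, n = 12
complete    vo      11  157.50  12  0.93  1.00  1.93
```

Event logs are plain CSV with columns `onset_s, offset_s, sextant, surface`
(surface codes `V`, `O`, `OCC`, `INC`), an optional `session_id` column for
batch files and an optional `non_brushing` flag column; see
`docs/methods.md` for the dialect and for mapping coding-software exports.

## The theoretical validation grid

`tsi grid` sweeps a full factorial of hypothetical brushing parameters —
area counts 1–16, repetition factors 1–5 (change counts 15–79), durations
30–480 s, isochronal vs non-isochronal time allocation — 1280 scored
combinations in total — and prints per-condition summaries:

```
$ tsi grid --conditions iso
640 grid rows
[isochronal]
  C   min 0.00  max 0.97  mean 0.32 ± 0.26
  I   min 0.00  max 1.00  mean 0.50 ± 0.31
  TSI min 0.00  max 1.97  mean 0.82 ± 0.52
```

## What this package does not do

Video coding itself (producing the event log from a recording), inter-rater
agreement statistics, and clinical group comparisons are out of scope.
Scores for real observed sessions require real coded videos; the theoretical
grid characterises the index's range and behaviour, not any population.
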
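# Methods

## Occupancy model and its assumptions

The analysis treats the per-position density of read 3′ ends as a snapshot
of polymerase occupancy. Two assumptions make that quantitative:

1. **Independent polymerases at steady state.** With constant initiation
   flux and no polymerase–polymerase exclusion, the expected occupancy
   density at position `i` is proportional to the dwell time `d_i` there,
   so the expected fraction of 3′ ends is `f_i = d_i / Σ_j d_j`. Exclusion
   (TASEP-style traffic) is deliberately out of scope: the occupancy-time
   conversion below itself assumes simple proportionality, so modelling
   traffic would put the simulator and the analysis on different theories.
2. **The 3′ end marks the active site.** The rightmost aligned base of a
   plus-strand read (leftmost for minus strand) is taken as the polymerase
   position; soft-clipped bases are excluded since they are not
   template-engaged.

**Occupancy time.** With unit length `L` and mean velocity `v`, the total
transit time is `T_total = L/v` and the per-position estimate is
`t_i = f_i · T_total`. Defaults are `L = 7800` nt and `v = 40` nt/s, giving
`T_total = 195` s and 25 ms per position for a uniform profile. The track
conserves `Σ t_i = T_total` exactly. Note the estimator is *calibrated to
the assumed mean velocity*: if the real (or simulated) polymerase is slower
on average — e.g. a dwell model whose total transit is 265 s — every `t_i`
carries the uniform factor `T_total / Σ d_j` (≈0.74 in the demo). Ratios,
ranks and Δlog2 responses are unaffected; absolute dwell readings at pauses
are accurate only insofar as the assumed velocity is.

## Pipeline stages and parameter defaults

| parameter | default | units | why |
|---|---|---|---|
| pseudocount α | 1.0 | counts/position | conventional add-one; guarantees strictly positive fractions for logs; recorded in metadata |
| profile window | 31 | nt | display/aggregation smoothing; odd so the kernel is centred (nearest odd to the conventional 30) |
| ratio window | 51 | nt | heavier smoothing before division stabilises the log2 ratio (nearest odd to 50) |
| pause window | 5 | nt | see "Pause calling" |
| min_prominence | 3 × median of the track | track units | scale-free peak threshold |
| min_distance | 50 | nt | minimum pause separation and the cross-condition matching tolerance |
| velocity | 40 | nt/s | canonical mean RNAPI elongation rate |

Order of operations: count 3′ ends → add α → normalise to fractions →
smooth each replicate → median across replicates (for two replicates the
median is their mean; the displayed band is the Q2–Q3 envelope with linear
interpolation). The Δlog2 track divides the 51-nt-smoothed replicate
medians (test over reference). Both the fraction-then-smooth order and the
smooth-each-replicate-then-aggregate order are fixed here; the underlying
functions (`log2_ratio`, `smooth_blackman`) accept explicit windows so the
alternative orders remain expressible.

**Smoothing details.** The Blackman kernel is normalised to unit sum; at
positions within half a window of a boundary it is renormalised over the
in-bounds support, so constants are exact fixed points and real boundary
peaks (the +36 initiation-proximal site, the 3′-end pile-up) are not
artificially decayed. Smoothed fraction tracks are renormalised to unit sum
(edge renormalisation moves total mass by a negligible but nonzero amount).
Even windows are accepted and bumped to the next odd value, which is
recorded in the profile metadata. The kernel's analytically-zero endpoints
are clipped against ~1e−17 float noise so smoothing is positivity-preserving.

## Pause calling

Pauses are local maxima with prominence ≥ 3× the track median, separated by
≥ 50 nt (`scipy.signal.find_peaks`; the leftmost sample of a plateau is
reported; width is the extent above half prominence). The caller runs on a
**5-nt**-smoothed track rather than the 31-nt display track. This is an
analytic necessity, not a tuning: a single-nucleotide pause of multiplier
`m` appears in an `M`-wide Blackman-smoothed track with elevation
`(m−1)·w₀/Σw` above baseline, where `w₀/Σw` is the normalised centre weight
(≈0.079 at M=31, ≈0.595 at M=5). At m=10 the 31-nt track retains only a
0.71× elevation — below any robust 3×-median prominence — while the 5-nt
track retains 5.4×. Calls from both conditions are matched by nearest
position within `min_distance`.

With attenuation 0.5 the depleted pauses (effective multiplier 5.5) sit at
≈2.7× prominence, right at the 3× threshold, so depleted-condition call
counts are expectedly unstable; cross-condition conclusions should rest on
the Δlog2 track (which needs no peak calls), with matched pause tables as
annotation.

## The synthetic-data generator

`simulate_reads` draws 3′-end positions multinomially from the analytic
fractions and extends each read upstream by a truncated-geometric length
(mean 30 nt, minimum 15 nt — plausible CRAC insert sizes; configurable,
including fixed lengths). The default demonstration model is a 7800-nt unit
at 25 ms baseline dwell with a 3× dwell enrichment over the 1300-nt 5′ETS,
twenty ×10 point pauses including +36 and +7715, and pause attenuation 0.5
in the depleted condition with 2 replicates × 5×10⁵ reads. Replicate seeds
are fixed offsets from the master seed (seed + 1000·condition + replicate).

What the generator does **not** emulate: PCR duplication and UMI structure
(no deduplication stage exists downstream to exercise), mapping error and
multi-mapping ambiguity (reads are placed exactly; the multimap policies
are exercised through alignment fixtures instead), sequence content, and
polymerase traffic. Passing recovery tests therefore demonstrate that the
estimators are correct *under the stated kinetic model*, not that real
libraries are free of these artefacts.

qPCR fixtures embed the dilution effect in the generated CTs (a d-fold more
dilute template shifts CT by +log2 d), so the dilution-corrected 2^ΔCT
analysis recovers the programmed enrichment exactly at zero noise; with
equal dilutions the corrected and uncorrected conventions coincide. The
correction is off by default and always flagged in the result, since
published "arbitrary units" conventions vary. Technical replicates are
summarised by their mean; no outlier rejection.

## Coordinate conventions

All intervals are 0-based half-open. Unit coordinates run 5′→3′ regardless
of genomic strand: a plus-strand read's 3′ end maps to
`read.end − 1 − unit.start`, a minus-strand read's to
`unit.end − 1 − read.start`. The multi-copy rDNA repeats are collapsed to
one representative unit; multi-mapped alignments are kept at weight 1 by
default, with `primary-only` and `fractional` (1/NH) policies available.
The packaged annotation fixes the 5′ETS as unit positions [0, 1300) of the
7800-nt unit; the internal 18S/ITS1/5.8S/ITS2/25S/3′ETS boundaries are
synthetic (plausible fission-yeast subunit lengths), as flagged in the
fixture's name and docstring.

## Degenerate inputs and numerical choices

All-zero count profiles refuse fraction conversion with a message directing
to pseudocounts. Nonpositive smoothed fractions abort the log2 ratio the
same way. Reads on the wrong strand/chromosome or outside the unit are
excluded (never raised) during counting. bedGraph output merges equal-value
runs and, at default precision, round-trips bit-exactly. Aggregation
quartiles use linear interpolation (`numpy.percentile` default). Ties in
pause plateaus break to the leftmost sample.

## Known limitations

- Rank-correlation summaries between a piecewise-constant dwell truth and a
  sampled estimate are capped well below 1 by tie blocks (thousands of
  baseline positions are exactly tied in the truth but ranked by noise in
  the estimate); Pearson correlation or pause-restricted error metrics are
  the informative recovery summaries for such models, and the recovery
  report emits both.
- Occupancy times inherit the assumed mean velocity (above).
- No statistical testing of per-position differences is provided; the
  Δlog2 track is descriptive, matching its intended use.
- No deduplication or UMI handling; upstream alignment is out of scope.
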
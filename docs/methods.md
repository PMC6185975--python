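# Methods

## The test

The unit of inference is a gene set S against a fixed background. After
per-gene z-scaling (each gene's M-point profile to mean 0, sd 1; sample sd
with denominator M−1 by default, population sd via `sd_ddof=0`), the score
is the Euclidean distance d between the set's mean profile and the
background profile, the mean over all retained genes. The null is
resampling-based: B random gene sets of the same size are drawn from the
full universe and scored against the *same* background, which is computed
once and never re-derived per draw. The p-value is the +1-corrected
exceedance fraction with a strict inequality, so p ∈ [1/(B+1), 1]; when
every null distance ties d exactly, p is the floor 1/(B+1). Raw p-values of
testable sets are adjusted for multiplicity and compared to α.

This is a *self-contained* test of temporal coherence: it asks whether the
set's mean profile departs from the background more than a size-matched
random set's would. It is not a competitive enrichment test and makes no use
of the spacing of the time grid — time labels are opaque ordered strings,
and 2 h → 35 d unevenness is deliberately ignored, matching the plain
Euclidean treatment of the profiles.

## Choices where the procedure is underdetermined

* **Sampling mode.** A "random gene set" is read as a subset: sampling is
  without replacement by default (`sampling="with_replacement"` is available
  and tested). Null draws never exclude the members of S.
* **Adjustment method.** "Adjusted p-value" is read as Benjamini–Hochberg
  FDR (the common default in expression screens); Holm and Bonferroni are
  flags, and untestable sets contribute nothing to the multiplicity m.
* **Null size.** The null is matched to the *overlap* (members actually
  present in the matrix), not the nominal GMT size, because the tested
  profile averages only present genes.
* **Minimum testable overlap.** Default 3; smaller overlaps yield a
  "not testable" record rather than an error or a degenerate single-gene
  test. Every skip is logged.
* **Filtering.** Genes with any missing value or with zero temporal
  variance are removed before scaling (both are unscalable); counts per
  reason are logged and echoed in the run manifest. Missing values are
  dropped, never imputed. Constancy is detected as max−min = 0 rather than
  sd = 0, because pairwise-sum round-off can give a constant row a tiny
  nonzero floating-point sd.
* **Reproducibility.** Each set's null uses a SHA-256-derived 31-bit seed
  from (global seed, set name), so a run is deterministic end-to-end and
  adding or removing one set never perturbs another set's null.
* **Identifier matching.** Matrix and gene-set identifiers are matched
  after whitespace trimming and case-folding (probe annotations are
  case-inconsistent); exact matching is a flag.

## The enumeration oracle

`exact_p` replaces the bootstrap with exhaustive enumeration of all
C(N, |S|) subsets, returning (K+1)/(C+1) for K strict exceedances; it is
capped (default 10⁵ subsets) and used for verification only. Note the
finite-enumeration +1 correction: the bootstrap estimates the exceedance
probability q = K/C, so its expectation is (Bq+1)/(B+1), which differs from
(K+1)/(C+1) by ≈ (1−q)/(C+1). On tiny universes this bias exceeds the
Monte-Carlo error; the agreement tests therefore compare the bootstrap p to
its exact expectation derived from `exact_p`, at 3 Monte-Carlo standard
errors.

## The synthetic generator

The generator emulates the data structure the test assumes: a few thousand
genes over an ordered post-injury grid (default: the nine points
2 h, 6 h, 24 h, 48 h, 4 d, 7 d, 14 d, 21 d, 35 d), with named sets whose
members share a temporal template. Gene g at time t is

    x[g,t] = baseline_g + scale_g · ( effect_s · template_phase(s)[t] + ε ),
    ε ~ N(0, noise_sd²) i.i.d.

Templates are mean-centred, unit-norm indicator shapes: `early_transient`
positive over the first ⌈M/3⌉ points and non-positive after;
`late_sustained` non-positive early, positive and flat from the midpoint
index on (so its scaled set profile peaks anywhere in the sustained
window); `null` is the zero vector. Non-null sets get disjoint member lists
so ground-truth labels are unambiguous; null sets are drawn from the
remaining genes.

Parameter defaults and rationale:

* `n_genes = 2000` — large enough for a stable background, small enough to
  keep the suite fast; the full study scale (18,560 × 9) is a configuration
  value, not a different code path, and is exercised by a feasibility test.
* `noise_sd = 1.0`, `effect = 3` for dynamic benchmark sets of size 50 —
  because the effect enters *before* scaling, detectability depends only on
  the effect/noise ratio; at 3:1 a coherent 50-gene set is comfortably but
  not trivially detectable at B = 1000.
* `baseline_sd = 2.0`, `scale_range = (0.5, 2.0)` — per-gene offset and
  gain emulating probe-level magnitude differences. Both are nuisance
  parameters that per-gene z-scaling removes exactly; their values are
  inert to every downstream statistic and are present so that a pipeline
  that *failed* to scale would fail the benchmarks.

What the generator does **not** model: gene–gene correlation beyond shared
templates, array batch structure, heteroskedastic probe noise, or real
pathway identities. A green calibration or power test therefore establishes
that the statistic, null construction and FDR control behave as designed
under independence — not that real microarray noise is this benign.

## Numerical notes

* Scaling is idempotent and invariant to per-gene affine maps a·x+b (a>0),
  both asserted as property tests.
* The results table prints 6 significant digits; round-tripping through the
  TSV preserves values to that precision.
* The profile report orders testable sets by (peak time index, raw p, name)
  — a deterministic stand-in for the early→late visual ordering of a
  time-course heatmap; the ordering rule is a presentation choice, not part
  of the inference.
* Runtime: the full study scale (18,560 genes × 9 points × 50 sets,
  B = 1000) completes in seconds on one CPU; null index drawing is the only
  per-resample Python-level loop.

## Limitations

* Empirical p-values are bounded below by 1/(B+1); with B = 1000 and many
  sets, sets tied at the floor are ranked by name, and finer ranking
  requires a larger B.
* The test conditions on one expression matrix; replicate-level variance at
  each time point is not modelled (the motivating dataset ships one profile
  per time point).
* Calibration holds under the generator's independence assumptions;
  strongly co-expressed null sets in real data behave like small coherent
  sets and can inflate significance, as for any self-contained set test.
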
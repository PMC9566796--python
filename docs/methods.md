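# Methods

## Model and procedure

The pipeline runs in four stages.

**1. Expert aggregation (optional).** A Delphi panel scores, per SWOT
group, the upper triangle of the pairwise-comparison matrix and one signed
intensity per factor. Scores are pooled cell-wise by the arithmetic mean
(the study convention this package follows; the geometric mean, standard
elsewhere in AHP practice, is available as an option). Pooling acts on
upper-triangle scores only and the lower triangle is mirrored as
reciprocals afterwards: averaging $a_{ij}$ and $a_{ji}$ independently does
not preserve $a_{ji} = 1/a_{ij}$, so full-matrix averaging would leave the
aggregate non-reciprocal. Pooled values are deliberately *not* snapped
back to the Saaty grid — an aggregate like 4.3 is legitimate panel
information. All experts must score every pair (no missing-entry
completion), and sign disagreement on an intensity is an error rather than
something to average away, since the S/O-positive, W/T-negative convention
leaves no legitimate room for it.

**2. Weights and consistency.** Weights come from the sum-product
(column-normalize, row-average) method, not the principal eigenvector.
This is a deliberate modelling choice, not an approximation of
convenience: the reported intermediates (column sums, AW, λmax) are those
of the sum-product chain, and the two estimators differ in the third
decimal for mildly inconsistent matrices. The eigenvector routine is kept
only as an independent cross-check in the test suite, where the two are
required to agree within 0.05 per component for matrices passing the CR
test. AW is the *original* judgment matrix times the weight vector (for a
consistent matrix AW = n·w); λmax is the mean of AW_i/w_i. The random
index table is, by order n = 1…9: 0, 0, 0.52, 0.89, 1.12, 1.26, 1.36,
1.41, 1.46 — note the n = 3, 4 entries differ from Saaty's classic 0.58,
0.90; the table is overridable per study but these are the defaults. CR
exactly at the 0.1 threshold fails (the pass condition is strict
inequality); CR is defined as 0 for n ≤ 2, where any reciprocal matrix is
perfectly consistent. Orders above 9 are rejected because RI is not
tabulated.

**3. Strength synthesis.** Factor strength = signed intensity × weight;
group totals are their sums. Intensities are stored signed (W/T negative)
and validated for sign and |I| ≤ 9; non-integer values are accepted
(Delphi means). Since weights are a convex combination, |total| never
exceeds max|intensity|. Combining strengths with a matrix that failed its
CR test is refused by default and downgraded to a warning under
`allow_inconsistent`.

**4. Strategy geometry.** Vertices (S′,0), (0,O′), (W′,0), (0,T′) — W′ and
T′ enter with their negative signs, no absolute-value step. The centroid
is the plain mean of the four vertices. The azimuth uses the two-argument
arctangent: a single-argument arctan(Y/X) cannot distinguish quadrants,
and the zone table is defined over the full [0, 2π). θ is reported both
signed in (−180°, 180°] and normalized to [0°, 360°). The eight zones are
half-open intervals [a, b); the single closed bound at π/2 is honored as
printed in the zone table, so exactly-vertical azimuths classify as
opportunity type and the ambitious area's aggressive type effectively
opens just above π/2. This makes `classify_zone` a total single-valued
function on [0, 2π). U = O′·S′ and V = T′·W′ are recomputed from
full-precision totals. Degenerate inputs: the all-zero quadruple (and any
quadruple with a centroid exactly at the origin, e.g. fully symmetric
totals) has no azimuth and raises; when U + V = 0 with an off-origin
centroid, ρ is defined as 0.5 — no intensity signal in either direction —
rather than raising. The maintain band for the intensity guidance defaults
to ρ ∈ [0.45, 0.55] and is configurable.

## Numerical choices

All computation is in double precision; rounding to 4 decimals (half-even)
happens only at text-rendering time, and JSON reports carry full
precision. Matrix cells given as fraction strings ("1/7") are parsed as
exact rationals before conversion, so CSV input reproduces 1/7 to the last
bit. Reciprocity of full-matrix input is *checked* (relative tolerance
1e-9), never silently repaired; upper-triangle input is completed by
construction. A consequence of chaining full precision: the bundled worked
example's strategy numbers differ slightly from a hand calculation that
chains 4-decimal intermediates (θ = −13.261° here vs −13.243° by the
rounded chain; ρ = 0.5377 vs 0.5370). The package reports its own
full-precision values.

## Synthetic panels and what they do (not) show

The generator emulates the Delphi process: a latent positive weight vector
per group defines a perfectly consistent matrix w_i/w_j (CI = 0 exactly);
each synthetic expert's matrix multiplies the upper-triangle entries by
exp(ε), ε ~ N(0, σ²) — judgments are ratio-scaled, so noise belongs on the
log scale — optionally snapped to the nearest Saaty value in log space
(midpoint ties snap toward 1, the less extreme judgment). Intensity jitter,
when enabled, adds ±1 to the magnitude, clamped to [1, 9], sign preserved.
Defaults mirror the bundled study's conditions: 10 experts, groups of 2–9
factors, arithmetic pooling. At σ = 0 without snapping the synthetic
pipeline reproduces the analytic one bit for bit, which anchors the
Monte-Carlo machinery to the deterministic path.

`simulate_strategy_distribution` runs the full pipeline per replicate,
rejects (and counts) replicates whose pooled matrix fails CR < 0.1, and
summarizes θ, ρ and zone frequencies. Everything is driven by one
`numpy.random.Generator` seeded from the spec, so identical spec + seed
gives bit-identical output. Default problem sizes (200 replicates, groups
of 3–4 factors) run in seconds on one core.

What the synthetic model does *not* capture: real panels are not
independent log-normal perturbations of a shared latent truth — Delphi
rounds induce correlation and anchoring, experts have systematic biases,
and real judgment error is not symmetric in log space. Passing tests
therefore demonstrate the *pipeline's* correctness and its sensitivity
behaviour under a plausible noise model, not calibrated statements about
any real expert panel.

## Known limitations

- No fuzzy/interval AHP, no ANP dependencies between factors, no
  missing-judgment completion.
- The four groups are treated symmetrically; there is no second-level
  weighting of S/W/O/T against each other.
- Consensus diagnostics across experts (e.g. Kendall's W) are out of
  scope; aggregation assumes the final Delphi round already converged.
- The zone labels are the eight table cells; coarser narrative labels
  sometimes used for the same quadrants are not emitted.
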
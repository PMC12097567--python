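# Methods

## Structural change decomposition

The decomposition treats a composition panel — category shares of one
workforce attribute, each year summing to 100% — as a compositional
time series and summarises its year-over-year movement. For each period
(year t−1 → year t) and category j:

- SCV_j(t) = (p_j(t) − p_j(t−1)) / 100, a signed fraction (the
  convention that a +1.8 percentage-point move is written 0.018);
- SCD(t) = 100 · Σ_j |SCV_j(t)|, in percent;
- SCC_j(t) = 100 · |SCV_j(t)| / Σ_k |SCV_k(t)|, in percent.

Because every year's shares sum to 100, Σ_j SCV_j(t) = 0 up to the
row-sum tolerance; SCD is permutation-invariant in the categories and
zero exactly when two consecutive rows are identical.

**Period convention and baseline.** Rows are labelled by the period's
end year. A panel of n years yields n−1 periods; an optional explicit
baseline share vector for the year preceding the panel adds a first
period, which is how a six-year panel can carry six decomposition rows
(published national tables often do this against an unpublished
prior-year composition). The package never invents a baseline.

**Degenerate periods.** If all SCVs of a period are zero the
contribution rates are reported as zeros with a `degenerate` flag
rather than NaN; 0/0 is never formed.

**Trend labels.** A category is `positive` over the window if its SCV
column sums above zero *and* strictly more than half of its nonzero
entries are positive (symmetrically `negative`; all-zero columns are
`no change`; everything else `mixed`). The majority fraction is a
parameter (default 0.5). There is no built-in numeric cutoff for
calling a period an "active" structural change — domain usage varies —
but `run_structural_change(..., scd_threshold=...)` lets the user set
one and query the periods that meet it.

## Grey relational analysis

Deng's grey relational analysis scores the similarity of each
comparison series' geometric shape to the reference series. It is
designed for exactly the data situation of annual yearbook panels: very
few observations (here n = 6 years), no distributional assumptions, and
a system only partially observed — conditions under which regression
would be uninformative.

Steps, for reference x₀ and comparisons x₁…x_m:

1. **Normalisation** (default `initial_value`): x′(k) = x(k)/x(1).
   Every series must be strictly positive; the reader enforces this.
   `mean_value` (divide by the series mean) and `none` are offered as
   logged alternatives — see Limitations for why.
2. **Differences**: Δ_i(k) = |x₀′(k) − x_i′(k)| with *two-level*
   (global) extrema Δmin = min_i min_k Δ, Δmax = max_i max_k Δ. The
   global extrema make coefficients set-dependent: adding or removing a
   comparison series can change every coefficient. Degrees are,
   however, invariant to series ordering and to rescaling any series by
   a positive constant (under initial-value normalisation).
3. **Coefficients**: ξ_i(k) = (Δmin + ρ·Δmax) / (Δ_i(k) + ρ·Δmax) with
   discrimination (resolution) coefficient ρ ∈ (0, 1], default 0.5 —
   the conventional choice; smaller ρ spreads the coefficients further
   apart, and every ξ and degree is non-decreasing in ρ. Under
   initial-value normalisation Δ_i(1) = 0 for every i, so Δmin = 0 and
   all coefficients lie in [ρ/(1+ρ), 1] = [1/3, 1] at ρ = 0.5. If
   Δmax = 0 all series are identical to the reference and all
   coefficients are 1.
4. **Degree and ranking**: r_i = mean_k ξ_i(k) (unweighted arithmetic
   mean — the published degree rows equal the column means of their
   coefficient tables), ranked descending with dense ranks; tied
   degrees share the smaller rank and the tied groups are reported in
   `GreyResult.ties`.

A comparison series proportional to the reference attains degree
exactly 1 and rank 1 (reflexivity).

## Numerical choices

- Internal arithmetic is full double precision; rounding happens only
  at serialisation, half-up (ties away from zero) to 3 d.p. for
  dimensionless values and 2 d.p. for percentages, matching how such
  tables are published.
- Before half-up rounding, values are snapped at eight extra decimal
  places so quantities that are exact decimal ties in real arithmetic
  (e.g. 0.011/0.032 = 0.34375) are not nudged off the tie by binary
  floating-point error. Without the snap, that cell would round down
  where a published table rounds up.
- Validation tolerances: composition rows must sum to 100 ± 0.5
  percentage points by default (published shares are rounded to 1 d.p.,
  so exact 100 cannot be demanded); the reader rejects violations and
  never silently renormalises.

## Synthetic data generator

The generator emulates the statistical shape of national yearbook
panels so every stage is testable without external data: a six-year
window, 5–6 categories per attribute, one reference series and eight
drivers, all positive with smooth annual trends.

- **Shares**: a linear drift in percentage points per category
  (feasibility-checked against the [0, 100] range; drifts must sum to
  zero so totals stay at 100), perturbed on the log-odds scale and
  renormalised — the simplest construction that keeps noisy rows valid
  compositions. Default noise scale 0.02 on the log-odds scale, a mild
  perturbation consistent with administrative count data. Planted
  drifts are recoverable: the mean SCV × 100 estimates the drift within
  3 standard errors across seeded replicates.
- **Factors**: the reference is a smooth compound-growth path; factor i
  with association a_i ∈ [0, 1] is a convex blend of the reference's
  normalised trajectory (weight a_i) and an independent smooth growth
  path (weight 1 − a_i), rescaled to the factor's own level, with
  multiplicative log-normal noise (default scale 0.02) so levels stay
  strictly positive. Association 1 with zero noise gives a factor
  exactly proportional to the reference (degree 1).
- One integer seed drives a single `numpy.random.Generator` per
  generated object, so everything is reproducible; the factor stream is
  offset from the share stream so the two panels are independent.

**Recovery scenario.** The rank-recovery property ("a factor that
tracks the reference much more closely than the rest is ranked first")
is tested with one factor at association 0.95 against seven at ≤ 0.3.
For the premise to hold, the competitors' *own* growth paths must
differ appreciably from the reference's: a factor growing at almost the
reference's rate has a nearly identical normalised shape regardless of
its association weight — a real feature of GRA, which sees shape, not
causation. The scenario therefore spreads competitor growth rates over
−2% to +13%/yr around a 6%/yr reference; the planted factor then ranks
first in 98% of 200 seeded replicates. Test sizes (200 replicates for
rank recovery, 60 for drift recovery) keep the whole suite under a few
seconds.

**What passing tests do not show.** The generator reproduces the
dimensions, positivity, smoothness and compositional constraints of
yearbook data, not its autocorrelation structure, measurement-revision
artifacts, or co-movement between drivers (generated factors are
mutually independent given the reference). Recovery results therefore
demonstrate correctness of the implementation under the planted model,
not real-world identifiability of drivers.

## Design choices on genuinely open points

- **Shares as percentages, change values as fractions.** Panels store
  shares on the 0–100 scale; SCVs are reported as signed fractions
  (0.018 ≙ 1.8 points), matching how such decomposition tables are
  printed. The conversion lives in exactly one place
  (`structural_change_values`).
- **Baseline for the first published row.** Published six-row tables
  over a six-year window imply differencing against an unpublished
  prior year; the package makes that baseline an explicit optional
  argument rather than guessing.
- **Dense ranks for ties.** Published tables have no ties, so tie
  behaviour had to be defined: tied degrees share the smaller rank,
  subsequent ranks are not skipped, and ties are reported explicitly.

## Limitations

- **Per-year coefficient reproduction is not guaranteed.** Under strict
  initial-value normalisation every series starts at 1, so every
  first-year Δ is 0 and every first-year coefficient is 1. The bundled
  published coefficient table has first-year coefficients well below 1
  (0.335–0.726), so whatever base point or normalisation produced it
  differs from the stated initial-value method; it cannot be
  reproduced from the stated procedure. What *is* reproducible — and is
  what the tests assert — is the degree row from the printed
  coefficients (the column means, at 3 d.p., for seven of eight
  factors) and the rank row from the degree row. The eighth factor
  (dependency ratio) has a column mean of 0.63550, exactly on the
  3 d.p. rounding boundary, and is excluded from the cell-level check.
  The `mean_value` normalisation option exists so users can explore
  such discrepancies; the choice is always an explicit, logged config
  field.
- The published abstract reports slightly different top-two degrees
  (0.787/0.682) than its own coefficient table yields (0.800/0.673);
  the bundled data follow the table.
- GRA degrees depend on the set of comparison series (global extrema);
  cross-study degrees are not comparable unless computed on the same
  factor set.
- No inferential statistics are attached to either method — both are
  descriptive, and with n = 6 years any such inference would be
  hollow.
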
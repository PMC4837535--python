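# Methods

## The index and its decomposition

For geographic units *i* with population shares *p_i* and resource
shares *y_i*, the package computes the population-share-weighted mean
log deviation ("Theil-L"):

    T = Σ_i p_i ln(p_i / y_i).

T is the Kullback–Leibler divergence of the resource-share distribution
from the population-share distribution, so on normalized shares it is
non-negative and zero exactly when allocation is proportional to
population. It is *not* bounded above by 1 — a unit holding population
but a vanishing resource share drives T → ∞ — and no cap is applied,
because capping would destroy the decomposition identity. (Popular
summaries that give the index a [0, 1] range describe the values
typically observed, not the statistic.)

For any partition into groups *g* (group shares p_g = Σ_{i∈g} p_i,
y_g = Σ_{i∈g} y_i; within-group index t_g computed on shares
renormalized by p_g and y_g):

    T = Σ_g p_g t_g + Σ_g p_g ln(p_g / y_g) = T_intra + T_inter

is an algebraic identity — it does not depend on the data, or even on
the share vectors summing to one. `decompose` therefore recomputes the
total independently and asserts |T − (T_intra + T_inter)| < 1e-12;
a violation indicates a software defect, never a data property.
Contribution rates divide each component by T and are reported as
`None` (not 0/0) when T = 0.

The population-weighted form is the only member of the
generalized-entropy family whose between/within weights are the p_g
above; the resource-weighted Theil-T (Σ y_i ln(y_i/p_i)) is a different
statistic with y-weights in its decomposition and is intentionally not
offered as a substitute.

## Share denominators: slice sums vs published totals

`build_share_vector` defaults to p_i = pop_i / Σ pop over the year
slice, so both share vectors sum to one and T ≥ 0 is guaranteed. Chinese
yearbook analyses, however, divide by the *national* totals, which
exceed the 31-province sums because some entities (e.g. centrally
administered and armed-forces facilities) are counted nationally but
attributed to no province — in 2013 the provincial populations sum to
1.35516 billion against a national total of 1.36072 billion. Passing
`population_total=` / `resource_total=` reproduces that convention; the
share sums then fall slightly below one (tracked by
`ShareVector.is_normalized`), the decomposition identity still holds
exactly, and within-group terms t_g are unaffected because their
renormalization cancels the denominators. The packaged national-totals
table (`load_china_national_totals`) supplies these denominators; the
national index under this convention is what matches the published 2013
series, and is what `scripts/acceptance.py` reports.

## Zero shares and the epsilon floor

A unit with p_i > 0 and y_i = 0 makes T infinite. The default is a hard
`ZeroResourceError` naming the offending units: silent infinities and
silent flooring both hide data problems. For exploratory use,
`epsilon_floor=True` floors zero resource shares at ε (default 1e-12,
configurable), rescales y to its original sum, and flags every
downstream result `adjusted=True`. Units with p_i = 0 contribute zero
regardless of y_i (the p ln p → 0 limit).

## Numerical tolerances

* Additivity identity: 1e-12 absolute. For n ≈ 31 and T of order
  10⁻²–10⁻¹ the floating-point residual is ~1e-16; 1e-12 leaves four
  orders of margin while remaining far below the 3–4 decimals results
  are reported at.
* Share-sum checks: 1e-9 — generous against accumulation over a few
  dozen additions, strict against real data errors.
* Panel CSV round-trips are bit-exact: files are written at full double
  precision and read back with correctly-rounded `float()` conversion.

## The packaged 2013 fixture

The fixture transcribes the published 2013 cross-section: 31
provincial-level units with population (10,000-person units), land area
(10,000-km² units) and four indicators (health-care institutions,
health technical personnel, beds, government health investment in
hundred-million yuan). Absolute amounts are reconstructed as printed
per-capita value × population, computed in exact decimal arithmetic, so
recomputed per-capita densities reproduce the printed table exactly
while absolute counts inherit the table's rounding (well below 1 % for
counts printed with 3–4 significant digits). Two transcription
judgments are encoded: the source table prints two rows named "Shanxi";
cross-referencing areas and the 12/8/11 regional structure, the
3764-population row is named Shaanxi (western group) and the
3630-population row Shanxi (central group). Fujian, absent from the
printed region lists, is assigned to the eastern group per the standard
statistical division.

Two published figures are *not* reproducible from the printed data and
are documented rather than matched:

* the 2013 national investment index (published 0.011): per-capita
  investment is printed with only 1–2 significant digits (0.05–0.13),
  and the reconstruction yields ≈ 0.020 (≈ 0.013 if reconstructed from
  the per-area table instead) — the printed precision is simply
  insufficient for a 3-decimal index;
* the personnel per-capita growth figure "25.8 %": the published
  per-capita column (41.48 → 52.92) gives 27.6 %.

Percent changes are computed on the published per-capita columns (the
rounded, printed densities), matching published growth arithmetic;
`national_density_trend(..., prefer_published=False)` recomputes from
raw counts instead.

The per-area density is amount / area with area in 10,000-km² units.
The published geographic table mixes scales across columns (count
indicators appear divided by a further 10⁴); since extremal *ratios*
are scale-free, comparisons against that table use ratios, not levels.

## Synthetic panels

`generate_panel` draws panels that emulate the statistical structure of
the real data while making the two decomposition terms independently
steerable:

* **Populations** — log-normal with dispersion σ = 0.9 (about a 30-fold
  spread across 31 units, as in the real panel), mean 44 million; areas
  log-normal with σ = 1.3.
* **Within-group scatter** — for each group and indicator, unit resource
  shares ~ Dirichlet(α_g · n_g · w), where w are the within-group
  population shares. E[share] = w for any α; t_g shrinks like 1/(2α).
  Default α = 50 gives t_g of order 0.01, the magnitude seen in the
  2013 fixture.
* **Between-group gradient** — each group's total is
  (base level) × (group population) × skew_g, so y_g ∝ skew_g p_g and
  uniform skew forces T_inter = 0 exactly. Default skew for the
  canonical 3-group layout is (1.15, 0.95, 0.85), a mild rich/middle/
  poor gradient; for other group counts the default is uniform.
* **Defaults** otherwise mirror the study layout: 31 units, 3 groups,
  years 2009–2013, four indicators at the 2013 national per-capita
  levels, 8 % annual growth in levels and 0.5 % in population.

All sampling flows from a single integer seed through a local
`numpy.random.Generator`; output is byte-identical across runs.

What the generator does **not** emulate: spatial autocorrelation,
within-unit (urban/rural) heterogeneity, serial correlation of the
Dirichlet draws across years (each year is redrawn independently), or
calibration to actual 2009–2012 values. Passing tests therefore
demonstrate correctness of the estimator and decomposition mechanics on
realistic magnitudes — not that any real panel satisfies the model's
independence assumptions.

## Problem sizes in the test suite

Property tests run on random share vectors of 2–30 units with random
partitions of up to 5 groups (1000 draws in the batched acceptance
property, 60 examples per hypothesis property); parameter-recovery
sweeps average 34–40 seeded replicates at three levels of α and of the
skew spread (≥ 200 replicates per sweep), with one year and one
indicator per replicate. These sizes make the full suite run in seconds
while keeping Monte-Carlo standard errors an order of magnitude below
the monotone effects being detected.

## Known limitations

* The Theil index compares *shares*; it is silent about absolute
  adequacy (a uniformly under-resourced country scores a perfect 0) and,
  like all members of the generalized-entropy family, its value is not
  directly comparable across populations with different unit counts.
* Only the 2013 cross-section ships as data; multi-year published
  series require the corresponding province-level inputs, which the
  trend machinery accepts but the package does not bundle.
* The epsilon floor is a presentation device: results with
  `adjusted=True` depend on ε and should not be reported as measured
  inequality.
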
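# Methods

## The screening problem

A candidate doping-biomarker panel is a set of gene symbols reported as
transcriptionally responsive to rHuEPO administration. The screen asks,
for each candidate, whether two legitimate physiological stimuli —
exercise and altitude-induced hypoxia — can produce the same signal. Genes
moved by either stimulus are flagged as confounded; the remainder form the
confounder-free panel. All comparisons are at the level of harmonised gene
symbols: the source datasets span platforms, eras of nomenclature and
statistical frameworks, so symbol-level overlap is the most robust common
denominator (no cross-study fold-change comparison is attempted).

## Exercise responsiveness

The exercise evidence arrives as summary statistics only: per-condition
mean and SD of normalised expression across six conditions (acute aerobic,
acute anaerobic, long-term aerobic, long-term resistance, other, and a
sedentary control), plus a single omnibus Kruskal–Wallis p per gene.
Group sizes are not published, which dictates two modelling choices:

* **Equal-weight pooled SD.** Cohen's d is
  `(m₁ − m₂) / sqrt((s₁² + s₂²)/2)`; an n-weighted pooled SD is impossible
  without group sizes. d is computed from the summary statistics even when
  per-sample values exist, so results match the summary-level source.
* **NaN p as a first-class state.** When every value in every group is
  identical, the rank test's tie-correction denominator vanishes and no p
  exists. Such genes are not discarded: effect sizes remain computable
  from means and SDs, so NaN passes the gate alongside p < α.

A gene is *responsive* when it passes the gate (p < α, default α = 0.05
strict, or NaN; the gate can be disabled) and |d| ≥ 0.5 (a moderate
effect) in at least one non-control modality. Statuses partition a panel
into significant / nan_p / not_significant / missing.

Degenerate case: both SDs zero with unequal means yields an undefined d,
reported as signed infinity; by default it does not count as a threshold
hit (flag `undefined_is_hit` to change). Strict `p < α` is the default
because the boundary is measure-zero on real data; `alpha_inclusive`
exists for exact replication needs.

## Altitude DEG replication

Each altitude study's published cut-offs are encoded as a
`ThresholdConfig` whose inclusivity flags mirror the printed operators
exactly: `FC ≥ 1.2 and FDR ≤ 0.05` (both inclusive); `|log₂FC| ≥ 1` with
no p criterion; `q < 0.01 and |log₂FC| > 0.5` (both strict). Thresholds
are applied two-sided on |log₂FC| by default — published DEG lists
conventionally include down-regulation and none of the sources states a
direction restriction — with a one-sided flag available. Linear and log2
effect fields are interconvertible (`log₂FC = log₂ FC`), and a row missing
a required adjusted p fails rather than erroring. Per-contrast pass sets
(altitude intervals, day labels) are retained beside each study-level
union; the cross-study union plus a per-study presence matrix form the
hypoxia-responsive panel.

## Overlap and attribution

The two-step framework first aggregates the altitude sets, then
decomposes candidate-panel membership against the altitude union and the
exercise-responsive set into the seven exclusive Venn regions (counts sum
to the three-set union; each gene sits in exactly one region). Attribution
assigns each candidate∩altitude gene to the exact combination of source
studies containing it; categories are mutually exclusive and exhaustive by
construction. The confounder-free panel is the set difference
`candidates \ (altitude ∪ exercise)`, with provenance carried through.

## Symbol harmonisation

Resolution is offline and table-driven: a primary snapshot table
(approved symbol, synonyms, biotype, description, stable IDs) and an
optional secondary table for identifiers — typically LOC placeholders —
that acquire an official name only in a second source. Matching is
case-insensitive on an uppercase key after whitespace trimming; empty
input is an error. An exact approved match always beats a synonym match.
Synonym ambiguity is resolved by total tiers (protein-coding biotype,
then non-empty description, then lexicographically smallest approved
symbol), so results are independent of input order; the `ambiguous` flag
records that more than one candidate existed. Where primary and secondary
tables disagree on metadata, the primary wins. Post-resolution duplicates
collapse with provenance union. Harmonisation is idempotent, and the audit
log always has one row per input.

## Over-representation analysis

Per term: `p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` via the survival
function (evaluated in log space by scipy), BH step-up adjustment across
terms, fold enrichment `(k/n)/(K/N)` and rich factor `k/K`. The background
universe is explicit: `measured` (the genes the experiment could actually
detect — the honest testable space) or `genome` (an annotation-wide set,
used when no measured space exists; it inflates apparent enrichment, which
a property test demonstrates). Input genes outside the universe or with an
excluded biotype (pseudogenes by default in the pipeline) are dropped with
a warning and reported. Ties in the ranking break on term id. The reported
q-value defaults to the BH value; a Storey estimate with a fixed λ grid is
available behind a flag, and a normal-approximation z score
`(k − nK/N)/√Var` can be attached for descriptive purposes — it is not
part of the test. No term-size filters are applied by default, and no GO
DAG propagation or redundancy reduction is attempted.

## Synthetic data: what it emulates, what it does not

Generators exist so that every stage has a recovery test with known truth:

* **Expression** — group-wise Gaussian on a normalised-log scale
  (baseline mean ~ N(5, 2), per-gene SD ~ U(0.3, 1.5), defaults chosen as
  a plausible normalised-expression scale), 30 samples per group by
  default (source group sizes are unpublished, so this is configuration,
  not fact), planted effects as mean shifts of `d × SD` in one modality,
  and all-constant genes to force NaN p. The summary table is derived
  exactly as the screen expects (ddof = 1, omnibus rank test).
* **DEG tables** — planted true DEGs sample their effect and adjusted p
  inside the passing region of their dialect's cut-offs; every other row
  is forced to fail the effect criterion, the p criterion, or both.
* **Alias tables** — configurable fractions of a panel emitted as
  historical synonyms, case/whitespace damage, or LOC placeholders
  resolvable only via the secondary table (with an unresolvable
  sub-fraction), with the intended resolution and route recorded.
* **Annotations** — random uniform terms plus planted terms over-sampled
  (default 80%) from a designated input set.

Each generator draws from its own RNG stream (`default_rng([stream,
seed])`), so outputs are byte-stable and mutually independent. What the
synthetic data does *not* capture: heavy-tailed and zero-inflated real
expression, correlated genes, batch structure, platform differences, and
annotation bias. Passing recovery tests therefore demonstrates that the
*rules* are implemented correctly and are well calibrated under their own
assumptions — not that the screen's operating characteristics on real
cohorts match the synthetic ones.

## Numerical and design notes

* TSV writers use `%.17g` and readers round-trip float parsing, so
  write∘read is an exact identity, including literal `NaN` p-values.
* The published effect-size values were evidently computed from unrounded
  source data; the shipped reference inputs carry two decimals. The test
  suite therefore asserts *interval consistency*: the published value
  (± its own print-rounding) must be reachable when each input moves
  within ±0.005. Cohen's d is monotone in each argument separately, so the
  extrema are attained at interval corners.
* Kruskal–Wallis uses the tie-corrected H with the χ² approximation
  (adequate at the group sizes involved; an exhaustive permutation oracle
  bounds the approximation error in the tests); the all-identical case
  returns NaN rather than raising.
* Test problem sizes (e.g. 10 recovery replicates at 210 genes, 200
  calibration seeds at 30 terms) were chosen to make Monte-Carlo bounds
  tight enough to be meaningful while keeping the default suite fast.

## Known limitations

* The screen treats the omnibus p as gene-level; if the upstream source
  ever switches to per-modality p-values the gate would need a per-record
  form.
* Attribution reports sharing patterns only; it does not model the
  within-study altitude-interval assignment of genes passing multiple
  contrasts (per-contrast sets are exposed for that purpose).
* Overlap significance is not tested (no null model for set overlap is
  provided), matching the descriptive use of the Venn decomposition.
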
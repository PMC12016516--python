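# Methods

## Statistical model

### The 2×2 construction

The enrichment test compares one protein's spectral counts against the
rest of the purified fraction, experimental vs. control.  Counts are
pooled (summed) across replicates:

|                      | experimental | control |
|----------------------|--------------|---------|
| this protein         | a            | b       |
| all other proteins   | c            | d       |

Pooling is a deliberate choice: an exact test needs integer counts, and
per-replicate means cannot feed one.  Replicate-level information is not
lost — it enters the rank through the detection count (below).  The
one-sided P value is the hypergeometric upper tail

P = P(X ≥ a),  X ~ Hypergeom(N = a+b+c+d, K = a+b, n = a+c),

computed with `scipy.stats.hypergeom.sf` and clamped to (0, 1] so that
−log₁₀P stays finite.  One-sidedness reflects the scientific question:
only enrichment in the experimental fraction evidences a partnership;
depletion is uninteresting.  The test suite verifies the implementation
against an exact big-integer enumeration oracle on every 2×2 table with
all four margins ≤ 60 (≈ 2.4 million tables, agreement < 1e−9).

P values are Benjamini–Hochberg adjusted **within** each bait/condition
comparison, across exactly the proteins tested there (those detected in
≥ 1 experimental replicate).  Thresholds are applied to adjusted P by
default (`p_mode="adjusted"`); raw-P mode is available because the source
procedure does not state which was used.

### Fold change

log₂FC = log₂((x̄_exp + c)/(x̄_ctrl + c)) with per-run means and
pseudocount c = 0.5.  Most true partners have zero control counts, so a
pseudocount is unavoidable; 0.5 is the conventional half-count.  With
`normalize=True` the means are first rescaled to a common library size
(total counts per run); pooled counts for the exact test are never
rescaled, since rescaled counts are no longer counts.

### Significance, rescue, rank

Significant ⇔ P_adj < α (0.05) **and** log₂FC ≥ 2.

Bait rescue: when the bait's own record has P_adj < α but
`rescue_floor` ≤ log₂FC < 2, the fold-change cutoff for that comparison is
lowered to the bait's log₂FC and significance recomputed; records that
pass only the lowered cutoff carry `rescued=True`.  The floor (default 1)
prevents a failed purification from dragging the cutoff toward 0; rescue
is meant for baits that *narrowly* miss.

Rank (significant records only): start at 5 and deduct

- one point per experimental replicate short of 3 (so detection in 1 of 3
  costs two points — the minimal reading of "one point per missing
  parameter" that can produce rank 1 under three categories);
- one point if P ∈ (0.01, 0.05] (the strict band is inclusive at 0.01);
- one point if log₂FC < 4.

floored at 1.  For rescued records (log₂FC below 2) the fold-change
deduction is taken as "log₂FC < 4" rather than the interval
[2, 4) — identical on every non-rescued record, and a single deduction for
rescued ones.  The replicate category always refers to the experimental
replicates; a fourth control replicate improves the test, not the rank.

Volcano-plot guide lines are −log₁₀ 0.05 ≈ 1.3 and −log₁₀ 0.01 = 2.

## Networks

Every significant, ranked (bait, prey, condition) triple is one directed
edge with attributes rank ∈ {1..5}, sulfur, pyruvate, rescued.  The bait
copurifying its own protein is recorded as a purification-success
annotation (`self_edges`), never as a partner.  Condition lives on the
edge, not in separate graphs, so ±S° contrasts are edge-set queries.
"Copurified by a complex" means by ≥ 1 tagged subunit of it; reciprocity
between two complexes requires evidence in both directions and excludes
subunits the complexes share (e.g. the γ subunit TK1978 shared by POR and
VOR), since a shared subunit cannot distinguish the two assemblies.
Exports (SIF, GraphML, edge TSV) are sorted, hence byte-deterministic;
GraphML round-trips every edge attribute exactly.

## Synthetic data generator

`simulate_experiment` emulates the statistical structure of the study
design, not its chromatography:

- **Proteome** of 2,306 proteins (`TK0001`…), of which a fraction
  (default 0.25) are background resin binders with per-protein mean
  counts ~ Exponential(background_mean = 10); this yields a few hundred
  identified proteins per run, matching the sensitivity regime of the
  modelled experiments.
- **Counts** are negative-binomial with dispersion k = 5
  (var = μ + μ²/k): spectral counts are overdispersed, and the
  calibration/recovery properties must hold under that extra variance,
  not just under Poisson noise.
- **Design**: 3 experimental replicates per bait/condition vs. 4 shared
  parental controls per condition; two conditions (±S°) by default.
- **Planted partners** (default 30 per bait, the study-scale average):
  experimental mean = (control mean + 1) · 2^effect, with effect ~
  U[2, 6] spanning both decision boundaries.  The "+1" floor is needed
  because most partners have zero control mean, where a pure
  multiplicative effect would be degenerate; it represents the minimum
  abundance a real partner contributes to the pulled-down complex.
- **Sticky proteins** (default 5%) have means elevated 8× in *every* run,
  experimental and control alike — a correct pipeline must reject them.
- **Undetectable proteins** (default 2%) emit zero counts everywhere
  regardless of their true associations, reproducing by construction the
  ferredoxin-1 phenomenon (essential, highly expressed, yet invisible to
  MuDPIT because its tryptic peptides yield no usable signal).  General
  per-protein detectability < 1 is applied as binomial thinning.
- **Seeding** is hierarchical (`SeedSequence((seed, domain, indices…))`):
  every run has its own substream, so enlarging the bait set or adding
  conditions never perturbs previously generated runs, and equal seeds
  give byte-identical TSV output.

What the generator does **not** emulate: peptide-level identification and
FDR filtering, protein length/abundance biases in spectral counting,
correlated contaminant structure across runs, or chromatographic
variation.  Passing the recovery and calibration suites therefore shows
the scoring procedure is correct and well calibrated under a realistic
noise model — it does not certify performance on any particular real
instrument's data.

## Numerical and testing choices

- Exact-test agreement tolerance 1e−9 against the enumeration oracle;
  observed agreement is ~1e−15.
- BH adjustment delegates to statsmodels and is checked against a
  hand-rolled step-up oracle.  Note the step-up map is *not* idempotent
  (re-adjusting can raise values further); the suite asserts the
  properties that do hold: inflationary, order-preserving, bounded by 1,
  flat vectors fixed.
- Property suites run on scaled problems chosen to exercise the same
  regime at desk scale: null calibration uses 50 partner-free simulations
  of a 400-protein proteome (observed mean significant fraction
  ~7×10⁻⁴, far below α); recovery uses 25 seeds of a 500-protein,
  30-partner design with effects ≥ 4 (observed recovery ≈ 100% at
  rank ≥ 4).  Generator defaults remain the study-scale values.
- Degenerate inputs: an all-zero 2×2 table is an error; proteins absent
  from all experimental runs are not tested; an undetected bait logs a
  warning and disables rescue; empty networks export valid documents that
  still declare bait nodes.

## Known limitations

- The pooled-count Fisher test treats replicates as exchangeable; strong
  replicate-level batch effects would violate the pooled null.
- No spectral-index abundance measures (NSAF/emPAI) and no probabilistic
  scoring (SAINT-style mixtures) — out of scope by design.
- The rank-1 rule (per-missing-replicate decrement) is a reconstruction:
  three binary categories alone cannot produce rank 1, and the chosen
  decrement is the minimal extension that can.
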
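# Methods

## The model

A coded bout is one totally ordered stream of categorical actions from a
fixed k-code alphabet (k = 9 for the TKDOT scheme). Lag-sequential analysis
asks, for each ordered pair (focal, conditioned), whether the conditioned
action follows the focal one at lag k more often than the independence
model predicts. The statistics are computed from the transition table
O[i, j] = #{t : x_t = i, x_{t+lag} = j}, accumulated per sequence; pairs
never span a sequence boundary, so N = Σ_s max(len(s) − lag, 0).

Under the independence null, E[i, j] = n_i· n_·j / N. The omnibus tests are
Pearson's χ² = Σ_{E>0} (O − E)²/E and the likelihood-ratio
G² = 2 Σ_{O>0} O ln(O/E) (0 ln 0 := 0), both referred to a χ² distribution
on (k − 1)² degrees of freedom — 64 for the 9-code alphabet, over the
*declared* alphabet even when a code never occurs (a warning lists unused
codes). Per cell, the default residual is the Haberman adjusted residual

    z = (O − E) / sqrt(E (1 − n_i·/N)(1 − n_·j/N)),

the standard in behavioral sequential analysis and asymptotically N(0, 1);
the cruder (O − E)/√E is available via `residual="standardized"`. A cell is
excitatory when z strictly exceeds the upper α/2 normal quantile (1.96 at
α = 0.05) and inhibitory when z falls strictly below its negative; the
per-cell two-sided rate is therefore α with α/2 in each tail, and no
multiple-testing correction is applied across the 81 cells — this mirrors
the reference analysis, which thresholds each cell at 1.96 without
correction. Diagonal (self-transition) cells are legal; there are no
structural zeros by default.

Degenerate cells (a zero marginal, or a marginal equal to N) have zero
estimated variance; their z is reported as 0 rather than NaN so masks stay
well defined.

## Patterns and the tactical model

Excitatory cells become pattern records carrying the observed pair count
and z. Ranking happens within the focal action's tactical block — attack
(OPE, DIA, INA), counterattack (ACA, SCA, PCA), defense (BLO, DOD, CUT) —
descending by count, ties broken by larger z, then lexicographically; the
published tables contain no ties, so the tie-break is a documented
convention rather than an observed case. OPE sits in the attack block
because the reference pattern table groups it there, although the category
itself describes distance control.

The tactical model merges per-group pattern sets into one directed graph.
Attack-focal edges are level 1 → 2 of the offensive–defensive scheme (the
attacker acts, the opponent responds); counterattack- and defense-focal
edges are level 2 → 3 (the original attacker responds in turn). Edge
presence across the male/female groups ("both", "male_only", "female_only")
encodes as an attribute what the reference figures draw as solid, dashed
and dotted arrows — one graph, three renderings. Level roles are assigned
purely from the focal action's class: the stream does not attribute actions
to athletes, so the A/B alternation of the scheme cannot be checked from
the data model. Inhibitory (negative-z) cells are computed and exportable
but given no tactical interpretation.

## Reliability

Two observers' codings of the same bout are compared position by position
(no alignment heuristics; a length mismatch is an error). Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) is banded at two-decimal resolution into weak
(0–0.20), distant (0.21–0.40), moderate (0.41–0.60), strong (0.61–0.80)
and almost perfect (0.81–1); values strictly between printed bands are
rounded to two decimals first. Negative kappa is reported with a
below-chance flag rather than rejected. Because averaging per-bout kappas
and pooling the confusion matrices can disagree, `kappa_report` returns
both.

## The synthetic-data generator

The generator emits exactly the structure lag-1 analysis detects: a
first-order Markov chain per bout, first event from an initial
distribution, later events from the row of a k×k stochastic matrix P. One
seeded `numpy.random.Generator` per simulate call; identical specs give
byte-identical corpora.

`paper_like_spec` calibrates to the published study conditions: 75 male /
76 female bouts, per-bout lengths split so the totals are exactly 11,474 /
12,980 events, initial distribution equal to the published per-code
proportions, and a base transition matrix whose every row equals those
proportions — the independence model on the published marginals, which is
also stationary at exactly those frequencies (so no separate stationary
solve is needed). `planted_pattern_spec` pins chosen cells of a base
matrix to target probabilities and rescales the rest of each row
proportionally.

What the generator does *not* emulate: athlete identity and the strict A/B
alternation, round structure, within-bout non-stationarity, scoring
context, and any higher-than-first-order dependence. Passing tests
therefore demonstrate that the statistics behave correctly on first-order
Markov data of realistic size and marginals — not that real bouts are
first-order Markov.

## Numerical and design choices

- Critical value: `norm.ppf(1 − α/2)` (1.959964 at α = 0.05) rather than a
  hard-coded 1.96; strict inequalities at the threshold.
- Row-stochasticity is validated to 1e−12 before any sampling; cumulative
  rows are clamped so the last bin always closes at 1.0.
- χ² skips cells with E = 0; G² errors if O > 0 where E = 0 (impossible
  under the independence model unless a marginal is zero, which is trapped
  earlier).
- ML transition estimation fills rows with no observed pairs with the
  uniform distribution and warns, keeping the estimate row-stochastic.
- Event-text dialect: UTF-8, `#` comments, `%key=value` directives (`%sex`
  sticky, `%bout` one-shot with auto-numbering), `/` terminator, codes
  upper-cased on read, canonical single-space output so parse∘write is the
  identity.
- Exit codes are fixed for pipeline embedding: 0 ok, 1 check failure,
  2 input error, 3 empty data.

## Validation problem sizes

The Monte-Carlo suites use 500 replicates of ~10,000 uniform lag-1 pairs
for type-I calibration (pooled excitatory rate vs 0.025), 100 replicates of
150 bouts × 75 events for detection power of a planted P(DIA→SCA) = 0.5,
and 20,000 events for ML recovery (max-norm error; the acceptance script
reports the median over 15 replicates because the per-replicate max across
81 cells fluctuates by ±30% around its ~0.018 typical value). Brute-force
oracle equivalence enumerates all 2×2 tables with cells 0–4 plus randomized
3×3 tables with N ≤ 30, compared at 1e−9 relative tolerance.

## Known limitations

- The published omnibus values (χ² = 10478.15 / 13283.10, G² = 11607.89 /
  14009.61) and the full z matrices cannot be recomputed without the raw
  coded sequences, which are not public; they are shipped as reference
  fixtures and used for structural checks only.
- Multi-event (co-occurring) codings are not modeled: the data model is one
  total order per bout, and simultaneous codes are rejected by design since
  lag pairing is only well defined on a total order.
- Kappa is unweighted and global; per-category or time-tolerant agreement
  is out of scope.
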
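# Methods

## Scoring model

A spectrum is a list of (m/z, intensity) peaks. Before scoring, intensities
are base-peak normalized (`I_i ← I_i / max_j I_j`) and scaled:

```
A_i = I_i · mz_i / (1 + ω·I_i),   ω = 1/(I − 0.5),   I = Σ_i I_i .
```

The mass factor up-weights heavy fragments, which are the more diagnostic
ions in EI spectra; ω damps spectra dominated by a single large peak. After
base-peak normalization `I ≥ 1`, so ω lies in (0, 2] and the pole at
`I = 0.5` is unreachable — the code asserts this rather than branching.

The similarity between query *U* and library spectrum *L* is the sqrt-cosine

```
S(U, L) = ( Σ_matched √(A^u A^l) )² / (A^u_total · A^l_total),
```

with the denominators the precomputed totals over *all* peaks of each
spectrum. By Cauchy–Schwarz `0 ≤ S ≤ 1` and `S(X, X) = 1`. A final clamp to
[0, 1] absorbs last-ulp floating-point overshoot of the bound.

**Peak matching.** Peaks match when `|Δm/z| ≤ t` with an absolute tolerance
`t` (default 0.5 Th unit-mass, 0.01 Th accurate-mass — conventional windows
for the two GC-MS regimes). Pairing is one-to-one and greedy: candidate
pairs are taken in order of increasing |Δm/z| (ties toward the lower library
m/z), and each peak is used at most once. A relational-join formulation
would instead pair a query peak with *every* library peak in tolerance; we
reject that as double-counting, which can push S above 1. With distinct
distances the greedy pairing is direction-independent, and symmetry of S is
enforced by test to 1e-9 on random instances. On spectra whose peaks are
separated by more than 2t the pairing coincides with exact m/z binning,
which is used as an independent oracle in the tests.

## Prescreening

For each library spectrum the m/z values of its `m` most intense peaks are
extracted (intensity-descending; intensity ties broken toward the higher
m/z — any deterministic rule works, but query and index must share it).
The `k`-th largest of the query's `n` top peaks is compared against the
first `d_k` entries of every library list, where the depth schedule
interpolates linearly between `d_1 = n` and `d_n = m`:

```
d_k = n + round((k−1)(m−n)/(n−1))     (n > 1;  d_1 = m when n = 1)
```

rounded half-up. This reduces exactly to the consecutive schedule
`d_k = n + k − 1` when `m = 2n − 1` (the graduated MSSearch-style pairs
(4,7), (6,11), (8,15)) and to the constant `d_k = n` for equal-peak pairs
(n = m); for other (n, m) the schedule is our interpolation choice. Queries
with fewer than `n` peaks use all their peaks; shorter library lists are
scanned in full.

Library spectra are ranked by the number of query peaks that found at least
one within-tolerance m/z in their prefix (ties in the ranking broken by id).
Whole equal-count tiers are accepted, highest count first, until at least
`R` candidates have accumulated — a tier is never split, so slightly more
than `R` may be returned — or until every spectrum with ≥ 1 match is
included. Prescreening uses the same tolerance as scoring, which makes the
exhaustive-parameter equivalence below exact.

Two exact guarantees follow from this construction and are property-tested:
candidate sets are monotone supersets in `R`, and per-spectrum matched
counts are non-decreasing in `m` (prefixes only grow). With `n, m` at least
the maximum peak count and `R` the library size, the candidate set is
exactly the set of spectra sharing ≥ 1 within-tolerance m/z with the query,
so the two-stage search reproduces the exhaustive search verbatim.

## Search engine

`LibrarySearch` is an sklearn-style estimator: `fit` scales the library and
builds the index; `search` returns hits with score strictly above the
threshold (default 0.6), sorted by score descending with id as the
deterministic tie-break, optionally truncated to `top_n`. The number of
similarity evaluations per query is reported as the portable cost proxy —
wall-clock comparisons are hardware-bound, operation counts are not. The
prescreen only removes candidates and never alters a score, so prescreened
hits are always a subset of full-search hits with identical scores.

## Inclusion-rate evaluation

For cutoff N,

```
InclusionRate(N) = M_pre(N) / M_orig(N),
```

where `M_orig(N)` counts top-N full-search matches with score > 0.6 summed
over all queries (micro-average: counts are summed before the one division)
and `M_pre(N)` counts those same (query, library id) pairs present anywhere
in the prescreened results, rank-ignored. A 0/0 case is reported as
undefined with a warning, never imputed. Because the scoring stage is
shared, a full-search hit is retained iff its id survives candidate
selection; the evaluator therefore reuses the full-search scores and checks
candidate-set membership instead of re-scoring, which makes (n, m, R) grid
sweeps cheap. A test asserts this equals literally re-running the
prescreened search.

The default grid crosses five equal-peak pairs (4,4), (6,6), (8,8),
(12,12), (16,16) and three graduated pairs (4,7), (6,11), (8,15) with
R ∈ {10, 50, 100, 500}; the grid table is wide — one row per (n, m, R)
triple with one inclusion-rate column per N.

## Synthetic benchmarks

The generator emulates the two acquisition regimes: low resolution draws
30–150 peaks per spectrum on the integer m/z grid [50, 500]; high
resolution draws 5–30 peaks with 4-decimal m/z in the same range.
Intensities follow an exponential law (EI fragment abundances are
heavy-tailed; one parameter suffices) and are base-peak normalized.
Queries are perturbed copies of library spectra: 10% independent peak
dropout (never the base peak), log-normal intensity noise with sd 0.3 on
the log scale, m/z jitter clipped at half the matching tolerance (0 in the
low-res regime, which stays on the unit-mass grid), and 1–5 spurious peaks
at ~5% of base-peak intensity. Every query is guaranteed to share at least
one within-tolerance peak with its source, so the fixtures test the search,
not the tolerance choice. Generation is fully reproducible from the config
seed; queries use a sub-stream of the same seed so library and query sets
are independently reproducible.

The shipped benchmark is 1000 low-resolution library spectra with 200
perturbed queries (and the high-resolution counterpart at the same sizes) —
large enough for tier statistics to stabilize, small enough that the full
evaluation runs in seconds on one CPU.

**What the fixtures do not model:** real EI spectra of related compounds
share correlated fragment series, so real libraries contain many
high-scoring near-neighbours per query. Synthetic spectra are mutually
independent, which makes low-ranked matches scarcer than in real data;
inclusion rates at large N are therefore optimistic here, while the exact
properties (equivalence, monotonicity, self-retrieval) are unaffected.

## Numerical and design choices

- Score threshold is strict (`score > 0.6`).
- Hit ordering ties are broken by spectrum id so runs are reproducible.
- Duplicate m/z within a record are merged by intensity summation at parse
  time; zero-intensity peaks are dropped and logged.
- MSP writing prints m/z with 1 decimal (low-res) or 4 decimals (high-res)
  and preserves unknown metadata lines verbatim; ids travel on a `DB#` line.
- `match_depth` rounds half-up (`floor(x+0.5)`) so the schedule is
  platform-independent; all default pairs interpolate to integers anyway.

## Limitations

- Absolute m/z tolerance only (no ppm mode) — adequate for GC-MS unit-mass
  and the 0.01 Th accurate-mass window, not for high-ppm-range MS/MS use.
- No alternative scores (plain cosine, entropy similarity) and no
  inverted-index acceleration beyond the top-peak prefix scan.
- The evaluation compares the two stages of this engine against each other;
  it does not benchmark external search programs.
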
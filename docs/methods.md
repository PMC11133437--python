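# Methods

## Molecular graph convention

A compound is modelled as its hydrogen-suppressed skeleton: a simple
undirected graph whose vertices are heavy atoms and whose edges are bonds.
Every bond — single, double, or aromatic — contributes exactly one edge, so
a sulfonyl sulfur (one C, two O, one N neighbour) has degree 4. Element
identity, bond order, charge and stereochemistry are deliberately not
modelled: every index here depends on connectivity alone. This convention
is the one under which the bundled sulfadiazine skeleton reproduces its
published descriptor row; no other reading of double bonds does.

Graphs are validated at construction (no self-loops, no duplicate edges,
no isolated atoms, all endpoints declared). A disconnected graph is legal —
the edge-sum formulas remain well-defined — but triggers a warning, since a
drug skeleton should be connected. An edgeless graph is an error for index
computation: it can only be an encoding mistake, and failing loudly beats
returning seven zeros.

## Indices and the edge partition

All seven indices have the form `Σ_{vw∈E} φ(d_v, d_w)`. The implementation
groups edges into degree classes first (the *edge partition*, keys stored
canonically as `(min, max)`) and evaluates `Σ count·φ(a,b)` class by class.
A second, independent evaluator (`brute_force_index`) walks the edges one
at a time; the test suite requires the two routes to agree exactly for the
integer-valued indices (M1, M2, F, ReZG3) and within 1e-9 for the
floating ones (H, SS, ReZG2) on a large seeded batch of random graphs.
The SS radical covers the whole quotient, `√(d_v·d_w/(d_v+d_w))`; the
alternative reading `√(d_v·d_w)/(d_v+d_w)` does not reproduce the bundled
reference values.

Integer-valued indices are returned as exact floats (summed in integer
arithmetic per class, so no accumulation error); H, SS, ReZG2 are computed
in double precision and only rounded (4 decimals, half away from zero)
at reporting boundaries — stored values stay unrounded.

## Regression panel

Each property Y is regressed on each index X by ordinary least squares,
one pair at a time (42 simple models; deliberately no multiple regression,
no multiple-testing correction — the design mirrors a descriptor screen).
With centred sums Sxx, Syy, Sxy:

- B = Sxy/Sxx, A = ȳ − B·x̄
- r = Sxy/√(Sxx·Syy), r² = r²
- S.E. = √(Syy(1−r²)/(n−2)) — the standard error of estimate
- F = (n−2)·r²/(1−r²), p = upper tail of F(1, n−2)
  (computed via the regularized incomplete beta function, as
  `scipy.stats.f.sf`; identical to the two-sided t test on the slope)

Degenerate inputs: n < 3 or a constant predictor raise errors. A constant
*response* is defined as r = 0, S.E. = 0, F = 0, p = 1 instead of erroring,
so matrix-valued callers survive a degenerate column. The estimator is
sklearn-compatible (`SimpleLinearRegression`), with the panel exposed as
fitted attributes; it is cross-checked against statsmodels OLS in the test
suite but does not use it.

## Prediction tables and rounding

Predicted-vs-actual tables default to the *published-equation* convention:
coefficients are first rounded to 4 decimals (half away from zero) and the
line is then applied. That is how a reader uses a reported model
`Y = A + B·X`, and it is how the bundled reference prediction tables were
generated (they are reproducible only from the 4-decimal coefficients;
e.g. 7.5184 + 0.1832·97 = 25.2888 exactly as printed, while the
full-precision fit gives 25.2909). `coef_digits=None` switches to
full-precision predictions, which satisfy `prediction == A + B·x` of the
unrounded fit to 1e-9. Report files round all values to 4 decimals and are
byte-deterministic across runs.

## Bundled study data

The eleven drug skeletons were encoded by hand from the drugs' standard
hydrogen-suppressed structures; each edge-list file documents its atom
numbering. Recomputing the indices from the skeleton reproduces the
bundled descriptor table's row for 7 of the 11 drugs (exact for integer
indices, printed precision otherwise); those carry `verified=True`. The
four others ship `verified=False` with the discrepancy noted in the file:

- **Meloxicam** — all indices match except M1 (computed 126, table prints
  226; the row's own F = 350 = Σd_v³ is consistent with 126, so the printed
  value is almost certainly a digit typo).
- **Sulphadoxine, Diuril, Metahydrin** — full-row mismatches; the drawings
  behind those rows are not recoverable from the reference tables, and the
  fixtures are never adjusted to force agreement.

Because of this, the regression layer of the bundled study uses the
*printed* descriptor table as its X source (the published fits are
recovered only with it — e.g. the M1 intercept 16.5920 requires
Meloxicam's 226), while graph-derived descriptors remain available via
`build_descriptor_table(graphs)` or the CLI `--graphs` mode.

The reference tables themselves mix round-half-up and truncation in their
last printed digit, and contain a handful of demonstrable internal
inconsistencies (a correlation printed with a shifted decimal point, an F
statistic that duplicates its row's S.E., prediction cells computed with a
neighbouring row's descriptor). Reproduction tests therefore compare at
one unit of the last printed decimal (capped at 4 decimals) and exclude
the inconsistent cells explicitly, with the reason stated next to each
exclusion; mismatches are documented, never matched.

## Random graph generator

`random_molecular_graph(seed, n, max_degree)` emulates the *shape* of
organic skeletons for property-based testing: a random spanning tree grown
vertex-by-vertex (guaranteeing connectivity), then ring-closing edges
rejection-sampled under the degree cap (default cap 4, tetravalent
carbon). It is seeded (numpy `default_rng`) and platform-reproducible. It
does **not** emulate chemistry — no per-element valences, no realistic
ring-size distribution, no heteroatom frequencies — so tests passing on it
certify the combinatorial identities (partition/brute-force equivalence,
handshake, hyper-Zagreb `Σ(d_u+d_v)² = F + 2·M2`, vertex forms
`M1 = Σd², F = Σd³`), not chemical realism.

## Problem sizes

The bundled study is tiny by construction (11 drugs, ≤ 38 edges per graph,
42 fits), so all reproduction checks are instantaneous. Property-based
checks use 100–1000 seeded random graphs of up to ~40 vertices, and OLS
parameter recovery uses 200 simulated datasets of n = 200 — sizes chosen so
the statistical assertions (3-SE coverage ≥ 95%) are stable across seeds.

## Known limitations

- Connectivity-only descriptors: isomers with identical degree sequences
  and adjacency degree classes are indistinguishable (sulfadiazine and
  sulfapyridine genuinely share one descriptor row).
- Simple regression only; with 11 observations per fit the p-values are
  screening indicators, not confirmatory inference.
- Four bundled skeletons cannot be validated against their reference rows
  (above); graph-level claims in the tests are restricted to the verified
  seven.
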
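# Methods

This note documents the statistical procedures implemented in `molprice`,
the synthetic-data model used to exercise them, and the numerical and
design choices a maintainer would want spelled out.

## Price metrics

The weight-based metric (WBM) P1 is the catalogue price per gram, taken as
given. The molar-based metric (MBM) is defined as P2 = P1 · MW with MW the
*average* molecular weight in g/mol — the physically correct molar
conversion (nominal, integer masses are used only for parity analyses, see
below). P2 is always derived, never stored independently, so the pair is
consistent by construction and the round trip P1 → P2 → P1 is exact to
machine precision. Units are $/g and $/mol.

## Descriptors

All descriptors derive from composition only (a Hill-notation formula or
an SDF V2000 connection table):

- `mw_avg` — Σ nᵢ·Aᵢ over the embedded IUPAC 2021 conventional atomic
  weights, frozen in `elements.py` for reproducibility without network
  access;
- `mw_nominal` — Σ nᵢ·Mᵢ over most-abundant-isotope integer masses
  (C=12, H=1, N=14, O=16, F=19, S=32, Cl=35, Br=79, I=127, Se=80, P=31);
- atom counts AC (total), C, H, heteroatom = AC − C − H, and per-element
  counts;
- the two parities entering the nitrogen rule: for C/H/N/O-only
  compositions, parity(`mw_nominal`) = parity(N count). A violation is
  possible only for valence-infeasible compositions and is surfaced as a
  data-curation flag (`inconsistent`), never silently accepted.

SDF reading assigns implicit hydrogens per atom as
max(0, valence − bond-order sum − |charge|), using the lowest feasible
valence for multivalent S/Se/P and counting aromatic bonds (type 4) as
1.5 with per-atom rounding, so Kekulé and aromatic benzene both yield
C6H6. Fully explicit-H tables round-trip exactly. When a vendor MF
property field and a connection table disagree, the MF field wins (vendor
fields reflect salts/hydrates the drawing may omit) and the mismatch is
logged. The allowed element set is C, H, N, O, S, F, Cl, Br, I, Se, P;
anything else is rejected by name.

## Data binning

Bins are half-open intervals [origin + i·w, origin + (i+1)·w) anchored at
origin 0, default width w = 1 Da. The floor-based anchored convention was
chosen (the boundary convention is otherwise arbitrary) because it
composes across resolutions: two 1-Da bins tile one 2-Da bin exactly, so
resolution-robustness comparisons are exact aggregations rather than
interpolations. Per bin, the table records occupancy and the mean of each
tracked variable; column sums are conserved (Σ count·mean = Σ raw, tested
at 1e-9 relative tolerance). Empty interior bins are emitted with count 0
and NaN means — flagged, not zero-filled — and excluded from downstream
correlations. The bin representative used as the x-value of binned
correlations is the bin center by default (configurable to the within-bin
mean). Binned correlations are unweighted across bins — one point per
occupied bin — because the instability of sparsely occupied bins is
precisely what the occupancy filter and the credibility nulls are meant
to expose, and weighting would hide it.

## Correlations and credibility nulls

Record-level association is the Pearson product-moment R (Spearman is
available but never the default); the matrix is computed on the
listwise-complete subset (records missing SAS are excluded from the
matrix only, and the n actually used is reported). Constant vectors and
n < 3 are rejected rather than returning NaN.

Binning can manufacture correlation: averaging within bins collapses n
records to B ≪ n points. Two seeded Monte-Carlo nulls quantify this.
The *random-variate* null correlates the fixed descriptor vector with
i.i.d. Uniform(0,1) draws; the *shuffled-price* null applies a fresh
Fisher–Yates permutation to the real price column each run, conserving
every order statistic of prices exactly. For independent vectors |R| is
asymptotically half-normal with scale 1/√n, so the unbinned null mean is
E|R| = √(2/(πn)) — the analytic anchor the tests assert at
n ∈ {10³, 10⁴, 10⁵} and at the full library size n = 2,248,243, where it
equals 5.32 × 10⁻⁴. The binned variants average the null draws within the
descriptor's bins first; with B occupied bins the null mean rises to
≈ √(2/(πB)), which is why a binned trend must clear a far higher bar than
an unbinned one. Default run counts are 10,000 (unbinned) and 2,000
(binned), overridable everywhere; every result records its mode, n, runs
and seed, and identical seeds give bit-identical results (NumPy
`default_rng`). The null engine computes |R| via pre-centered dot
products; `scipy.stats.pearsonr` serves as the independent cross-check in
the tests.

## Sub-libraries and the parity comparison

A sub-library is a filter (≥ min_count atoms of one element, optionally
restricted to C/H/N/O compositions), hence idempotent. The nitrogen-rule
comparison splits records by parity of the nominal mass — equivalently,
within a CHNO sub-library, parity of the N count — and compares class
mean prices inside each MW bin, emitting only doubly-occupied bins.

One consequence of working with average masses deserves emphasis: over
218–739 Da the cumulative mass defect of C/H/N/O compositions stays well
below 1 Da, so a 1-Da bin of average MW contains essentially a single
nominal mass and therefore a single parity class. The parity comparison
consequently defaults to 2-Da bins, the narrowest width in which both
classes coexist; this is also exposed as configuration.

Per-element price profiles report mean P1/P2 by exact atom count k with
occupancies; counts below a configurable threshold (default 30) are kept
but flagged unstable, since sparse-count means are noise. No grouping of
heteroatoms into classes is hard-coded — the profiles let the data show
any grouping.

## Synthetic catalogue generator

The generator creates catalogues with the statistical skeleton the
analysis assumes, at study-condition defaults:

- **MW distribution** — a three-component truncated-normal mixture on
  [218.26, 738.74] Da: a narrow component at 250 Da (σ = 16) carrying the
  global mode, a broad body at 305 Da (σ = 38) and a small heavy tail at
  470 Da (σ = 105). Weights (0.7365, 0.2523, 0.0112) were solved in
  closed form (truncated-normal CDFs) so that P(MW < 350) = 0.96 and
  P(MW < 400) = 0.99 exactly at the population level.
- **Formulas** — per record, heteroatom counts are Poisson draws (rates:
  N 1.1, O 1.0, S 0.15, F 0.12, Cl 0.12, Br 0.05, I 0.02, Se 0.012 —
  chosen so every sub-library keeps ≥ 10³ members at n = 10⁵, a
  testability choice, not market realism); the C/H skeleton is solved
  from the residual mass at an H:C ratio drawn uniformly from [1.0, 1.9],
  with H rounded to the parity that makes the degree of unsaturation
  DBE = (2C + 2 + N − H − halogens)/2 a non-negative integer. Draws
  failing the 0.5-Da mass tolerance or feasibility are redrawn (bounded
  retries, then error). Every emitted formula is valence-feasible; CHNO
  records obey the nitrogen rule by construction.
- **Prices** — P1 = max(1, base + 3.0·min(MW, 250) + Σ nₑ·premiumₑ + ε),
  ε ~ N(0, 150²) $/g. The slope is flat above the 250-Da breakpoint, so
  the rising-price regime exists only at low MW. Premiums per atom:
  N +15, O +6, S +4, F +4 $/g; Cl −18, Br −22, I −28, Se −24 $/g — N, O,
  S, F priced with the skeleton, the heavier halogens and Se planted as
  discounts. The intercept is calibrated per catalogue as
  base = 537.83 − mean(structural part), so the library mean lands on the
  target up to O(σ/√n) noise and rare floor clipping. The noise scale was
  set analytically so the implied corr(P2, MW) falls near 0.47 at the
  default MW distribution; the generator also returns the exact
  closed-form planted corr(P2, MW) (noise integrated out, floor ignored)
  for recovery tests.
- **SAS stand-in** — SAS = clip(a + 0.06·AC + η, 1, 10) with a set so the
  mean score is 4.0 and sd(η) chosen from the attenuation identity
  corr = 1/√(1 + σ²_η/σ²_signal) to hit corr(SAS, AC) = 0.380. This
  column emulates only the one property the analysis consumes (its
  correlation with atom count); it is a declared stand-in with no claim
  of fidelity to any commercial synthetic-accessibility program.

What the generator does *not* emulate: the fine multi-modal structure of
real MW histograms (a smooth mixture approximates it), real structural
chemistry (only compositions exist — no graphs, rings or stereochemistry),
salt/hydrate notation, pack-size economics, and any dependence of price
on synthesis route or demand. Passing recovery tests therefore shows the
*pipeline* recovers planted effects of realistic magnitude under
realistic marginals — not that real catalogues behave this way.

## Numerical and scale choices

Everything is driven by one integer seed through NumPy `default_rng`;
catalogues, null results and report bundles are bit-reproducible.
Problem sizes used by the test suite and the acceptance script: the nulls
run at the full emulated library size (2,248,243 records; 200–1000 runs,
reduced from the headline 10,000 since the Monte-Carlo standard error of
the mean |R| scales as 1/√runs and is already ~2% at 1000); calibration
summaries use 10⁶ samples; planted-parameter recovery uses 10⁵ records.
Curation never imputes: records with unparseable structures, non-positive
prices or duplicate keys are dropped and counted, and the report's
categories must reconcile exactly with the input size. Duplicate key:
same record id, or identical (formula, price) pair — full structural
canonicalisation is out of scope and the key is configurable.

## Known limitations

- Formula parsing is flat Hill notation: no parentheses, hydrates,
  charges or isotopes (catalogue MF fields are flat).
- SDF support is V2000 only; V3000 is an explicit unsupported-dialect
  error. The generator's SDF writer emits composition-only records (MF
  property field over an empty ctab) — it does not invent structures.
- The charge correction max(0, valence − degree − |charge|) is a
  simplification; onium species (e.g. N⁺ with four bonds) are treated
  conservatively rather than with element-specific charge valences.
- Binned correlations treat bins as exchangeable points; no spatial/serial
  correlation across adjacent bins is modelled.
- The economic interpretation of any recovered trend is out of scope; the
  package measures associations and their credibility against nulls.
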
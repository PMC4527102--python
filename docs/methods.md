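# Methods

## Setting

The package analyses a protein × (sample, replicate) spectral-count
matrix for a two-group comparison. Spectral counting treats the number
of MS/MS spectra matched to a protein as a rough abundance measure; it is
integer-valued, zero-inflated for low-abundance proteins, and heavily
right-skewed across a proteome. The reference design is 5 control vs 15
case biological samples with three injections each, but nothing in the
code assumes those numbers.

All statistics operate on *pooled* counts: technical replicates are
summed within each biological sample first, and the 2×2 tests further sum
across samples within a group. Pooling replicates stabilises the counts
and is exactly conservative (the multinomial replicate model in the
simulator makes this an identity, not an approximation).

## Statistics

**Spectral index.** `SpI = (d_B/N_B)(n_B/(n_A+n_B)) −
(d_A/N_A)(n_A/(n_A+n_B))`. The first factor of each term is the fraction
of that group's biological samples in which the protein was detected; the
second its share of the protein's pooled counts. The product form keeps
SpI in [−1, 1], makes it antisymmetric under swapping group roles, and
rewards effects that are consistent *across samples*, not only large in
aggregate — the detection fractions are what distinguish SpI from a bare
count ratio. When the protein is absent from the control group, SpI
reduces to the case detection fraction `d_B/N_B`. SpI is undefined (and
refused) when the protein was never observed.

This formula reproduces all 31 published spectral-index values bundled in
`spcdiff.datasets` to the three printed decimals (largest deviation
3.3 × 10⁻⁴, i.e. rounding of the printed column); that reproduction is
asserted in the test suite and recomputed by `scripts/acceptance.py`.

**R_SC.** The pseudocounted log2 ratio with group-total correction,
`log2((n_B+f)/(n_A+f)) + log2((t_A−n_A+f)/(t_B−n_B+f))`, `f = 0.5`. The
totals `t_A`, `t_B` are taken over all proteins in the analysed matrix.
The bundled reference table's printed R_SC column is *not* recoverable
from its printed pooled counts under any single pair of totals (the
required offsets differ row by row, suggesting the published values used
counts normalised in some unstated way), so R_SC correctness is anchored
to exact-rational reimplementation of the formula rather than to the
printed column; no test asserts those printed R_SC values.

**G-test with Yates correction.** The 2×2 table is (target protein, all
other proteins) × (control, case), i.e. cells `(n_A, n_B; t_A−n_A,
t_B−n_B)`. Each observed cell is shifted 0.5 toward its expectation,
clamped so a cell whose deviation is below 0.5 contributes nothing, then
`G = 2 Σ O′ ln(O′/E)` over cells with `O′ > 0`, with `p` from χ²₁. The
implementation computes the adjusted deviation `(O′−E)/E` with an exact
integer numerator and uses `log1p`, which keeps the relative error below
10⁻¹⁰ against a 50-digit arbitrary-precision oracle even for near-null
tables where the naive sum cancels catastrophically. Tables with a zero
margin are refused (`DegenerateTableError`) and the protein is carried
through with null statistics and a logged reason.

**Exact validation tests.** Fisher's exact two-sided p (scipy) sums
hypergeometric probabilities of all tables at the observed margins no
more probable than the observed one; the test suite checks it against
exhaustive enumeration in exact rational arithmetic for every table with
margins ≤ 12. The Mann–Whitney U test runs on the pooled per-sample
counts of each protein, unnormalised (matching the universe of the
G-test). U counts case wins with half-credit for ties. For combined
sample counts ≤ 25 the p-value comes from the exact permutation
distribution of U over all group-label assignments — computed via the
midrank identity `U = R_case − n_case(n_case+1)/2`, which remains valid
under ties, with the two-sided p doubling the smaller tail (capped at 1);
beyond 25 samples the tie-corrected normal approximation with continuity
correction is used. The cutoff makes the reference design (5 + 15,
15 504 assignments) exact.

**Classification.** Case-characteristic: `p_G < α` and `R_SC > 1`;
control-characteristic with `R_SC < −1`; top tier additionally `p_G <
10⁻⁴` and `|R_SC| > 2`. The SpI rule (`|SpI| > 0.4`) is reported as a
flag but does not gate the label: the selection criteria are the p/R_SC
pair, with SpI kept as an orthogonal, detection-aware indicator. No
multiple-testing correction enters the classification; a
Benjamini–Hochberg FDR column is attached for information.

## Synthetic data

`generate_dataset` draws, per protein `p` and sample `j`, a mean
`μ_pj = baseline_p · depth_j · fold_p^[j∈case]` with log-normal baselines
(default median 5 counts, log-sd 1.5 — a heavy right tail spanning
roughly three orders of magnitude, as proteome-wide spectral counts do)
and mean-one log-normal depth factors (log-sd 0.3). Sample counts are
negative binomial with variance `μ + μ²/k` (default `k = 2`, substantial
biological heterogeneity; `k = ∞` gives Poisson), zeroed with probability
`logistic(−slope·(μ − midpoint))` (default midpoint 1, slope 1: dropout
is appreciable only below a few expected counts), and split into
replicate injections by a symmetric multinomial. Defaults mirror the
reference design: 508 proteins, 5 vs 15 samples, triplicates, 20% of
proteins affected with fold 2 or 4 in either direction.

What the generator does **not** emulate: peptide-to-protein inference and
shared peptides, correlated dropout across proteins, batch effects, and
any intensity-level structure. Passing operating-characteristic tests
therefore demonstrates correctness of the statistics under the stated
count model, not performance on any particular real acquisition.

## Operating characteristics, and an honest caveat

Two regimes matter:

- **Count-limited (Poisson) sampling** — the regime the pooled 2×2 tests
  implicitly assume, since pooling collapses biological samples into one
  pair of totals. Here the Yates-corrected G-test is well calibrated at
  depth: measured null call rate ≈ 0.046 at α = 0.05 for mean counts
  above 50 (it is anticonservative for very small counts, which is what
  the continuity correction mitigates). SpI and R_SC point in the true
  direction for ≥ 97% of fold-4 effects at mean count ≥ 30.
- **Biologically overdispersed sampling** (the generator's default,
  `k = 2`). The pooled G-test ignores between-sample variance entirely,
  and its null call rate rises to ≈ 0.69 in the same high-count setting;
  SpI sign accuracy for down-regulated proteins in the asymmetric 5 vs 15
  design drops to ≈ 0.74, because SpI's count-share margin (≈ 0.14 for a
  4-fold change) is smaller than the biological coefficient of variation
  regardless of depth.

The calibration and power checks in the test suite and acceptance script
therefore run in the Poisson regime, which is the claim the pooled tests
can support; the overdispersed numbers above are reproducible with
`evaluate_calls` at the default config and are the reason the pipeline
carries the distribution-free Mann–Whitney test (computed on per-sample
counts, hence sensitive to biological variance) as a validation column.
Power figures quoted in the README use 120-protein matrices over 200
paired seeds (power) or 20 seeds (calibration); these sizes give
binomial standard errors below one percentage point on the reported
rates.

## Numerical and design choices

- Detection means pooled per-sample count ≥ 1 (threshold configurable);
  with this rule a protein's detection count is zero exactly when its
  pooled group count is zero.
- Column order is canonicalised (control samples, then case, each
  lexicographic by sample id, replicates in index order) so every output
  is deterministic; repeated runs are byte-identical, and the simulator
  is fully reproducible from its seed.
- Never-observed proteins stay in the matrix but are excluded from
  testing and the presence partition, with a logged count.
- p-values are floored at the smallest positive double so reported values
  lie in (0, 1]; records are sorted by descending SpI with entry name as
  the tie-break.
- Degenerate tables (a protein holding *all* counts, or an empty group
  margin) are skipped per protein, never fatal for the run.

## Limitations

Spectral counting saturates for very abundant proteins and undercounts
short ones; none of that is corrected here (no NSAF/emPAI). The pooled
tests share one universe (`t_A`, `t_B`), so results change if the matrix
is subset before analysis. The exact Mann–Whitney branch enumerates all
assignments and is meant for small designs; very unbalanced large designs
fall back to the asymptotic path.
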
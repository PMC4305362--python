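# Methods

## Model and fitting

`anovatab` analyses complete two-factor layouts: every combination of the
a levels of factor A and the b levels of factor B (a *treatment*) must be
observed at least once. Observations are assumed independent and normal
with a common variance σ² across treatments; neither assumption is tested
by the package, so it should be used only where they are plausibly close
to true.

The two-way fit computes sequential (Type I) sums of squares by nested
least-squares projections on treatment-coded design matrices: SS(A) from
intercept→A, SS(B|A) from A→A+B, SS(A×B|A,B) from A+B→full. F ratios use
the residual mean square; p-values come from the F survival function
without finite-sample corrections. In balanced designs the decomposition
is orthogonal and order-invariant; in unbalanced designs the entry order
matters, which is surfaced rather than hidden — `--both-orders` emits one
table per order. Type I was chosen over Type II/III because the
order-dependence is the behaviour the surrounding workflow documents and
explains to its users; it also makes the sum-of-squares identity
SS(A)+SS(B|A)+SS(A×B)+SS(res) = total corrected SS hold exactly, which
the tests exploit.

All post-hoc work collapses the design to the cell-means model (one
factor with a·b levels). Its pooled within-cell variance equals the
two-way residual mean square by construction; the suite asserts the
equality to 1e-12 relative.

Designs with exactly one observation per treatment cannot support the
interaction model; they raise a replication error, the sheet is reported
and skipped, and no table is produced for it. Missing numeric values are
dropped per (response, record) pair, so per-cell n can differ between
responses; the design report warns when that happens because the caption's
single "n = …" statement then glosses over per-response differences.

## Pairwise procedures

All procedures compare all a·b·(a·b−1)/2 treatment pairs with the pooled
MSE on N−ab degrees of freedom.

- **LSD** — per-pair two-sided t tests; with `--adjust bonferroni` or
  `holm` the raw p-values are adjusted (Holm: step-down running maximum of
  min(1, (m−rank)·p)). The adjustments are implemented directly (they are
  three lines each) and cross-checked against statsmodels in the tests.
- **Tukey–Kramer** — q = |m_i−m_j| / √(MSE/2·(1/n_i+1/n_j)) referred to
  the studentized range distribution with k = a·b groups (scipy's
  `studentized_range`). With equal n this is Tukey's HSD.
- **SNK / Duncan** — means sorted descending; a pair spanning p ordered
  positions is tested against q(γ_p, p, df) with γ_p = α (SNK) or
  1−(1−α)^(p−1) (Duncan), and a range contained in a non-significant range
  is declared non-significant without testing. Because of this step-down
  protection there is no per-pair p-value; the results carry decisions
  only, which is exactly what the letter display consumes. For unequal n
  the Kramer per-pair standard error is used (harmonic-mean alternatives
  were rejected to keep each pairwise SE exact). Duncan's fractional γ_p
  is evaluated by direct inversion of the range distribution.
- **Westfall-style max-t** — free step-down max-|t| resampling: treatment
  means are simulated under the complete null together with a
  χ²-scaled variance estimate (so each simulated statistic is marginally
  t), and adjusted p-values follow the step-down max-statistic rule with
  monotonicity enforcement, clipped from below by the raw p. This is a
  deliberate simplification of the logically-constrained truncated closed
  testing procedure of Westfall (1997): the free step-down variant ignores
  logical constraints among pairwise hypotheses and is therefore
  conservative relative to the original, while remaining more powerful
  than Holm in the simulated comparisons. Deterministic given `--seed`;
  default 10 000 resamples.

Ties in ordered means are broken by treatment label, making every
procedure deterministic and permutation-equivariant (tested).

## Compact letter display

Insert-and-absorb: start with one column holding all treatments; each
significant pair co-resident in a column splits it into two copies (one
without each member); columns contained in another are absorbed.
Columns become letters ordered by descending column-maximum mean, so "a"
always marks the largest mean; tied means fall back to label order (the
tie rule is a package choice — the convention in the literature leaves it
open). When no pair is significant, no letters are shown at all. The
display is sound and complete (sharing a letter ⟺ not significantly
different) but not guaranteed minimal; against an exhaustive
minimal-clique-cover oracle on ≤6 treatments it matched the optimum or
exceeded it by one letter on every random instance tried. More than 26
letters raises an error (unreachable for realistic two-factor tables).

## Pooled SEM

Balanced: PSEM = √(MSE·2/n), the standard error of every pairwise
difference of means. Unbalanced: the per-pair value
√(MSE·(1/n_i+1/n_j)) is computed for every pair and the maximum
reported — a conservative single number for a layout that really only
suits balanced data. Pooled SEM is computed per response, since each
response has its own MSE.

## Formatting

Means and SEMs are rendered at `--sig-digits` significant digits
(default 3) with half-even rounding via decimal arithmetic, then trailing
fractional zeros are trimmed ("4.20" → "4.2", "12.0" → "12"); the
trimming is cosmetic and matches how such tables are typically printed,
at the cost of sometimes showing fewer than the requested digits.
`format_sigfigs` itself keeps the exact digit count ("3.2" at 5 digits is
"3.2000") for callers that need it. p-values use `--p-decimals` decimal
places (default 3); values below 10^−d print as "<0.001"-style bounds so
a positive p never renders as zero, and trailing zeros are trimmed.

Captions are assembled from the options: summary type, the n statement
(a single n when uniform, a range otherwise), the letter-range sentence
with α and the test name (only when letters were used anywhere), and the
expansion of the interaction column's first-letter abbreviation.

## Input handling

A column is a factor iff at least one value fails numeric parsing;
integer-coded factors (0/1) are therefore responses, and the schema error
says so — levels must be spelled with letters. Exactly two factor columns
are required, in order of appearance; levels are ordered
lexicographically, so prefixing levels with digits ("1Overweight",
"2Lean") overrides the alphabetical default without special casing.
Column names are sanitized to identifiers (spaces → underscore, Greek
letters transliterated to ASCII names, other invalid characters → dot,
invalid leading patterns prefixed with "X"); every change is logged.
Names are never truncated, and factor *level values* are never rewritten.
A column mixing numbers and text is treated as a factor (the unparsable
value decides); this is an explicit policy choice for an ambiguous case.
Legacy `.xls` workbooks are not read (no reader for the legacy binary
format is bundled); `.xlsx` and `.csv` are.

## Synthetic data and what the tests show

`generate_dataset` draws i.i.d. normals per cell — exactly the model's
assumptions, with defaults mirroring the worked example's design (2×2,
n = 9, cell means from the serine row, σ = 20.9, the pooled within-cell
SD implied by that row's SEMs). Missingness is completely at random and
applied to responses only. Real data deviate from this generator in ways
the tests deliberately do not probe: non-normal errors, heteroscedastic
cells, correlated responses, informative missingness. Passing tests
therefore certify the arithmetic and the error-control behaviour *under
the model*, not robustness to violations of it.

`dataset_from_summary` rebuilds raw-looking data from published per-cell
means and SEMs by scaling a fixed standardized vector, reproducing the
printed means, SEMs and hence the pooled MSE exactly. Every statistic
that depends only on those moments (all F tests, all pairwise procedures,
the pooled SEM) is recovered exactly up to the 3-digit rounding of the
printed summaries themselves. That rounding moves integer means by up to
±0.5, which shifts near-null p-values by as much as ~0.1 — the suite's
reconstruction checks use that bound — while leaving the letter patterns
untouched (the smallest significant studentized range in the serine row,
q ≈ 8.5, is more than twice the critical value 3.83).

## Problem sizes and numerical choices

Monte-Carlo checks use 1000 replicates for the family-wise error rate
under the complete null (judged within 3 binomial standard errors of α),
500 random fits for the procedure-nesting property and 1000 random
matrices for the letter-display oracle — sizes at which the binomial
noise is far smaller than the effects being asserted. Sequential sums of
squares are clipped at zero against −1e-15-scale projection residue; the
SS identity is asserted at 1e-9 relative. RTF output is pure ASCII with
\uN? escapes, byte-identical across runs and platforms, and the golden
checks rely on that determinism rather than on stored golden files.

## Known limitations

No Type II/III sums of squares, random effects, covariates or >2 factors;
no Dunnett/control-only comparisons or confidence intervals (tables
report letters, not intervals); no diagnostics for normality or
homoscedasticity; no DOCX/HTML output. The Westfall-style procedure is
the free step-down approximation described above, not the original
truncated closed test.
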
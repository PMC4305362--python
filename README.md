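# anovatab

Publication-ready two-way ANOVA tables for biology and agriculture.

Experiments that cross two nominal factors — a diet and a body-weight
class, a genotype and a treatment — are conventionally reported as one
table row per response variable: the mean ± SEM of every treatment group,
superscript letters encoding which groups differ, and three p-values for
the two main effects and their interaction. Producing such tables by hand
(fit the ANOVA, run a post-hoc test, translate the pairwise decisions into
letters, typeset the result) is slow and error-prone. `anovatab` automates
the whole pipeline: it reads long-format spreadsheets, fits the model,
runs the chosen all-pairwise comparison procedure, builds the compact
letter display and writes editable RTF tables with an auto-generated
caption, plus interaction plots as PDF.

## The model

For factors A (a levels) and B (b levels), the two-way ANOVA with
interaction

y_ijk = μ + α_i + β_j + (αβ)_ij + ε_ijk,  ε_ijk ~ N(0, σ²)

is decomposed with sequential (Type I) sums of squares — SS(A), SS(B|A),
SS(A×B|A,B), SS(residual) — so unbalanced designs are handled, with the
caveat that the factor entry order then matters (a flag emits both
orders). All post-hoc work uses the *cell-means model*: the two factors
collapsed into one factor with a·b levels (treatments), sharing the
two-way residual mean square (MSE).

Pairwise procedures over the treatment means (α = 0.05 by default):

| test | type | error control |
|---|---|---|
| `tukey` | single-step studentized range (Tukey–Kramer) | FWER, strong |
| `snk` | step-down range, γ_p = α | FWER, weak |
| `duncan` | step-down range, γ_p = 1−(1−α)^(p−1) | FWER, weak |
| `lsd` | pairwise t tests (`--adjust none/bonferroni/holm`) | per-pair / FWER |
| `westfall` | free step-down max-\|t\| resampling | FWER, strong |

Non-significant pairs share a superscript letter ("compact letter
display", insert-and-absorb); when nothing differs in a row no letters are
printed. The optional pooled-SEM layout reports a single standard error
per row: PSEM = √(MSE·2/n) in balanced designs, and the maximum of
√(MSE·(1/n_i + 1/n_j)) over all pairs otherwise.

## Worked example

The package ships its worked example as data: per-cell means and SEMs
(n = 9) of 24 plasma amino-acid concentrations from a rat study crossing
diet (HF/LF) with weight class (Lean/Overweight), from which raw-looking
data are reconstructed exactly.

```python
import anovatab as at

ds = at.plasma_dataset(["Ser", "Cit"])
tables, _ = at.analyze_dataset(ds, at.TableOptions(), at.MCPConfig())
for row in tables[0].rows:
    cells = "  ".join(f"{c.text}^{c.superscript}^" for c in row.cells)
    print(row.response, cells, "P:", ", ".join(row.p_values))
print(tables[0].caption)
```

prints

```
Ser  359 ± 10.3^a^  294 ± 4.39^b^  353 ± 7.43^a^  292 ± 3.76^b^   P: 0.57, <0.001, 0.776
Cit  79.9 ± 2.66^a^  53.8 ± 1.63^c^  69.6 ± 3.37^b^  73.9 ± 1.84^ab^   P: 0.056, <0.001, <0.001
Values are means ± SEM, n = 9 per treatment group. a-cMeans in a row
without a common superscript letter differ (P < 0.05) as analyzed by
two-way ANOVA and the TUKEY test. D × W = Diet × Weight interaction effect.
```

Serine responds to weight class only (a,b,a,b: both Lean cells differ from
both Overweight cells); citrulline shows a diet × weight interaction, with
HF-Overweight (53.8, letter c) separated from everything and LF-Overweight
(ab) distinguishable from neither the top nor the middle group. The three
p-values per row are the diet main effect, the weight main effect and
their interaction.

From the shell, the same pipeline over a whole workbook:

```sh
anovatab plasma.xlsx --test tukey --out tables.rtf --plots plots.pdf
anovatab plasma.xlsx --format pooled --no-phc --out plain.rtf
```

writes one RTF table per sheet (open it in any word processor and edit
freely) and one interaction-plot page per response.

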
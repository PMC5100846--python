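# decaykit

Modeling what makes some mRNAs decay faster than others in budding yeast.

Genome-wide mRNA degradation rates in *Saccharomyces cerevisiae* vary by an
order of magnitude, and no single transcript property explains that
variation. `decaykit` implements a complete, testable pipeline for the
multiple-regression approach to this question: compute sequence-derived
predictors for every transcript, assemble them with genome-wide measurements
into a transformed predictor table, build a minimal linear model of the
degradation rate constant by stepwise selection, quantify the variance each
factor explains, and validate individual constructs with transcriptional-
shutoff qPCR decay fitting. A synthetic-data generator with known ground
truth stands in for the genome-wide datasets, so every stage can be tested
end to end.

## The model

The degradation rate constant k (min⁻¹; k = ln 2 / t½, with growth dilution
ln 2 / T_doubling subtracted where rates come from metabolic labeling) is
approximately normally distributed across transcripts and is modeled as

    k = β₀ + Σⱼ βⱼ xⱼ + ε,      ε ~ N(0, σ²)

where the xⱼ are transformed transcript properties: log₁₀ coding length,
log₁₀ abundance and ribosome density, GC content at each codon position
(GC1/GC2/GC3, untransformed proportions), log₁₀ codon adaptation index
(CAI), normalized translational efficiency (nTE), folding energy ΔG, and so
on. Before fitting, extreme rates outside the Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] are removed. Model building proceeds two ways
that should agree: backward elimination from all univariately significant
predictors (p < 0.05), and forward inclusion in order of ascending
univariate p with literal conflict-resolution rules; a greedy AIC reduction
is available as a cross-check. Adding binary indicators for functional (GO
SLIM) annotation and RNA-binding-protein targets gives the extended
"model++". Poly-proline transcripts (≥ 4 consecutive proline codons, which
stall elongation) are compared against the rest by Wilcoxon rank-sum.

For single constructs, decay after transcriptional shutoff is quantified by
ΔCt against a stable reference gene (Y = 2^(Ct_ref − Ct_gene), normalized to
t = 0), and k is the negated slope of ln Y on time, with case-resampling
bootstrap confidence intervals and pairwise construct comparisons through
the bootstrap distribution of Δk.

## Worked example

Generate a 4,000-gene synthetic dataset (linear model at target R² = 0.43
plus two planted categorical effects), fit it, and analyze the qPCR
time courses:

```sh
cat > config.yaml <<'YAML'
categories:
  - {label: stress_response, prevalence: 0.12, shift: 0.015}
rbp_categories:
  - {label: Puf3, prevalence: 0.05, shift: 0.02}
YAML
decaykit simulate --config config.yaml --seed 1 --n-genes 4000 --outdir sim
decaykit model sim/predictors.tsv --annotations sim/annotations.tsv --outdir model
decaykit qpcr sim/qpcr.csv --seed 7 --outdir qpcr
```

The model step prints

```
model: 6 terms, R^2 = 0.403; model++ R^2 = 0.419
```

and `model/variance_summary.tsv` decomposes the variance (sign = direction
of the univariate association; the generator's true effects are length +,
ribosome density −, CAI −, nTE −, GC3 −, ΔG +):

```
            term       kind  r_squared  signed_r_squared  p_value
   coding_length univariate     0.1627            0.1627   0.0000
ribosome_density univariate     0.0655           -0.0655   0.0000
             cai univariate     0.0567           -0.0567   0.0000
              dg univariate     0.0435            0.0435   0.0000
             nte univariate     0.0277           -0.0277   0.0000
             gc3 univariate     0.0264           -0.0264   0.0000
       abundance univariate     0.0000           -0.0000   0.9408
           model      model     0.4028            0.4028      NaN
         model++      model     0.4194            0.4194      NaN
```

Backward selection recovered exactly the six predictors with non-zero true
effects (dropping the null `abundance` column); no single predictor explains
more than ~16% of the variance, but together they explain 40%, and adding
the categorical indicators lifts this to 42% — the qualitative signature of
the genome-wide analysis. The qPCR step fits each construct's decay constant
with a bootstrap 95% CI (`qpcr/decay_fits.tsv`):

```
gene    k        half_life  ci_low   ci_high
GFP2    0.0309   22.4       0.0208   0.0385
GFP3    0.0301   23.0       0.0249   0.0347
GFP4    0.0121   57.3       0.0076   0.0157
```

(true constants 0.035, 0.025, 0.015 min⁻¹), and `decay_comparisons.tsv`
flags GFP4 as decaying significantly more slowly than the other two.

The same machinery is available as a library:

```python
from decaykit import GeneratorConfig, gen_predictor_table, iqr_filter, backward_stepwise

table, truth = gen_predictor_table(GeneratorConfig(seed=1, n_genes=4000))
table = table.subset(iqr_filter(table.response).kept)
model = backward_stepwise(table, alpha=0.05)
print(model.terms, round(model.r_squared, 3))
```

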
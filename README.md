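# prognet

Evidence synthesis and target-network analysis for prognostic biomarker
studies, built around a worked example: the association between miR-203
expression and overall survival in colorectal cancer.

When a candidate prognostic marker has been evaluated in several published
cohorts, each reporting a hazard ratio (HR) with a confidence interval, two
questions follow. First, what does the evidence say jointly — is high marker
expression associated with worse survival once all cohorts are pooled, and
how consistent are the studies? Second, what might the marker do — which of
its target genes sit at the centre of the protein–protein interaction (PPI)
network, which dense network modules do they form, and which annotated
pathways are over-represented among them? `prognet` implements both halves
as a tested, reusable library with a small command-line front end.

## The model

Published effects are pooled on the log scale. Each ``HR (lo–hi)`` row
becomes

```
y_i = ln HR_i,      se_i = (ln hi_i − ln lo_i) / (2 z),   z = Φ⁻¹(0.975)
```

The **fixed-effect** estimate weights studies by `w_i = 1/se_i²`. Between-
study heterogeneity is measured by Cochran's `Q = Σ w_i (y_i − ȳ)²` and
Higgins' `I² = max(0, (Q − df)/Q)`. The **random-effects** model assumes
study-level true effects `θ_i ~ N(μ, τ²)` with the DerSimonian–Laird
moment estimator

```
τ̂² = max(0, (Q − df) / C),   C = Σw_i − Σw_i²/Σw_i
```

and weights `w*_i = 1/(se_i² + τ̂²)`. The model is chosen by the
conventional gate: random effects when the Q-test rejects at 0.05, fixed
otherwise — applied level-wise in subgroup analyses. Around the pooled
estimate the package provides leave-one-out sensitivity analysis,
method-of-moments meta-regression, and Egger / Begg publication-bias tests
with funnel-plot export.

The network half screens hub genes as the intersection of the top-ranked
nodes under degree, betweenness and closeness centrality, detects dense
modules with an MCODE implementation (k-core-based vertex weighting, greedy
seeded expansion, 2-core post-processing), and tests gene-set
over-representation with the hypergeometric tail, reporting
Benjamini–Hochberg q-values alongside raw p-values.

## Worked example

Eleven cohorts (1452 patients, seven publications) relating high miR-203
expression to colorectal-cancer overall survival ship with the package:

```python
import prognet as pn

records = pn.bundled_table1()
result = pn.MetaAnalysis.from_records(records).fit()   # auto model choice
print(result.summary())
```

```
Meta-analysis of 11 studies (random-effect model)
----------------------------------------------------------
Pooled HR                1.55  (1.07-2.24, 95% CI)
z = 2.312, p = 0.0208
Heterogeneity: Q = 41.91 (df 10), p_Q = 7.79e-06, I2 = 76.1%, tau2 = 0.2955
----------------------------------------------------------
study                        HR          95% CI   weight
schetter_2008              3.10     (1.50-6.40)     8.2%
bovell_2013                1.90     (1.05-3.43)     9.2%
tao_2014                   1.38     (0.77-2.48)     9.2%
deng_2016_c1               0.62     (0.32-1.20)     8.7%
deng_2016_c2               0.36     (0.20-0.64)     9.3%
kingham_2017_c1            1.92     (1.17-3.14)     9.9%
kingham_2017_c2            1.98     (1.14-3.43)     9.5%
takano_2017                2.27     (1.28-4.01)     9.4%
hur_2017_tissue            1.56     (0.80-3.05)     8.6%
hur_2017_serum_a           2.14     (1.09-4.21)     8.6%
hur_2017_serum_b           2.35     (1.34-4.12)     9.4%
pooled (random)            1.55     (1.07-2.24)   100.0%
```

High miR-203 expression is associated with a 55% higher hazard of death
(HR 1.55, 95% CI 1.07–2.24, p ≈ 0.021), with substantial between-study
heterogeneity (I² = 76.1%) — hence the random-effects model. Stratifying
pinpoints the heterogeneity: the association is strong and homogeneous in
non-Asian cohorts (HR 2.08, fixed effect) and in large cohorts (HR 2.05),
weaker and heterogeneous in Asian, serum-based and small cohorts:

```python
table = pn.subgroup_analysis(records, "ethnicity")
print(table.to_frame().round(2))
```

The same pipeline is exposed as a CLI
(`prognet meta`, `bias`, `network`, `enrich`, `simulate`); the network and
enrichment stages take user-supplied STRING-style edge lists and GMT gene
sets, or synthetic inputs with planted ground truth from
`prognet.simulate`.

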
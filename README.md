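# oncohub

Integrative discovery of oncogenic hub-gene networks in
transcription-factor-driven cancers.

`oncohub` implements, as a tested and fully reproducible pipeline, a
systems-level gene discovery strategy of the kind used to find driver gene
sets in castration-resistant prostate cancer downstream of constitutively
active androgen-receptor splice variants (AR-V7). Three independent
evidence layers are computed and intersected:

1. **Co-expression modules across patient cohorts.** Multi-study expression
   matrices are outlier-filtered (samples whose mean inter-sample Pearson
   correlation falls more than 2.5 SD below average), combined over shared
   genes, and quantile normalized. A weighted network is built from
   pairwise correlations raised to a soft-threshold power β chosen by the
   scale-free topology criterion (fit R² ≥ 0.8); the topological overlap
   matrix ω_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) defines a
   dissimilarity that is clustered with average linkage. Branches of ≥ 30
   genes become modules, modules whose eigengenes (first principal
   components) have dissimilarity 1 − cor < 0.25 are merged, and each
   eigengene is correlated with ordered disease phenotypes
   (normal < benign < HGPIN < cancer < CRPC < metastasis).
2. **Regulation by the driver factor.** An inducible-knockdown experiment
   (target construct vs shGFP-style control, induced vs non-induced,
   replicated) is analyzed with per-gene Welch tests at unadjusted
   p < 0.05; genes that also respond in the control construct are
   subtracted, and the surviving genes are mapped onto the modules with
   hypergeometric enrichment.
3. **Functional interaction with the driver.** A yeast deletion-library
   growth screen (four replicates, inducing vs non-inducing conditions) is
   scored by area under the colony-growth curve; Welch tests at p < 0.05
   call suppressor (fitness ratio < 1) and enhancer (> 1) hits.
   Library-absent essential genes join the hit list when they contact ≥ 2
   primary hits in a protein network at confidence ≥ 0.7, and all hits are
   projected onto human orthologs (genes supported by both an essential and
   a non-essential yeast hit form the "mixed" class).

Genes present in a disease-associated module, down-regulated upon driver
knockdown (i.e. upregulated by the driver), and present in the functional
interactome form the **hub gene set**. The set is validated by z-score
survival stratification (a patient is "altered" when ≥ k of m hub genes
have expression z ≥ 1.96; Kaplan–Meier curves and a log-rank test compare
altered vs normal patients) and the therapeutic angle is quantified with
the median-effect/combination-index method: each drug is fit by
fa/(1−fa) = (D/Dm)^m and a dose pair (d1, d2) at combined effect fa has

    CI = d1/Dx1(fa) + d2/Dx2(fa),   Dx = Dm·(fa/(1−fa))^(1/m),

with CI < 1 synergy, CI = 1 additivity, CI > 1 antagonism.

Because the original patient cohorts and screens are external datasets, the
package ships a first-class synthetic-data generator that plants every
signal (modules with phenotype-linked activity, knockdown targets and
control artifacts, growth-rate interactions, network-wired essential genes,
an elevated hazard in altered patients, median-effect dose-response
surfaces under Loewe additivity or planted synergy) and records the ground
truth, so the entire pipeline is verifiable end to end at desk scale.

## Worked example

```python
import oncohub as oh

res = oh.run_all(oh.PipelineConfig(), seed=1)
truth = res.study.truth
print(res.partition.n_modules, res.disease_module_labels)
print(res.hub.genes, res.hub.as_set() == truth.hub_genes)
print(res.logrank)
```

On the default study (2,000 genes, 8 planted modules, 300 samples, seed 1)
this prints, via `python examples/06_full_pipeline.py`:

```
soft threshold beta: 2
modules after merging: 8 (planted 8)
disease modules (positive trait correlation, p < 0.01): [1, 4, 5]
regulated genes after control filter: 215
deletion-screen hits incl. essentials: 42

hub genes recovered: G0352, G0856, G1085, G1121, G1349, G1524, G1918
planted hub genes:   G0352, G0856, G1085, G1121, G1349, G1524, G1918
exact match: True

survival validation: log-rank chi-square = 47.97, p = 4.33e-12
synergy stage: CI = 1.000 on the Loewe-additive default surface
```

The eight planted modules are recovered exactly; the three modules whose
eigengenes rise with disease stage are flagged; the three-way intersection
returns precisely the seven planted hub genes; patients carrying the
upregulated hub signature show dramatically worse survival; and the
Loewe-additive dose-response surface calibrates the combination index to 1.

Each capability also has a narrative script under `examples/`
(modules/traits, perturbation mapping, deletion screen, survival
stratification, drug synergy, full pipeline), and a thin CLI mirrors the
stages:

```bash
oncohub simulate --outdir run1 --seed 1
oncohub synergy --dose-response run1/dose_response.csv --out run1/ci.tsv
oncohub run-all --outdir run1 --seed 1
```

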
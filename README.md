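# gemmomics

Multi-omic integration toolkit for genetically engineered mouse models
(GEMMs) of breast cancer. The package reimplements, as a tested and
reusable library, the analysis chain used to ask whether the
histological subtypes of an oncogene-driven mammary tumor model
(e.g. microacinar, squamous, and EMT-like tumors of a Myc-driven
model) carry conserved genomic events, whether those events drive
expression, and which human breast cancer intrinsic subtype each mouse
tumor most resembles.

## Who this is for

Computational cancer biologists integrating whole-genome sequencing
call sets with expression profiling of mouse tumor cohorts, and anyone
who needs the individual stages — consensus variant merging, ssGSEA,
signature refitting, ComBat-style batch adjustment, a PAM50-style
soft-voting classifier, Kaplan–Meier analysis — as plain Python
functions over pandas/numpy containers.

## The pipeline

1. **Consensus somatic variants** (`gemmomics.variants`). SNVs are the
   exact intersection of two callers on (chrom, pos, ref, alt), with
   strain-background (germline) calls subtracted. Structural variants
   merge when both breakpoints agree within 100 bp (1,000 bp for
   translocations); merged CNV/inversion calls are kept when length
   > 10 kb, MAPQ ≥ 60 (≥ 50 for translocations), and no wildtype call
   matches; translocations additionally require an orthogonal
   gene-break hit. Conserved mutations are genes with moderate/high
   impact calls in ≥ 66% of a subtype's tumors.
2. **Copy-number / expression integration** (`gemmomics.integration`).
   Per gene with a discrete copy change (|ΔCN| ≥ 1), Kendall's τ-b and
   Pearson's r between integer CN and expression; flags are inclusive
   at τ ≥ 0.3 and r ≥ 0.7. The *integrative gene set* crosses
   per-contrast differential expression (two-sided pooled-variance
   t-test, p < 0.05) with conserved CN events and maps survivors
   through a mouse→human homolog table. Ward clustering and
   2-component PCA summaries are included.
3. **Pathway enrichment** (`gemmomics.enrichment`). Single-sample GSEA:
   genes ranked by descending expression, in-set genes weighted by
   |rank statistic|^α (α = 0.75), out-of-set genes penalized
   1/(N − m); the score integrates the running sum. Volcano-rule
   comparison flags sets with |Δ| ≥ 0.4 and p ≤ 0.05.
4. **Mutational signatures** (`gemmomics.signatures`). 96-channel
   trinucleotide catalogs (pyrimidine-reference convention) and
   forward-selection exposure refitting with nonnegative,
   sum-to-at-most-one weights, a 0.06 retention cutoff, and SSE
   reporting.
5. **Cross-species subtype classifier** (`gemmomics.subtype`).
   Parametric empirical-Bayes batch adjustment (location/scale, normal
   and inverse-gamma priors), recursive feature elimination with
   stratified CV under an RBF-SVM (permutation importance), then a
   soft-voting ensemble of logistic regression, RBF-SVM, random
   forest, gradient-boosted trees, and an MLP over 15 stratified 70/30
   splits. Metrics: accuracy, support-weighted F1, and the multiclass
   Matthews correlation coefficient, all derivable from the confusion
   matrix. Mouse samples get the class with the highest probability
   averaged over every learner of every instantiation.
6. **Survival** (`gemmomics.survival`). Kaplan–Meier product-limit
   curves with Greenwood variance, log-log 95% bands,
   Brookmeyer–Crowley median CIs, and log-rank two-group comparison.
7. **Synthetic cohorts** (`gemmomics.synthdata`). Deterministic
   generators for every input above, each with a ground-truth sidecar,
   so the whole pipeline is testable without any download.

## Worked example

```python
from gemmomics import synthdata as sd, variants as va

cfg = sd.SynthConfig(seed=7, n_sv_events=60, sv_jitter_sd=20.0,
                     fp_rate=0.3, wt_frac=0.2)
res = sd.gen_sv_callsets(cfg, kind="CNV")
consensus = va.consensus_svs(res.caller_a, res.caller_b, res.wildtype)
print(len(res.caller_a), len(consensus))
```

Running `python examples/01_consensus_variants.py` prints:

```
caller A calls:        78
caller B calls:        78
true events:           60 (12 also in wildtype)
consensus calls:       48
recall vs somatic truth: 1.00
```

Each caller reports 78 calls (60 jittered true events plus 18 private
false positives). The consensus keeps exactly the 48 events that are
real *and* absent from the wildtype background: private false
positives never agree between callers, and the 12 wildtype-duplicated
events are subtracted. `examples/` contains one analogous script per
stage; `python examples/06_survival_analysis.py`, for instance,
estimates median overall survival of 83.9 vs 172.1 months for cohorts
generated at 87.7 / 163.5 (log-rank p ≈ 1e-15).

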
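# qmprofiler

Quantitative microbiome profiling (QMP) and method-concordance analysis for
16S rRNA gene amplicon data.

## The problem

Amplicon sequencing yields *compositional* data: read counts per sample sum
to an arbitrary sequencing depth, so only relative abundances survive.
When one taxon blooms, every other taxon's relative abundance must fall,
which confounds differential-abundance analysis.  Quantitative microbiome
profiling fixes this by anchoring the sequencing profile to an externally
measured microbial load — but the anchor can come from flow-cytometry cell
counts, from qPCR/ddPCR 16S copy quantification, or from cell counts after
propidium-monoazide (PMA) treatment that excludes extracellular DNA, and
these choices can produce very different absolute profiles.  This package
implements all four normalizations, the load quantification models behind
them, the statistics used to compare them, and a synthetic fecal-cohort
generator with fully known ground truth so every stage is testable without
any sequencing data.

It is written for microbiome methods researchers and bioinformaticians who
want to reason quantitatively about when and why load-anchored profiles
diverge.

## The core method

For a taxon-by-sample count matrix `C_st` with per-taxon 16S copy numbers
`k_t` and per-sample microbial loads `L_s` (cells/gram):

1. **Copy-number correction** — `C'_st = round(C_st / k_t)`, corrected
   depth `D_s = Σ_t C'_st`.
2. **Even sampling depth** — sampling depth `SD_s = D_s / L_s` (corrected
   reads per cell); every sample is rarefied (multivariate hypergeometric
   subsampling) to `n_s = floor(min_s SD_s × L_s)` reads, so all samples
   carry the same reads-per-cell resolution.
3. **Rescaling** — `abundance_st = rarefied_st / n_s × L_s`, giving
   cells/gram; each sample's profile sums exactly to its load.

Variants differ in where `L_s` comes from: **QMP** uses flow-cytometry cell
counts; **QMP-PMA** applies the same arithmetic to libraries built after
PMA treatment; **QMP-qPCR** derives `L_s = Q_s / A_s` from total 16S
copies/gram `Q_s` (standard-curve qPCR or Poisson ddPCR) and the sample's
average copy number per cell `A_s = R_s / D_s`.  **RMP** (relative
profiling) rarefies to an even read count and reports proportions.

Supporting models: qPCR standard curves (`Ct = slope·log10(copies) +
intercept`, efficiency `10^(−1/slope) − 1`), ddPCR Poisson quantification
(`λ = −ln(1 − positive fraction)`), paired untreated/PMA load differencing
for the extracellular DNA fraction, Bray–Curtis + PCoA concordance
statistics, per-genus Kendall τ-b rank concordance, and
Dirichlet-multinomial mixture (DMM) enterotyping with Laplace-approximated
model evidence.

## Worked example

```python
from qmprofiler import SimConfig, generate_truth, qmp_profile, qmp_qpcr_profile
from qmprofiler.simulate import (simulate_sequencing, simulate_cell_counts,
    simulate_paired_molecular_loads, subject_mean_loads, loads_for_samples,
    aliquot_loads)
from qmprofiler import stats as st, quantify as qt

cfg = SimConfig(n_subjects=16, n_replicates=2, seed=1)   # synthetic cohort
truth = generate_truth(cfg)
counts = simulate_sequencing(truth, "untreated", seed=2)
cells = simulate_cell_counts(truth, seed=3)
loads = loads_for_samples(subject_mean_loads(cells), counts.samples)

qmp = qmp_profile(counts, truth.copy_numbers, loads, seed=4)
print(qmp.abundances.iloc[:4, :3])
```

```
                   s01_r1   s01_r2   s02_r1
taxon
Bacteroides      1.75e+10 1.75e+10 1.29e+10
Prevotella       2.07e+08 2.26e+08  9.3e+07
Faecalibacterium 2.02e+09 2.05e+09 1.84e+09
Blautia          1.87e+09  1.9e+09  9.6e+08
```

Abundances are in cells per gram of feces; each column sums exactly to that
sample's measured load (here ~2.95×10^10 cells/g for subject s01).  The
paired untreated/PMA qPCR loads recover the extracellular DNA fraction the
cohort was generated with (39%):

```python
paired = simulate_paired_molecular_loads(truth, "qpcr", seed=5)
res = qt.estimate_extracellular_fraction(
    aliquot_loads(paired, "untreated"), aliquot_loads(paired, "pma"))
print(res.mean_fraction, res.p_value)   # 0.396, 8.3e-07
```

and the concordance layer shows the qPCR-anchored profiles diverging from
cell-count-anchored ones far beyond replicate variation — the consequence
of DNA-extraction yield varying between aliquots:

```python
qmp_q = qmp_qpcr_profile(counts, truth.copy_numbers,
                         aliquot_loads(paired, "untreated").reindex(counts.samples),
                         seed=6)
report = st.replicate_dissimilarity_analysis({"QMP": qmp, "QMP-qPCR": qmp_q})
print(report.summary["median"])
```

```
within:QMP              0.011
within:QMP-qPCR         0.274
between:QMP|QMP-qPCR    0.243
```

A replicate of the same sample profiled twice by QMP differs by a
Bray–Curtis dissimilarity of ~0.01, while the same aliquot profiled by QMP
vs QMP-qPCR differs by ~0.24.

A `qmprofiler` command-line tool wraps the same stages
(`simulate`, `profile`, `compare`, `enterotype`, `mockeval`, `run`); see
`qmprofiler --help`.

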
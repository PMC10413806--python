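# burstkit

Transcriptional-bursting analysis for single-cell UMI count data: binomial
capture-noise modelling, Poisson-Beta maximum-likelihood inference of
two-state promoter kinetics, and statistics that place bursting in its 3D
genome context (TADs, TAD boundaries, A/B compartments), together with a
synthetic-data generator that makes every stage verifiable by parameter
recovery and planted-effect detection.

## Who it is for

Groups analysing plate-based scRNA-seq of homogeneous cell populations
(ideally haploid or allele-resolved) who want per-gene burst kinetics and
group-level contrasts such as "is burst frequency more similar for genes
sharing a TAD than for random genes?" — without needing any particular
sequencing dataset to validate the machinery: the bundled simulator plants
known effects and the test suite checks they are recovered.

## The model

A promoter switches between OFF and ON at rates K_on (OFF→ON) and K_off
(ON→OFF); mRNA is made at rate K_syn while ON and degrades at rate d ≡ 1
(all rates per mRNA lifetime). At steady state the copy number follows the
Poisson-Beta law

    P(X = x) = ∫₀¹ Pois(x; K_syn·b) Beta(b; K_on, K_off) db,

and measurement applies binomial capture X_obs ~ B(n, p) with single-molecule
efficiency p (0.35 by default), whose technical-noise floor is
CV = sqrt((1−p)/np). Per gene, `burstkit` maximises the Poisson-Beta
likelihood (Gauss-Jacobi quadrature, log-space L-BFGS-B, moment
initialisation), flags unidentifiable and ill-fitting genes, and reports
burst frequency (K_on) and burst size (K_syn/K_off, with the alternative
K_syn/K_on alongside). Group analyses compare coefficients of variation of
burst frequency across TADs, boundaries (5% flanks of adjacent TADs) and
random gene groups via Wilcoxon rank-sum tests and 10,000-fold bootstraps of
the median CV, and compare Spearman co-expression of gene pairs by genomic
context via two-sample KS tests. See `docs/methods.md` for the full account.

## Worked example

```python
import burstkit as bk

# a TAD-structured genome with a planted within-TAD burst-frequency effect
genome = bk.simulate_genome(n_tads=10, genes_per_tad=10,
                            boundary_genes_per_boundary=5, seed=1)
cfg = bk.DatasetConfig.well_expressed(share_tad_kon=True, kon_jitter_sigma=0.1)
matrix, truth = bk.simulate_dataset(genome, cfg, n_cells=150, seed=1)

fits = bk.filter_fits(bk.fit_matrix(matrix), matrix)
from burstkit.burst_inference import fits_to_frame
table = fits_to_frame(fits)
print(table[table.kept][["gene_id", "k_on", "k_off", "k_syn"]].head(3))

ana = bk.tad_cv_analysis(genome[1], genome[0], table, n_boot=2000, seed=1)
import numpy as np
for cls, cvs in ana.cvs.items():
    print(f"{cls:16s} median CV {np.median(cvs):.3f} ({len(cvs)} groups)")
print("tad vs random p =", ana.bootstrap.wilcoxon_raw[("tad", "random_tad")])
```

Output (seed 1):

```
  gene_id      k_on     k_off      k_syn
0  g_t0_0  0.232062  1.129609  14.694526
2  g_t0_2  0.216579  1.084193  19.040887
4  g_t0_4  0.189319  0.723296   5.455339
tad              median CV 0.293 (5 groups)
random_tad       median CV 0.721 (5 groups)
boundary         median CV 0.639 (6 groups)
random_boundary  median CV 0.588 (6 groups)
tad vs random p = 0.007936507936507936
```

The three genes shown share TAD 0, and their estimated burst frequencies
cluster accordingly (k_on ≈ 0.19–0.23 per mRNA lifetime). Within-TAD groups
show a much smaller burst-frequency CV (~0.29) than size-matched random
groups (~0.72), recovering the planted sharing of K_on (true jitter CV 0.1;
the residual reflects estimation noise); the Wilcoxon rank-sum comparison
flags the difference even at this small genome (p ≈ 0.008 with 5 eligible
TADs; the full verification battery uses 50 TADs and reaches p ~ 1e-10). Equivalent stages are
available from the shell:

```sh
burstkit simulate --seed 1 --out run/simulate
burstkit fit-burst --counts run/simulate/counts.tsv --out run/fit
burstkit tad-analysis --fits run/fit/burst_fits.tsv \
    --genes run/simulate/genes.bed --tads run/simulate/tads.bed \
    --seed 1 --out run/tad
burstkit all --config configs/null_small.json --seed 1 --out run/all
```

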
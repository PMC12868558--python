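# hetconn

Heterogeneity-aware multiscale analysis of functional connectomes.

Case–control studies of neurodevelopmental disorders (autism, ADHD,
schizophrenia) are plagued by individual heterogeneity: group means blur
over idiosyncratic signal, and the shared disease signature is hard to
separate from subject-specific variability. `hetconn` implements a pipeline
that treats heterogeneity as structured variance to be factored out rather
than noise to be averaged away:

1. **Meta-BOLD extraction (heterogeneous matrix factorization).** Each
   subject's standardized region × time BOLD matrix is modelled as

   $$M_i = U_g V_{gi}^{\top} + U_{li} V_{li}^{\top} + E_i,
     \qquad U_g^{\top} U_{li} = 0,$$

   where $U_g$ spans the group-shared ("meta-BOLD") subspace and
   $U_{li}$ the subject-specific one. The factors minimize
   $\tfrac12\sum_i \lVert M_i - U_g V_{gi}^{\top} - U_{li} V_{li}^{\top}
   \rVert_F^2$ by alternating least squares in which every step is an exact
   constrained minimizer, so the loss is provably non-increasing and the
   orthogonality constraint holds to machine precision.
2. **Connectivity and the shared transdiagnostic pattern.** Pearson FC of
   the meta-BOLD reconstructions, Fisher z, edgewise standardization, and
   covariate regression produce a subjects × edges cohort matrix. The
   first PLS component against pooled patient/control labels — in closed
   form, $w \propto X^{\top}y$ — is the shared transdiagnostic abnormal
   connectivity pattern (STACP).
3. **Disorder-specific deviations.** Patients are projected onto $w$; the
   per-disorder means of the residuals $r_i = x_i - (x_i \cdot w)\,w$ are
   disorder-specific connectivity deviations (DSCDs), compared by cosine
   similarity.
4. **Molecular annotation.** Edge patterns are related to region × gene
   expression (correlated gene expression with exponential distance-decay
   correction $r(d) = A e^{-d/n} + B$ and an exact per-gene decomposition
   of each pair's correlation) and to low-dimensional neurotransmitter /
   mitochondrial maps (Ledoit–Wolf shrinkage covariance
   $\hat\Sigma = (1-\alpha)S + \alpha\,\mathrm{tr}(S)/p\, I$, precision
   matrices, and leave-one-feature-out perturbation scores
   $S_{ij,f} = P^{\mathrm{full}}_{ij} - P^{-f}_{ij}$), via PLS regression
   with spatially constrained permutation and bootstrap inference.
5. **Validation.** Bootstrap direction stability, stratified 5-fold
   cross-validated discrimination, label-permutation testing, split-half
   reliability.

Every input the pipeline consumes can be generated synthetically
(`hetconn.synth`) with the statistical structure the analyses assume, so
the full pipeline runs and is testable with no data download.

## Worked example

```python
import hetconn as hc

results = hc.run_pipeline()          # synthetic demo, ~2 s
print(results["stacp"].summary())
```

```
Edge-space PLS (first component)
========================================
patients / controls:  180 / 60
edges:                45
explained covariance: 0.2202
|w|:                  1.000000
DSCD cosine similarities:
  ASD vs ADHD: -0.865
  ASD vs SCZ: -0.352
  ADHD vs SCZ: -0.166
```

The demo cohort plants a deviation geometry in which the first two
disorders' deviation directions have cosine −0.9 (and the third closes the
sum-to-zero constraint that mean residuals of a centered cohort must
satisfy). The fitted DSCD cosine of −0.865 recovers it up to the analytic
shrinkage caused by averaging noisy residuals; the remaining cosines match
the closed geometry (−0.224 planted, estimated −0.35/−0.17 at this sample
size). The same bundle carries the factorization diagnostics, decay fits
and a validation report:

```python
print(results["validation"].summary())
```

```
Validation report
========================================
bootstrap cosine:  0.799 +/- 0.052 (n=100)
CV AUC:            0.671 +/- 0.070
CV accuracy:       0.733 +/- 0.040
permutation p:     0.05941
split-half r:      0.977 (min 0.960)
```

A command-line interface mirrors the library
(`hetconn simulate | hmf-fit | fc | atlas-merge | stacp | dscd | edges |
annotate-genes | annotate-features | validate | run`).

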
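# plsperm

Partial least squares (PLS) correlation with the full family of
permutation-based significance tests — unrotated and orthogonal-Procrustes
rotated (behaviour / brain / both) — plus split-half stability, bootstrap
feature-weight reliability, and a synthetic-data generator with a
controllable latent effect.

The package is aimed at researchers who relate a high-dimensional "brain"
block to a "behaviour" block (neuroimaging, multi-omics, any two-block
design) and who need to know not just *whether* a latent variable passes a
permutation test, but how the choice of rotation changes that answer, and
what strength and stability say that significance does not.

## The model

Given matched data blocks `X` (n × p) and `Y` (n × q) with z-scored
columns, the PLS correlation is the SVD of the Pearson cross-correlation
matrix

```
C = Xᵀ Y / (n − 1) = U Σ Vᵀ
```

A latent variable (LV) is a matched column pair of `U` (brain weights) and
`V` (behaviour weights) with its singular value σᵢ; σᵢ² / Σⱼ σⱼ² is the
LV's fraction of cross-block covariance explained. There are k = min(p, q)
LVs, ranked by singular value.

Significance is assessed by permutation: the rows of one block are
shuffled, the decomposition repeated, and the permuted LV strengths build a
per-LV null distribution. Four scoring rules are provided:

* **none** — permuted singular values enter the nulls directly;
* **behaviour** — the orthogonal Procrustes rotation `R = N Pᵀ` (from the
  SVD `V(p)ᵀ V = N O Pᵀ`) re-aligns the permuted behaviour component, and
  the column norms of `V(p) Σ(p) R` enter the nulls;
* **brain** — same, aligning `U(p)` to `U`;
* **both** — both rotated value vectors, averaged.

All four methods consume one shared table of shuffle indices, so p-value
differences are attributable to the rotation alone. Two exact algebraic
facts drive the package's headline behaviour: the rotation conserves total
squared covariance (`Σᵢ valᵢ² = Σᵢ σ(p)ᵢ²`) but can never push any value
above the permuted LV1 strength (`valᵢ ≤ σ(p)₁`). Rotation therefore only
weakens the LV1 null distribution — rotated tests systematically favour
passing LV1, even in pure noise — which is why the complementary strength
and split-half stability diagnostics matter.

## Worked example

```python
from plsperm import PLSCorrelation, SimulationSpec, generate_dataset

# one latent effect of canonical correlation 0.5, 500 observations, 90 x 10
data = generate_dataset(SimulationSpec(n=500, p=90, q=10, r=0.5, seed=42))
res = PLSCorrelation(data).fit()
nulls = res.permutation_tests(n_perm=2000, seed=0)
print(res.summary(nulls))
stab = res.split_half_stability(n_splits=50, seed=1)
print(stab.summary().head(3).to_string(index=False))
```

```
 lv  singular_value  covariance_explained  p_none  p_behaviour  p_brain  p_both
  1          0.7685                0.2772  0.0000       0.0000   0.0000  0.0000
  2          0.5476                0.1407  0.0220       0.0000   0.0000  0.0000
  3          0.4892                0.1123  0.2650       0.0380   0.0320  0.0065
  4          0.4390                0.0905  0.7785       0.3885   0.3225  0.3105
 ...
 lv  stability_x_mean  stability_x_sd  stability_y_mean  stability_y_sd
  1          0.391156        0.073211          0.765922        0.097031
  2          0.091712        0.065482          0.302858        0.202309
  3          0.074777        0.063856          0.291074        0.203984
```

Only one effect was simulated, and the metrics tell a layered story: LV1 is
significant under every method, strong (28% of covariance) and stable
(mean split-half |r| of 0.77 on the behaviour side). But the rotated tests
also pass LV2 and LV3 (p = 0.038, 0.032, 0.0065 for LV3) even though no
second effect exists, while LV2+ strength and stability collapse toward
the noise floor — the pattern a cautious analyst should look for.

The same workflow is available from the shell:

```bash
plsperm simulate --regime latent --n 500 --r 0.5 --seed 42 --out sim
plsperm permtest --x sim_X.csv --y sim_Y.csv --method all --n-perm 2000 --seed 0 --out perm.csv
plsperm stability --x sim_X.csv --y sim_Y.csv --n-splits 50 --seed 1 --out stab.csv
plsperm sweep --analysis random --profile desk --seed 0 --out sweep_out/
```

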
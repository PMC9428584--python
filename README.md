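# commtype

Community typing and clinical association screening for gut microbiome
cohorts.

Large metagenomic cohort studies often summarize each participant's gut
microbiome as membership in a small number of discrete community types —
the classic three "enterotypes" (Bacteroides-, Prevotella-, and
Firmicutes-dominated) or finer clusterings that further separate the
extremes of the Bacteroides–Prevotella gradient. Whether such clusters
carry clinical signal is an empirical question that needs a full chain of
statistics: mixture-model clustering, a defensible choice of the number of
clusters, phenotype association tests with multiple-testing control,
covariate and drug-usage adjustment, and time-to-event screening of
incident disease. `commtype` implements that chain as a tested, reusable
library plus CLI, together with a synthetic cohort generator so every stage
can be validated against known ground truth — useful when the real cohort
data sit behind restricted access.

## The model

Genus-level counts $x_i$ for sample $i$ (depth $n_i$) follow a
$K$-component **Dirichlet-multinomial mixture** (DMM):

$$
z_i \sim \mathrm{Cat}(\pi), \quad
p_i \sim \mathrm{Dirichlet}(\alpha_{z_i}), \quad
x_i \sim \mathrm{Multinomial}(n_i, p_i).
$$

Fitting is by EM with a quasi-Newton M-step in $\log\alpha$; the number of
clusters is scored by a **Laplace approximation of the model evidence**
and selected by an elbow rule (smallest $K$ after which the evidence gain
becomes negligible). Downstream, each phenotype factor is tested against
three representations of the same structure — a fixed 3-cluster enterotype
model (ET), the selected community-type model (CT), and the continuous
log Prevotella/Bacteroides **gradient** — using logistic/linear likelihood-
ratio tests or chi-squared tests with Benjamini–Hochberg FDR, an AIC
comparison of the three representations, a post-hoc drug-confounding scan,
and Cox proportional-hazards screening of incident diseases. Details and
all numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

Generate a 1,000-sample synthetic cohort with known structure and run the
whole analysis:

```bash
commtype simulate --seed 0 --n-samples 1000 --n-genera 50 --out demo/
cat > config.yaml <<EOF
counts_path: demo/counts.tsv
phenotypes_path: demo/phenotypes.tsv
prevalent_path: demo/prevalent.tsv
drugs_path: demo/drugs.tsv
incident_path: demo/incident.tsv
output_dir: run/
k_max: 4
seed: 0
EOF
commtype run-all config.yaml
```

Or from Python:

```python
import numpy as np
from commtype import fit_dmm, fit_curve, select_k, make_demo
from sklearn.metrics import adjusted_rand_score

counts, pheno, prevalent, drugs, incident, truth = make_demo(seed=0)
curve = fit_curve(counts, k_max=4, seed=0, n_starts=2)
print("Laplace scores:", [round(s) for s in curve.scores])
print("selected K:", select_k(curve))
fit = curve.fits[select_k(curve)]
labels = fit.responsibilities.argmax(axis=1) + 1
print("ARI vs truth:", round(adjusted_rand_score(truth.true_labels, labels), 3))
print("mixing weights:", np.round(fit.pi, 3))
```

prints

```
Laplace scores: [171271, 167255, 162545, 162607]
selected K: 3
ARI vs truth: 1.0
mixing weights: [0.256 0.422 0.322]
```

The evidence curve bottoms out at the generative $K = 3$; the recovered
partition agrees with the ground-truth labels perfectly, and the mixing
weights are close to the generator's 0.45/0.25/0.30 up to label order
(the residual gap is sampling noise in which component each sample drew).
`run-all` additionally writes, under `run/`: cluster assignments and the
ET–CT correspondence table, driving genera, diversity and PCoA
coordinates, the per-factor association table with q-values, the AIC
comparison of ET/CT/gradient per factor, the drug-confounding report, the
incident-disease Cox screen, and a JSON manifest with every threshold and
seed.

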
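# Methods

## The model

`commtype` clusters gut-microbiome samples with a Dirichlet-multinomial
mixture (DMM). Each sample's genus count vector $x_i \in \mathbb{N}^G$ with
depth $n_i = \sum_j x_{ij}$ is assumed to arise from one of $K$ latent
community types: a component label $z_i \sim \mathrm{Categorical}(\pi)$, a
composition $p_i \sim \mathrm{Dirichlet}(\alpha_{z_i})$, and counts
$x_i \sim \mathrm{Multinomial}(n_i, p_i)$. Marginalizing $p_i$ gives the
Dirichlet-multinomial component density

$$
\mathrm{DM}(x \mid \alpha)
= \frac{n!}{\prod_j x_j!}
  \frac{\Gamma(A)}{\Gamma(n + A)}
  \prod_j \frac{\Gamma(x_j + \alpha_j)}{\Gamma(\alpha_j)},
\qquad A = \sum_j \alpha_j ,
$$

which captures the overdispersion of real taxonomic profiles that a plain
multinomial misses. All density evaluations go through `gammaln`; no
factorials are ever formed.

### Fitting

`fit_dmm` runs EM. The E-step computes responsibilities
$r_{ik} \propto \pi_k\,\mathrm{DM}(x_i \mid \alpha_k)$ in log space; the
M-step updates $\pi$ in closed form and maximizes each component's
responsibility-weighted DM log-likelihood over $\lambda_k = \log \alpha_k$
with L-BFGS and the analytic digamma gradient. A *partial* M-step (15
L-BFGS iterations) is sufficient for a generalized-EM ascent guarantee; the
penalised (MAP) objective is recorded per iteration and asserted
non-decreasing in the tests. The raw log-likelihood can dip by a few
hundredths of a nat when the shrinkage prior trades likelihood for prior
mass; that is expected behaviour of MAP-EM, not a defect.

Initialisation uses seeded k-means on the proportion vectors for the first
start and random Dirichlet responsibilities for the remaining starts
(default `n_starts=5` at the API, 2 in the pipeline where the curve over K
dominates the cost). Runs whose smallest mixing weight falls below
$1/(10N)$ are treated as degenerate and restarted. After convergence
(relative change of the penalised objective below `tol`, default `1e-6`) a
polishing phase alternates full M-steps and E-steps until the objective is
tight, so independent starts land on numerically identical optima.

A weak Gamma(shape 1, rate 0.1) shrinkage prior acts on each $\alpha_{kj}$
(in log space, including the Jacobian). Its mode at $\alpha = 10$ matches
the scale of genus-level concentrations; it regularises near-empty
components and makes the evidence computation proper.

### Choosing K: Laplace evidence

`laplace_evidence` reports the negative log marginal likelihood

$$
-\log p(D) \approx -\Big[\log p(D \mid \hat\theta) + \log p(\hat\theta)
  + \tfrac{d}{2}\log 2\pi - \tfrac12 \log \det H\Big],
$$

where $d = KG$ counts the free log-concentration parameters and $H$ is the
Hessian of the negative log posterior at the fitted mode in
$\lambda$-space. The Hessian is assembled analytically per component from
trigamma terms, weighted by responsibilities — a block-diagonal
approximation that ignores cross-component curvature, as is standard for
DMM evidence scoring. Eigenvalues below $10^{-8}$ are clipped before the
log-determinant and the fit is flagged. On a tiny instance ($N=30$, $G=4$,
$K=1$, where the approximation carries no block-diagonal error) the score
agrees with brute-force grid integration of the marginal likelihood to
within 0.1 nat; the acceptance suite re-verifies this.

`select_k` implements the "no further significant improvement" reading of
the fit curve: the smallest $k$ whose gain $s(k)-s(k+1)$ drops below
$\tau \cdot [s(1)-s(2)]$, default $\tau = 0.05$. A global-minimum rule is
provided for sensitivity analysis. The choice of $\tau$ is ours — the
informal elbow criterion admits no unique formalisation — and it is
configurable; on well-separated three-component synthetic data the rule
recovers $K=3$ in at least 16 of 20 seeds with `k_max=5`.

### Representations

Three representations of community structure feed the downstream
statistics:

* **ET** — the fixed 3-cluster enterotype model (Bacteroides-, Prevotella-,
  and Firmicutes-dominated);
* **CT** — the elbow-selected model (5 clusters in the motivating cohort,
  separating extreme Bacteroides/Prevotella dominance);
* **gradient** — the continuous per-sample score
  $g_i = \ln\big[(P_i + c)/(B_i + c)\big]$ on Prevotella and Bacteroides
  counts with pseudocount $c = 0.5$ (configurable; natural log throughout).

Driving genera are ranked per cluster by the deviation of the expected
within-cluster proportion $\alpha_{kj}/A_k$ from the across-cluster mean.
Diversity descriptors are observed richness and Shannon entropy (natural
log); ordination is classical PCoA on Bray-Curtis dissimilarities of
per-sample proportions, with negative eigenvalues reported uncorrected.

## Preprocessing

Samples below a configurable read-count threshold are dropped (an
`n_lowest` variant removes a fixed number of worst libraries when no cutoff
is published). The taxon filter keeps a taxon when it reaches relative
abundance ≥ 0.001 (inclusive) in strictly more than 10% of samples; both
thresholds are configurable because the inclusivity convention is a
genuine judgment call. Species-to-genus aggregation sums counts within the
genus rank of the lineage string and pools genus-less species into an
`unclassified` column so per-sample depths are conserved exactly — the
multinomial depth is part of the model, so dropping reads silently would
bias the fit.

EHR factors become binary indicators: diseases (3-digit ICD-10) need at
least 20 cases; drug codes are rolled up the ATC hierarchy (level 5 → 4 →
3) until a level reaches 20 cases, else dropped, with the roll-up recorded.

## Association testing

Factors are regressed **on** the representation (phenotype as outcome,
cluster as categorical predictor with the largest cluster as reference):
logistic regression for binary factors, OLS for continuous and ordinal
ones, each tested by a likelihood-ratio test of the representation term
($\chi^2$, $K-1$ df for clusters, 1 for the gradient). Categorical factors
use Pearson's chi-squared against the cluster composition and accept no
covariates. Complete cases per test; missingness is never imputed.
Benjamini–Hochberg FDR is applied within each representation's family
(separate families match the per-model significance counting), implemented
as the exact step-up rule with NaN p-values excluded from the family size.

Adjusted disease models add age, gender, BMI, and Bristol stool score
(entered numerically) before the cluster LRT. The drug-confounding scan
then asks, per drug: does the cluster still improve a model already
containing covariates and that drug? If the cluster term's LRT p exceeds
0.05 (configurable) for at least one drug, the association is reported as
confounded and the drugs listed. Note the intrinsic ceiling: under full
mediation the cluster-given-drug p-value is uniform, so the detection rate
of a truly mediated association is at most $1 - \alpha = 95\%$.

Representation comparison fits the same model family three times, varying
only the representation term, and reports AICs ($2p - 2\ell$); the minimum
wins. The CT model's four extra parameters are penalised, so under a null
factor it rarely wins; under a cluster-specific effect invisible to ET and
non-monotone in the gradient it wins in ≥ 80% of replicates, and likewise
for a generative gradient effect.

## Survival screening

Incident diseases are screened with Cox proportional-hazards models
(lifelines, Efron tie handling) after excluding subjects with a prevalent
record of the same 3-digit code. Cluster labels enter as indicator
contrasts against the largest cluster; the headline p-value is the global
LRT of the cluster term against the covariate-only model. The PH
assumption is checked by correlating scaled Schoenfeld residuals with
Kaplan–Meier-transformed time; the reported global statistic sums the
per-term chi-squared contributions (exact per term, approximate jointly —
adequate for screening, and flagged as an approximation here). BH-FDR runs
across the disease panel within each representation. Time origin is sample
collection; staggered entry, competing risks, and time-varying covariates
are out of scope.

## The synthetic cohort generator

Because the motivating cohort is access-restricted, every stage is
exercised on generated data with known truth:

* **Counts** — exactly the DMM generative process above. Default presets:
  a well-separated 3-component preset (Bacteroides-heavy,
  Prevotella-heavy, Firmicutes-spread, mixing 0.45/0.25/0.30) and a
  5-component preset adding extreme-Bacteroides and extreme-Prevotella
  components along the gradient. Depth is LogNormal(log 5·10³, 0.3),
  rounded, floored at 1 — a scale typical of genus-level tables and fast
  to simulate; the preset concentrations are design defaults, not claims
  about any real cohort.
* **Phenotypes** — covariates age ~ N(50, 10) truncated to [23, 89] (the
  plausible adult-cohort range), gender ~ Bernoulli(0.7 female),
  BMI ~ N(26, 4), Bristol score binned from a latent normal. Factors
  follow logistic/Gaussian/softmax/binned-latent models whose linear
  predictor contains a cluster term, a gradient term, or neither.
* **Drugs** — either an indication pathway (use depends on realized
  disease) or a mediation pathway (use depends on cluster, disease on
  drug), the latter creating a fully drug-carried cluster–disease
  association for the deconfounding scan to find.
* **Incident disease** — Weibull proportional hazards with per-cluster log
  hazard ratios and covariate terms; administrative censoring at 3.1 years
  with ±50% uniform jitter emulates staggered entry with a ~3-year median
  follow-up.

All generators are pure functions of (spec, seed). What passing tests on
this generator do **not** show: robustness to compositional artefacts not
captured by the DM family (e.g. zero inflation beyond DM expectation),
taxonomic misassignment, real correlation structure among phenotype
factors, or informative censoring — the generator draws all of these from
the model the analysis assumes.

## Numerical choices and problem sizes

* EM: `tol=1e-6` relative on the penalised objective, `max_iter=1000`,
  component-weight floor $1/(10N)$, L-BFGS bounds $|\lambda| \le 30$.
* Evidence: eigenvalue clip $10^{-8}$, flagged when active.
* Chi-squared tables with expected cells < 1 are flagged; optional pooling
  of rare subdiagnosis codes into "other".
* Ties in driving-genera rankings break alphabetically; cluster-label ties
  in assignment break to the lowest component index.
* Verification problem sizes (tests and `scripts/acceptance.py`): recovery
  and K-selection at N=600, G=40, depth ≈ 5·10³; calibration at 1,000 null
  replicates; Cox coverage at 500 replicates of N=2,000; demo pipeline at
  N=1,000, G=50, `k_max=4`. These sizes put every asymptotic test well
  inside its regime while keeping the whole suite re-runnable in minutes.

## Known limitations

* The Laplace Hessian ignores cross-component curvature; evidence values
  for strongly overlapping components are approximate (the selection rule
  only consumes differences, which are far larger than this error on
  separated data).
* The global PH statistic is a sum of per-term statistics, not the joint
  score test.
* Ordinal factors are treated as continuous by default; no ordinal
  logistic regression.
* The gradient score uses exact genus-name matching (`Prevotella`,
  `Bacteroides`); messy taxonomies need the configurable name arguments.
* No BIOM import, rarefaction, UniFrac, mixed models, or competing risks.
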
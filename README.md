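# lcdr — latent class distributional regression

Reference intervals — the central range (e.g. the 2.5%–97.5% quantiles) of
an analyte in a healthy population — are usually estimated *indirectly*
nowadays: from routine laboratory databases that mix an unknown majority of
healthy samples with pathological ones. Splitting such data into age groups
and estimating each group separately produces discontinuous limits and
wastes information. `lcdr` instead fits a **finite mixture of
distributional regression models** to the contaminated data, extracts the
"healthy" component, and reads continuous, covariate-dependent reference
limits off its conditional quantiles.

## Model

Each observation has response \(y^{(i)}\) and covariates \(x^{(i)}\). The
mixture density is

\[ f(y^{(i)} \mid x^{(i)}) = \sum_{m=1}^{M} \alpha_m\,
   f_m\bigl(y^{(i)} \mid \mu_m(x^{(i)}), \sigma_m(x^{(i)})\bigr),
   \qquad \alpha_m > 0,\ \textstyle\sum_m \alpha_m = 1, \]

where every component is a two-parameter distributional regression
(Gaussian or gamma): both parameters get their own additive predictor
through a link function,

\[ g_k(\theta_k^{(i)}) = \beta_{0k} + \sum_j h_{jk}(x^{(i)}_{j}), \]

with the non-linear terms \(h\) built from cubic B-splines (default: three
basis columns, i.e. the cubic-polynomial span). Estimation is an EM
algorithm: the E-step computes per-observation membership weights
\(w^{(i)}_m \propto \alpha_m f_m(y^{(i)})\), the M-step refits each
component by weighted maximum likelihood and sets
\(\alpha_m = \tfrac1n \sum_i w^{(i)}_m\); the mixture log-likelihood
increases monotonically and iteration stops when it changes by less than
ε = 0.001. Because random initial memberships often strand the flexible
components in poor local maxima, the default initialization derives the
starting weights from the CDF of a *naive* single-component fit to all the
data, directing the second component at the upper tail (or lower /
two-sided, where the pathology sits below or on both sides).

The component quantile \(Q_{m,q}(x) = F_m^{-1}(q \mid \mu_m(x),
\sigma_m(x))\) of the extracted healthy component is the reference limit.

## Worked example

Simulate a contaminated dataset (70% healthy component, spacing c = 20),
fit a two-component Gaussian mixture with spline location and scale, and
compare the healthy component's estimated 95% quantile curve against the
known truth:

```python
import numpy as np
import lcdr

scen = lcdr.Scenario(c=20, alpha1=0.7, n=1000, seed=4)
data = lcdr.simulate_dataset(scen)          # columns x, y, label

spec = lcdr.scenario_model_spec()           # B-spline df=3 for mu and log-sigma
mix = lcdr.fit_lcdr(data, lcdr.MixtureSpec(components=(spec, spec)))
print(f"status={mix.status}  iterations={mix.n_iter}  "
      f"alpha={np.round(mix.alpha, 3).tolist()}  loglik={mix.loglik:.1f}")

grid = np.linspace(0, 1, 201)
q_hat = lcdr.component_quantile_curve(mix, 0, 0.95, "x", grid)
q_true = lcdr.true_quantile(scen, 0.95, grid)
naive = lcdr.fit_quantile_curve(mix.naive_fit, 0.95, "x", grid)
for name, vals in [("LCDR", q_hat.values), ("NAIVE", naive.values)]:
    ie = lcdr.integrated_error(vals, q_true, grid)
    ise = lcdr.integrated_squared_error(vals, q_true, grid)
    print(f"{name:5s}  IE={ie:+.3f}  ISE={ise:.3f}")
```

Output:

```
status=converged  iterations=94  alpha=[0.668, 0.332]  loglik=-4230.6
LCDR   IE=+0.002  ISE=1.331
NAIVE  IE=+21.045  ISE=457.207
```

The mixture recovers the healthy proportion (0.668 vs the true 0.7) and
its 95%-quantile curve is essentially unbiased (integrated error ≈ 0,
integrated squared error 1.3), while the naive single-component fit —
which treats all data as healthy — overestimates the limit by about 21
units on average, with an ISE three hundred times larger.

The same pipeline is available from the shell:

```bash
lcdr simulate --c 20 --alpha1 0.7 --n 1000 --seed 4 --out data.csv
lcdr fit --data data.csv --config model.json --out fit.json
lcdr quantiles --fit fit.json --levels 0.025,0.975 --grid 201 --out curves.csv
lcdr experiment --grid grid.json --reps 200 --seed 1 --out results.csv
lcdr fixture --n-per-sex 2000 --seed 0 --out hemoglobin.csv   # synthetic
```

`model.json` declares the component formulas (family, spline/linear/
categorical terms per parameter); see `lcdr.io.model_spec_to_dict` for the
schema. The `fixture` command writes a *synthetic* hemoglobin-like
pediatric dataset (age, sex, value, true label) for end-to-end exercises
with contamination below the healthy component.

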
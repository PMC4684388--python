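# allocarbon

Compatible additive allometric modelling of tree component biomass and
carbon stocks, for forest biometricians who need tree-level carbon
estimates that add up.

Estimating forest carbon from destructively sampled trees involves two
linked questions: how to fit component biomass/carbon equations whose
predictions are mutually consistent (stem + branch + foliage + root =
total, exactly), and whether carbon should be predicted *directly* from a
fitted carbon model or *indirectly* by converting predicted biomass with a
carbon-concentration factor. This package implements both halves for
single-predictor power-law allometries of the Korean pine plantation type,
and quantifies the error each conversion strategy adds.

## The model

Each mass pool follows `Y = a X^b` with `X = D` (diameter at breast
height, cm) or `X = D²H`. The compatible system constrains the components
to the total:

    Y_stem = aX^b / S,  Y_branch = a r1 X^(b+k1) / S,
    Y_foliage = a r2 X^(b+k2) / S,  Y_root = a r3 X^(b+k3) / S,
    S = 1 + r1 X^k1 + r2 X^k2 + r3 X^k3

The eight parameters (a, b, r1–r3, k1–k3) are estimated jointly by
nonlinear seemingly unrelated regression (iterated feasible GLS with
power-of-x heteroscedasticity weights), validated by leave-one-out
jackknife (RMSEp, ME, ME%, MAE, MAE%, adjusted R²), and used to compare
four carbon-stock strategies — a direct carbon model versus biomass × {0.5,
whole-tree mean concentration, component mean concentrations} — via the
relative RMSE of carbon (RMSE_rc) and a randomized-complete-block ANOVA
with LSD letters. A seeded generator produces datasets with the assumed
structure (heteroscedastic, cross-correlated component noise;
concentrations near 0.47–0.49), so everything is testable without field
data. See `docs/methods.md` for details and assumptions.

## Worked example

```python
import allocarbon as ac
from allocarbon.simulate import SimulationConfig, simulate_dataset
from allocarbon.carbon import method_error_matrix, rmse_rc_table

trees = simulate_dataset(SimulationConfig(seed=1))   # 89-tree emulation
res = ac.CompatibleSystemModel(trees, "BM1").fit()
print(res.summary())
```

    Compatible additive system BM1 (biomass, predictor D)
    n = 89 trees, iterated FGLS, converged in 6 outer iterations
    variance-power weights (stem, branch, foliage, root): 2.33, 2.01, 1.67, 2.19

     param     estimate      std err
         a       0.0704       0.0084
         b       2.5330       0.0404
        r1       0.0011       0.0002
        r2       0.0314       0.0049
        r3       0.1003       0.0157
        k1       1.7619       0.0608
        k2       0.5212       0.0534
        k3       0.4561       0.0539

`a` and `b` are the total-biomass allometry (total = 0.0704·D^2.533 kg);
the ratios say, e.g., that the branch equation's coefficient is r1 ≈ 0.001
times the stem's while its exponent is k1 ≈ 1.76 larger — branches are a
small but steeply growing share. The generating values (a = 0.0891,
b = 2.456, …) sit within about two standard errors of the estimates.

```python
bm = res.jackknife()                                   # 89 leave-one-out refits
cm = ac.CompatibleSystemModel(trees, "CM3").fit().jackknife()
print(rmse_rc_table(method_error_matrix(trees, bm, cm)).round(2))
```

               stem  branch  foliage   root  total
    method_1  14.57    6.48     7.61  10.32  10.12
    method_2  14.84    8.96     7.44  11.64  10.98
    method_3  14.23    6.53     8.81  10.31   9.92
    method_4  14.40    6.34     7.28  10.28   9.89

Each entry is the relative RMSE (%) of leave-one-out carbon prediction.
The blanket 0.5 factor (method 2) is worst for stem and total — true stem
concentration is near 0.47, so 0.5 adds a systematic ~6 % bias — while the
empirical factors (methods 3–4) track the direct carbon model (method 1)
within a fraction of a point.

The same analysis runs from the shell:

    allocarbon run-all --labels BM1,CM3 --seed 1 --out-dir run/
    allocarbon simulate --n-trees 89 --seed 1 --out trees.csv
    allocarbon fit trees.csv --model BM1

`run-all` writes the tree table, per-system parameter/adjusted-R²/error
tables, conversion factors, the RMSE_rc table with bootstrap CIs, ANOVA
tables with LSD letters, and a run manifest. A field dataset in the same
CSV layout (see `allocarbon/data.py`; XLS via `--excel`) replaces the
simulation anywhere a table is accepted.

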
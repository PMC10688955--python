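# riskbn

Hybrid Bayesian-network analysis of how passengers of a (simulated)
self-driving car perceive collision risk when pedestrians cross its path.

## The problem

In a shared-space street experiment, participants ride through 36 scripted
pedestrian-crossing situations while (a) continuously rating perceived
collision risk with a rotary potentiometer (20 Hz) and (b) having their
electrodermal activity recorded.  Seven two-level factors describe each
crossing — pedestrian side and orientation, vehicle and pedestrian speed,
crossing angle, order of passage, and safety margin — arranged as a
2^(7−2) fractional factorial (32 runs, balanced through third-order
interactions) plus four scripted collision trials at fixed ranks.

Each trial is reduced to four indicators over the window from crossing
onset to 3 s after the pedestrian has passed:

* **iSA** — area under the subjective risk curve (dynamics of the rating),
* **mSA** — its maximum,
* **nSCR** — number of skin conductance responses (SCRs),
* **mSCR** — largest SCR amplitude.

The question is which factors drive which indicators, and whether the
physiological response is better explained by the factors or by the
subjective assessment itself.

## The model

Indicators are analysed in pairs — (iSA, nSCR) for dynamics, (mSA, mSCR)
for maxima — as nine-node hybrid Bayesian networks: seven Bernoulli(1/2)
factor roots, a Gaussian node for the subjective indicator (cell means
over its factor parents, shared variance) and a Tweedie node for the SCR
indicator.  The SCR indicators are zero-inflated nonnegative quantities,
so they follow a compound Poisson–gamma (Tweedie) law Tw_p(μ, φ) with
1 < p < 2, Var Y = φμ^p and

    Pr(Y = 0) = exp(−μ^(2−p) / (φ(2−p))),

fitted through a log link with the power p profiled by maximum likelihood
over the exact series density.  With each indicator allowed at most three
factor parents and at most one edge between the two indicators, there are
3 × (Σ_{i≤3} C(7, i))² = 12,288 candidate structures per pair.  All of
them are scored by BIC = −2 log L + k ln n (node families are fitted once
and reused across structures), ranked ascending, and differences graded on
Raftery's scale (≤2 weak, ≤6 positive, ≤10 strong, >10 very strong).
Finally the condition-cell means of the winning Gaussian node are
clustered by scoring every set partition of the cells (pooled means per
block, shared variance) with the same BIC currency.

Because the original recordings are not public, the package ships a
synthetic-data generator whose defaults plant the reported effect
structure (Order contrasts of 0.98/0.72 for iSA at the 1.5 m/2.5 m
margins, orientation-modulated contrasts 1.0/0.23 for mSA, log-link SCR
slopes 0.14 and 0.2), so the whole pipeline is testable end to end as a
parameter- and structure-recovery study.

## Worked example

```python
import riskbn as r

summary = r.run_pipeline(r.RunConfig(seed=7, n_participants=27,
                                     out_dir="demo"))
print(summary["pairs"]["dynamics"]["best_structure"])
print(summary["pairs"]["dynamics"]["order_contrast"])
```

prints (seed 7):

```
{'sa_parents': ['Order', 'Margin'], 'scr_parents': [],
 'inter_edge': 'sa_to_scr', 'bic': 12698.752343007307,
 'delta_bic': 0.0, 'grade': 'Weak'}
{'1.5 m': 1.060014, '2.5 m': 0.652864}
```

Reading: of the 12,288 candidate networks for the dynamics pair, the best
(lowest-BIC) one links the subjective indicator iSA to the factors Order
and Margin only, and explains the SCR count through iSA rather than
through any factor — exactly the planted structure.  The runner-up is
2.04 BIC points worse (positive evidence).  The fitted Order contrasts,
1.06 at the 1.5 m margin and 0.65 at 2.5 m, recover the planted 0.98 and
0.72 up to sampling noise, and the cluster stage groups the four
Margin × Order cells into three levels of perceived risk (first-passage at
1.5 m highest, second-passage at 2.5 m lowest, the other two cells
intermediate).

The same stages are available from the shell:

```sh
riskbn simulate --pair dynamics -n 27 -s 7 -o table.csv
riskbn search --pair dynamics --data table.csv -o top.csv
riskbn cluster --pair dynamics --data table.csv --parents Margin,Order -o cl.csv
riskbn run -s 7 -n 27 -o demo/
```

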
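# concord

Synthesis of significance lists from two or more related experiments.

When the same features (genes, probe sets, metabolites, network edges …) are
scored in several comparable experiments — different tissues, treatments or
species — a recurring question is which features are significant in *all* of
them, and at what significance cutoff the common list should be drawn.
`concord` answers both questions from nothing but the matrix of p-values
(one row per feature, one column per experiment; any ranking measure mapped
to a common [0, 1] scale works). It is aimed at analysts synthesizing
differential-expression results across related studies without access to the
raw data.

## The statistics

For a threshold *h* on the probability scale, let *O_l(h)* be the number of
features with *p ≤ h* in list *l*, *O(h)* the number significant in every
list, and *n* the total number of features. Under independence of the lists
the expected common count is

    E(h) = n · ∏_l ( O_l(h) / n )        (for two lists: O_1+ O_+1 / n)

and the **association ratio** is

    T(h) = O(h) / E(h).

Scanning *T* over a fine grid of thresholds avoids committing to one cutoff;
the ordinal statistic *T(h_max) = max_h T(h)* measures the maximal deviation
from independence and is tested by a **Monte Carlo permutation test**: the
first list is held fixed, every other column is independently permuted *B*
times, and each replicate contributes the maximum of its own curve to the
null distribution.

The **Bayesian counterpart** models the 2^L table of joint significance
patterns at each *h* as a multinomial with a conjugate Dirichlet(α = 1)
prior, and samples the posterior of

    R(h) = p_all / ∏_l m_l ,

the probability of being significant everywhere over the product of the
marginal significance probabilities. From the per-threshold posterior
quantiles two decision rules pick the reporting threshold:

* **h_max** — maximize the posterior median of *R* among thresholds whose
  credible interval excludes 1 (high specificity);
* **h_2** — the largest *h* with median *R* ≥ 2, i.e. where the common list
  at least doubles its chance expectation (balances specificity and
  sensitivity).

Either rule can be "not applicable"; the report says so rather than forcing
a threshold.

## Worked example

Simulate a two-list study of 2000 features in which 8% of features are
perturbed in both experiments and 3% in each experiment alone (perturbed
p-values drawn Beta(0.1, 1), nulls uniform), then run the full pipeline:

```sh
concord simulate --n 2000 --pi-common 0.08 --pi-specific 0.03 \
    --alt-shape 0.1 --seed 4 --out-dir demo
concord report demo/matrix.csv --draws 5000 --seed 4 --out-dir demo
concord test demo/matrix.csv -B 200 --seed 4 --out-dir demo
concord extract demo/matrix.csv -h 0.05 --out-dir demo
```

which prints

```
wrote 2000 x 2 matrix (171 features perturbed in all lists)
                   rule    h    T R_median  common  DE_List.Pval1  DE_List.Pval2          CI
h_max (freq & Bayesian) 0.01 4.98     4.95      67            166            162 4.17 - 5.79
                    h_2 0.10          2.08     141            364            371 1.86 - 2.31
pvalue < 0.005
104 features in common at h = 0.05
```

Reading the table: at the most stringent rule (*h_max* = 0.01) 67 features
are significant in both lists — 4.98 times the ≈13.5 expected by chance from
marginals of 166 and 162, with posterior median *R* = 4.95 and 95% credible
interval (4.17, 5.79). The more sensitive rule *h_2* = 0.10 reports 141
common features, the largest list whose common count still at least doubles
its chance expectation. The permutation test (B = 200) never produced a null
maximum as large as the observed one, hence `pvalue < 0.005` (an empirical
zero is reported as "< 1/B"). `extract` writes the common-feature list with
each feature's per-list p-values at any chosen threshold.

The same analyses are available as library functions (`ratio_curve`,
`find_hmax`, `permutation_test`, `posterior_curve`, `apply_rules`,
`create_table`, `extract_features`, `simulate_matrix`) on a `PValueMatrix`
read with `read_pvalue_matrix`.

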
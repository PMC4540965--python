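# coevotrace

Does amino-acid covariation measure molecular coevolution?  `coevotrace`
is a toolkit for asking that question quantitatively.  It combines

* an exact **two-site binary coevolution model**: a continuous-time Markov
  chain on the joint states (00, 01, 10, 11) in which matched states are
  favored with population-scaled selection strength *S*, every mutational
  rate being scaled by the diffusion-theory fixation factor
  *S* / (1 − e^(−*S*)) toward favored states and by its value at −*S*
  toward disfavored ones;
* **covariation metrics** on alignment columns (MI, MI/H(X,Y), the
  average-product-corrected MIp, a permutation-null-corrected MI, and the
  chi-square statistic), plus readers for externally computed score tables
  (PSICOV / direct-information style);
* **Fitch–Hartigan parsimony** on trees that classifies, for any column
  pair, each branch as carrying a single-site or a double (two-site)
  change, and the aggregate scores MP_ind (total independent changes) and
  MP_dep (branches with any joint change);
* **structural context**: minimum heavy-atom distances, contact maps,
  relative solvent accessibility (Naccess-style `.rsa` files or an internal
  Shrake–Rupley), burial classes, and volume-weighted pair accessibility;
* **evaluation machinery**: top-*L*/5 pair selection per metric, contact
  precision, bootstrap 95% random-expectation bands, and
  selected-versus-rest comparisons with BH false-discovery control;
* a **synthetic-data generator** producing trees, alignments with
  independent and coevolving binary columns (with exact per-branch event
  logs as ground truth), and structures in which burial is coupled to low
  evolutionary rate at a tunable strength ρ.

The central phenomenon the package exposes is the *coevolution paradox*:
selection strong enough to force compensatory double changes suppresses
the substitution rate so severely that such changes are rarely observable.
What the best covariation methods detect instead is largely pairs of
slowly evolving sites, which concentrate in the protein core and are
therefore in contact.

## Worked example

```python
from coevotrace.model import PairModelParams, relative_rate, single_fraction

print(f"{relative_rate(2.0):.4f}")                                    # 0.5514
print(f"{100 * single_fraction(PairModelParams(S=2.0, t=1.0)):.1f}")  # 72.3
print(f"{relative_rate(5.0):.4f}")                                    # 0.0674
```

Moderate coevolutionary selection (*S* = 2) already cuts the pair's
substitution rate to 0.55 of the neutral rate, and even for distantly
related sequences (*t* = 1.0) 72.3% of the observable substitutions are
still single changes.  Strong selection (*S* = 5) drops the rate to 6.7% —
almost nothing happens, which is exactly why coevolution is hard to see.

The `analysis/` directory holds the full narrative as numbered drivers:

```bash
python analysis/01_model_curves.py        # rate and change-class curves over S, t
python analysis/02_simulate_dataset.py    # protein-scale synthetic benchmark bundle
python analysis/03_decompose_covariation.py  # where each metric's signal comes from
python analysis/04_rate_burial_precision.py  # precision vs random; burial comparisons
python analysis/05_benchmarks.py          # replicated null + paradox experiments
```

Each writes its tables under `results/` and prints a summary; for
instance, driver 04 reports the smallest-mean-rate predictor at precision
0.38 against a random band topping out at 0.12, while every covariation
metric stays inside the band, and driver 05 finds the double:single branch
ratio elevated (sign test p ≈ 0.004) yet total changes reduced ~13-fold
for pairs simulated under strong coevolution.

A `coevotrace` command-line interface wraps the same steps
(`model-curves`, `simulate`, `score`, `parsimony`, `structure`,
`evaluate`, `run-all`); every output table carries its configuration hash
and seed, and identical invocations reproduce identical bytes.

## Layout

```
src/coevotrace/     library: model, covariation, parsimony, structure,
                    evaluation, simulate, pipeline, cli
analysis/           numbered narrative drivers (see above)
scripts/            acceptance.py
tests/              pytest suite, including end-to-end recovery tests
docs/methods.md     modeling and design notes
```
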
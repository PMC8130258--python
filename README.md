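# foodsecbn

Discrete Bayesian belief networks for household food-security analysis.

Food insecurity in low-resource rural settings is shaped by many interacting
household characteristics — education, employment, socio-economic status,
water access, household composition — and a policy that moves one of them
can ripple through the others.  `foodsecbn` implements the full modelling
pipeline used to study this as a *causal belief network* over 15 ordinal
household variables with a binary food-security outcome (FS; state 0 = food
secure):

* **Structure learning** — Max-Min Parents and Children (MMPC) driven by a
  stratified, tie-corrected Jonckheere–Terpstra conditional-independence
  test for ordinal data, constrained by a causal ordering of the variables
  (earlier levels may cause later ones; FS causes nothing), optionally
  seeded with an expert-elicited network as a prior.
* **Parameter estimation** — MAP conditional probability tables,
  θ_jk = (n_jk + 1)/(n_k + r), i.e. multinomial likelihood with a Dirichlet
  prior equivalent to add-one smoothing.
* **Exact inference** — variable elimination, verified against full-joint
  enumeration; posterior, MAP prediction and joint-marginal queries.
* **Predictive validation** — k-fold cross-validation scored by the Brier
  score S_B, information reward S_IR = mean(1 + log₂ p) and Bayesian
  information reward S_BIR (improvement over the food-insecurity base
  rate), plus 90/10 confusion matrices.
* **Interventions and sensitivity** — do-operator queries by graph surgery
  (P(FS | do(X = x))), and per-variable mutual-information reduction I,
  I/H(FS) and expected change of belief S².
* **Structure audit** — d-separation, minimum separating sets, and the
  enumeration of implied independence relations A ⊥ B | C for expert review.
* **Synthetic data** — a seeded generator of Agincourt-like household
  tables sampled from a known ground-truth network, so the whole pipeline is
  testable without access to restricted surveillance data.

See `docs/methods.md` for the model, formulas, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (they write their outputs to `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_learn_structures.py
python analysis/03_fit_and_validate.py
python analysis/04_interventions_sensitivity.py
```

which prints, for the bundled seed:

```
ground-truth network: 22 edges, FS parents = ['EdL', 'EmL', 'RCA', 'SES']
exact P(FS=insecure) = 0.1000; empirical = 0.1036 over 11739 households
data-only: 22 edges, skeleton F1 vs truth = 0.955
data+prior: 21 edges, skeleton F1 vs truth = 0.977
data: S_B=0.0399  S_IR=0.8069  S_BIR=0.2874  confusion tp=83 fp=20 tn=1021 fn=50
prior: S_B=0.0399  S_IR=0.8069  S_BIR=0.2874  confusion tp=83 fp=20 tn=1021 fn=50
baseline Pr(FS=secure) = 0.8929
most informative variables for FS: RCA (I=0.0931 bits), HHG (I=0.0743 bits), EmL (I=0.0626 bits)
do(EmL=2,SCL=1): Pr(FS=secure) = 0.7417
do(LLV=2,UWF=1,UCL=1): Pr(FS=secure) = 0.8929
do(CGS=1,EmL=2,SCL=1): Pr(FS=secure) = 0.7417
```

Reading this: 11,739 households are sampled from a known 22-edge network in
which food security is caused by education, employment, communal aid and
socio-economic status.  MMPC alone recovers the skeleton with F1 0.96;
seeding it with the expert network (here the truth itself) raises that to
0.98.  Cross-validated prediction of FS from the other 14 variables gets a
Brier score of 0.040 — far below the 0.25 of a coin — and a Bayesian
information reward of 0.29 bits, i.e. it clearly beats the 10% base rate.
The do-queries show graph surgery at work: forcing high employment while
controlling crop sales moves Pr(FS = secure) from 0.893 to 0.742 under this
particular ground truth (interventional effects follow the sampled truth's
CPTs, and can point either way), while intervening on variables with no
directed path to FS (LLV, UWF, UCL here) leaves it exactly unchanged.

The same steps are available as a CLI
(`foodsecbn simulate|learn|fit|validate|confusion|query|intervene|sensitivity|dsep-report|export-dot`),
e.g.:

```bash
foodsecbn learn --data results/households.csv --ordering results/ordering.yaml \
    --alpha 0.05 --out structure.json
foodsecbn intervene --network results/network_prior.json --set EmL=2,SCL=1 --target FS
```

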
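# Methods

## Model

The package works with discrete Bayesian belief networks over 15 household
variables — child grant status (CGS), education level (EdL), employment level
(EmL), household head gender (HHG), local vegetation level (LLV), number of
dependants (ND), number of working-age adults (NWAA), receipt of communal aid
(RCA), refugee status (RS), selling of crops and livestock (SCL),
socio-economic status (SES), use of crops and livestock (UCL), use of wild
foods (UWF), water access (WA) and the binary outcome food security (FS).
Each variable is ordinal with 2–4 states; FS state 0 means "food secure" and
state 1 "food insecure".  A network is a DAG plus one conditional probability
table (CPT) per variable,

    theta_i^{jk} = Pr(A_i = j | pa(A_i) = k),

and the joint distribution is the product of the CPT entries.  A fixed
*causal ordering* partitions the variables into levels (earlier levels may
cause later ones; FS sits alone in the last level and causes nothing).  The
ordering plays two roles: it orients every learned edge, which makes
acyclicity automatic, and it bars FS from appearing in any other variable's
candidate-cause set during learning.

## Inference

Queries are answered exactly by variable elimination with a greedy min-fill
elimination order.  Exactness, not speed, is the contract: on every network
small enough to enumerate, the engine must agree with brute-force summation
of the joint to 1e-10, and the test suite enforces this on batches of random
networks.  Junction-tree propagation would give identical answers; variable
elimination was chosen because it is simpler to verify against enumeration.
Zero-probability evidence raises a dedicated error instead of returning
NaNs; fitted networks cannot trigger it because smoothing keeps all CPT
entries positive, but user-supplied CPTs can.

Held-out prediction conditions on all 14 non-outcome variables.  With full
evidence the posterior is proportional to the joint, so the evaluation
module computes it by vectorised CPT indexing over whole data frames; the
tests assert this shortcut equals the engine per row.  (Conditioning on the
Markov blanket only would give the same numbers for an exact engine.)

## Structure learning

The skeleton is learned with Max-Min Parents and Children (MMPC).  For each
target variable, the forward phase repeatedly adds the candidate whose
*minimum* association over conditioning subsets of the current
parents-children set is greatest, stopping when no candidate's worst-case
association is significant; the backward phase removes any member rendered
independent by some subset; an edge survives under the conservative AND
rule.  Association is 1 − p from the conditional-independence test; subset
search is capped at `max_conditioning` (default 3) for tractability.  No
multiple-testing correction is applied inside MMPC — `alpha` (default 0.05)
is the per-test level, as in the algorithm's standard form.

Because FS is excluded from other variables' candidate sets by design, the
AND rule is applied only across sides that were allowed to consider the
other endpoint; an FS edge is therefore decided by FS's own
parents-and-children set alone.

### The ordinal independence test

Conditional independence is tested with an asymptotically normal
Jonckheere-Terpstra (JT) statistic, which targets monotone trend of an
ordinal Y across the ordered states of X — the natural alternative for
gradients such as education → employment → socio-economic status, with far
more power there than an omnibus chi-square.  For one stratum with group
sizes n_i (states of X) and Y tie-group sizes t_a:

    T    = sum_{i<j} [ #(Y_i < Y_j pairs) + #(Y_i = Y_j pairs)/2 ]
    E[T] = (n^2 − sum_i n_i^2) / 4
    Var[T] = standard tie-corrected three-term expression in n_i and t_a

Conditioning on C stratifies the data by C's configurations; strata with
fewer than `min_stratum` rows (default 5) are dropped.  T, E[T] and Var[T]
are summed over usable strata and referred, two-sided, to N(0, 1).  If no
variation survives in any usable stratum the test is degenerate and returns
p = 1.  The implementation works entirely from contingency tables, so a test
costs one `bincount` pass regardless of n; the tie-corrected moments are
verified in the tests against exhaustive permutation enumeration at n = 7,
and the statistic against a literal pairwise double loop.

Two-sided p-values are used because association direction is not
pre-specified per pair.

### Expert network as a prior

When an expert-elicited structure is supplied, its edges are injected into
the initial candidate sets of both endpoints and are retained unless the
data *fail to reject* independence at a laxer threshold `alpha_keep`
(default 0.20 > alpha); non-expert edges must pass the ordinary alpha.  This
is one defensible mechanism for letting data overrule weakly contradicted
expert edges while keeping supported ones; outputs under this rule should
not be read as replications of any published expert-seeded structure.

## Parameter estimation

CPTs are estimated by the MAP of a multinomial likelihood under a Dirichlet
prior equivalent to add-one smoothing:

    theta_jk = (n_jk + a) / (n_k + r a),   a = 1 by default.

Smoothing keeps every entry strictly positive even for parent configurations
absent from the data.  The pseudocount is exposed as a parameter so
sensitivity to the prior can be checked; the default reproduces add-one.
Complete cases are required; row filtering happens at load time.

## Predictive validation

Ten-fold cross-validation keeps the structure fixed and refits CPTs per
fold (seeded shuffle, contiguous near-equal folds, remainder spread one per
leading fold).  Held-out households are scored by:

* **Brier score** `S_B` — mean (p − y)^2 with y = 1 for food insecure.  The
  binary single-term convention is used (not the two-class sum); with a
  minority insecure class this keeps scores on the familiar [0, 1] scale.
* **Information reward** `S_IR` — mean 1 + log2 p(true state); equivalently
  1 minus the cross-entropy in bits.  Positive beats a fair coin.
* **Bayesian information reward** `S_BIR` — mean over the two classes of
  log2(p_c/p0_c) for the true class and log2((1−p_c)/(1−p0_c)) for the
  other, with the prior p0 set to the training split's food-insecurity
  frequency.  Positive means the model beats the base rate.

Logs are base 2 throughout (a documented constant; changing base rescales
IR and BIR linearly).  The 90/10 confusion matrix fits on a seeded 90% split
and takes the maximum-posterior FS state on the rest, ties resolving to
"food secure" (state 0); positive class is food insecure.  Confusion counts
move with the split seed, which is why the cross-validated scores are the
primary comparison.

## Interventions and sensitivity

An intervention do(X = x) is graph surgery: remove X's incoming edges, fix
its CPT to a point mass, and query the mutilated network; multi-variable
interventions cut all intervened variables simultaneously.  Surgery leaves
every other CPT bit-identical, and the tests verify the backdoor-adjustment
identity P(Y | do(X=x)) = Σ_z P(Y | x, z) P(z) against enumeration.

Sensitivity of FS to each other variable X is summarised by

    I   = H(FS) − Σ_x P(x) H(FS | X = x)        (bits)
    I/H = I / H(FS)
    S²  = Σ_x P(x) Σ_s (P(FS=s | x) − P(FS=s))²

with all distributions computed by exact inference.  Both metrics weight by
the *observational* marginal P(x): they measure how much observing X moves
beliefs about FS, not the effect of intervening on X.  The S² ("expected
change of belief") formula is a documented reconstruction of that
belief-change construction and is isolated behind a single function so it
can be swapped if a different variant is preferred.  If H(FS) = 0 the ratio
is reported as 0 with a degeneracy flag.

## Structure audit via d-separation

`d_separated` implements Bayes-ball reachability; the test suite checks it
against an independently coded moral-ancestral-graph oracle and against
networkx.  `reduce_relationships` emits, for every separable non-adjacent
pair, one relation A ⊥ B | C with A the later variable in the ordering and C
a minimum-cardinality separator (ties broken lexicographically on the sorted
member list, so output is reproducible); inseparable pairs are skipped.  Any
further human triage of which relations deserve expert review is out of
scope.  `implied_independencies` enumerates all singleton relations up to a
caller-chosen conditioning-set bound — the bound is a parameter because
exhaustive enumeration grows combinatorially.

## Synthetic household generator

The generator exists because the real surveillance data are restricted.  It
emulates: the 15-variable roster, a five-level causal ordering (L1 = HHG,
RS, EdL, NWAA, ND, LLV, WA; L2 = EmL, CGS, RCA; L3 = SES, UCL, UWF;
L4 = SCL; L5 = FS — a plausible, configurable stand-in, not a claim about
any published ordering), ordinal cardinalities 2–4, edges running only from
earlier to later levels (Bernoulli at `edge_density` = 0.25, at most 4
parents per child, FS guaranteed at least one parent), and a minority
food-insecure class.

CPTs use a monotone ordinal tilt: a Dirichlet(2.0) baseline row is
multiplied by exp(score · u_j), where u_j maps the child's states to
[−1, 1] and the score is a weighted sum of the parents' centred states with
random signs and magnitudes of about `effect_strength` = 1.5.  This produces
the dose-response-shaped conditional distributions expected of
socio-economic gradients, which is also the alternative the JT test is
designed to detect.  The FS table is then shifted on the logit scale so its
*exact* marginal insecurity probability equals `insecure_rate` (default
0.10; solved with Brent's method against the exact parent-set marginal).
Sampling is forward ancestral, fully vectorised, seeded.

What the generator does **not** emulate: missing data, survey measurement
error, longitudinal structure (one row per household, no repeated years),
non-monotone or interaction-dominated dependencies, and satellite-derived
vegetation processing (LLV is generated directly as an ordinal variable).
Passing tests therefore demonstrate correctness and calibration of the
machinery under monotone ordinal data-generating processes at realistic
scale — not performance on the real surveillance data.

`coarsen_rare_states` mirrors the usual pre-processing of sparse ordinal
scales: the rarest state below a frequency threshold is merged into its
less-rare ordinal neighbour (ties toward the interior) until every state
passes or two remain; the recode map is returned and order is preserved.

## Numerical choices and problem sizes

CPT rows must sum to 1 within 1e-12 at construction and 1e-9 at file load;
posteriors within 1e-10.  MAP prediction ties resolve to the lower state
index.  Minimal-separator ties resolve lexicographically.  All enumeration
outputs are canonically sorted.  Every stochastic routine takes an explicit
seed and is bit-reproducible; the CLI writes a run manifest (command,
parameters, seed, version) next to its outputs.

Parameter-recovery checks compare fitted CPT rows to the generator's truth
only for parent configurations with at least 1,000 observations: a binary
row estimated from m rows carries binomial noise with standard error up to
0.5/√m, so the 0.05 total-variation tolerance is a three-standard-error
bound at m = 1,000 but is routinely breached by noise alone near m = 100.

The bundled analyses and checks run at the study scale of 11,739 households
for the end-to-end pipeline, n = 10,000 for structure-recovery experiments
(10–20 seeds), n = 50,000 for parameter recovery, and 500–1,000 replicates
at n = 500 for test calibration; the full test suite completes in well under
a minute on one CPU.

## Known limitations

* The JT test has little power against non-monotone dependence; an edge
  whose effect reverses across the scale can be missed.  This is the price
  of targeting the ordinal alternative.
* The expert-prior mechanism (`alpha_keep`) is one reading of "expert
  network as a prior" for a constraint-based learner; score-based
  alternatives (structure priors in a Bayesian score) are out of scope.
* Orientation comes entirely from the causal ordering; the data are never
  asked to orient an edge, so a wrong ordering yields confidently wrong
  directions.
* S² is a reconstruction (see above).  I/H shares H(FS)'s degeneracy.
* No missing-data handling: complete cases are a hard contract.
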
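# Methods

## Ontology handling

The GO DAG is parsed from OBO (1.2/1.4) via `obonet` and wrapped so that
only non-obsolete terms enter the graph, alternate accessions remap to
primary ids, and edges are aspect-pure: the rare cross-aspect `part_of`
links are dropped so molecular function, biological process and cellular
component stay independent, each with a single root. Propagation follows
the true-path rule over `is_a` + `part_of` (a config flag restricts to
`is_a`); `regulates` is never followed, matching standard GOA practice.
Annotations that cannot be resolved are collected in a rejects report
rather than silently dropped. All counting scorers require their input
annotation sets to be propagated first; with propagated inputs every scorer
satisfies score(parent) ≥ score(child) by construction.

## Component scorers

**Structural (P1).** A protein is a structural neighbor of a domain when
their protein structure distance is strictly below 0.1 (PSD combines RMSD
with a secondary-structure alignment score; lower is more similar; it
arrives precomputed in the neighbor table). Duplicate (domain, protein)
rows collapse to the minimum PSD, and proteins are counted at PDB-entry
granularity (chains collapsed; a flag enables chain-level counting).
P1(g|d) is the fraction of neighbors annotated with g; terms carried by no
neighbor are omitted rather than emitted as zero, and a `min_support` floor
(default 1) can suppress fractions built on very few neighbors.

**InterPro (P2).** Distinct InterPro accessions hit by the domain define
the denominator n; each hit's InterPro2GO term set is closed under
ancestors before counting. Hits with no InterPro2GO entry stay in n and
contribute to no numerator — the equation divides by the number of InterPro
domains owned by the sequence, not the number of mapped ones.

**PSSM (P3).** Profiles are read from PSI-BLAST ASCII PSSM files (first,
log-odds block; the percentage block is ignored). The auto-covariance
transform yields 20 descriptors × 10 lags = 200 features; the optional
cross-covariance extension (covariance between distinct descriptor columns,
same 1/(DL−lag) normalization) is off by default — only the auto terms
define the canonical feature set here. One binary SVM per GO term (linear
kernel by default, for determinism; RBF by config) is trained on
standardized features when at least 10 positive and 10 negative domains
exist; otherwise the term is skipped with a logged reason. Margins are
calibrated to probabilities with the sigmoid 1/(1+e^{Af+B}) fitted by the
robust Newton procedure of Lin, Lin & Weng (2007) with prior-smoothed
targets, on out-of-fold margins from a stratified 5-fold split so the
calibration is not optimistically biased. A successful fit has A < 0, so
P3 increases with the margin. Note a calibrated sigmoid never outputs
exactly 0 or 1, so even noiseless training data yields P3 < 1.

**Homolog (P4).** Hits with query coverage strictly above 0.6 are retained
(query-relative, since the query is the domain being annotated; an explicit
`qcovs` column is preferred, else coverage is computed from the alignment
coordinates and a query-length table). One hit per (query, subject) is kept
at minimum E-value; E-values printed as 0.0 are clamped to 1e-180. Each
homolog votes with weight −log Eᵢ + b where b = log 10 in the same base —
the normalized weights are therefore base-invariant (every weight equals
log(10/Eᵢ) up to a common positive factor); natural log is used internally.
Hits whose weight would be non-positive (E ≥ 10) are dropped rather than
floored, since a negative weight breaks the probability contract.

## Likelihood-ratio integration

Scores are binned into 10 equal-width bins over [0, 1], left-closed with
the last bin closed at 1. On calibration data, LR_bin =
[(pos_bin+s)/(neg_bin+s)] / [(pos_tot+s)/(neg_tot+s)] with additive
smoothing s = 1 (s forbids zero and infinite ratios). The calibration
universe is the union of (domain, term) pairs any method scored; pairs in
propagated gold are positives, the rest negatives. An all-pairs universe is
available by passing explicit candidates but is dominated by never-predicted
pairs and adds nothing. Pairs a method did not score fall into a dedicated
"absent" pseudo-bin fitted the same way (neutral LR 1 when the universe has
no unscored pairs). Tables are fitted per method and per aspect; methods
combine by LR product (conditional independence given the label), and the
posterior is prior_odds·LR/(1+prior_odds·LR) with the prior odds estimated
per aspect on the same calibration universe. The default reporting cutoff
is posterior ≥ 0.5 (inclusive).

## Evaluation

Domain-centric CAFA-1 protocol: at each threshold t (the sorted distinct
prediction scores — exact maximization, no grid), precision is averaged
over domains predicting at least one term at ≥ t and recall over all
gold-annotated domains of the universe; Fmax is the maximum harmonic mean.
Aspect roots are excluded from gold and predictions (they are trivially
true), and prediction scores are propagated up the DAG by the
max-over-descendants rule so thresholded sets respect the true-path rule.
Coverage is the fraction of the domain universe with at least one
prediction. Train/test decontamination removes test domains with sequence
identity strictly above 0.9 to any training domain; identities are consumed
from a precomputed table (BLAST `pident`), not computed internally.

## Synthetic benchmark

The fixture generator emits every input dialect the pipeline reads, from a
seeded configuration, byte-identical under a fixed seed. Per aspect it
builds a random layered DAG (depth 4 by default, 60 terms across the three
aspects); each domain draws 2 gold and 2 decoy terms per aspect from a
single deep level, so gold and decoy picks are never ancestor-related and
generating rates survive closure exactly.

Signal model: every evidence carrier (neighbor protein, InterPro entry,
homolog) inherits each gold term with the channel's signal strength
(default 0.9) and each decoy term with the noise rate (default 0.4). Decoys
play the role of functionally related but wrong signals — structural
analogues, promiscuous signatures — which is what makes individual channels
fallible at desk scale the way real channels are at database scale.
Evidence is sparse (5 neighbors, 4 InterPro hits, 6 homologs per domain)
and each channel covers each domain with probability 0.8, emulating the
partial coverage of real sources; the fused annotator's coverage advantage
over single channels follows directly. PSSM profiles encode term membership
as elevated lag-one autocorrelation (AR(1), ρ = 0.65) on a per-term subset
of descriptor columns — syntactically valid integer log-odds files, not a
model of real substitution statistics. Homolog E-values are log-uniform on
[1e-30, 1e-2], spanning the weighting regime of the homolog vote without
modelling extreme-value theory. The neighbor table includes decoy rows
above the PSD cut and the homolog table rows below the coverage cut, so the
filters are exercised end to end.

What passing tests show — and not: the generator validates the counting
equations, the calibration machinery and the fusion logic under known
rates; it does not model real structure or sequence evolution, annotation
bias, or inter-channel error correlation, so synthetic Fmax values say
nothing quantitative about performance on real databases. The end-to-end
benchmark (160 domains, half train / half test) is sized so that per-aspect
Fmax estimates are stable while the full run completes in seconds.

A separate direct generator draws (score, label) pairs with explicit
per-bin positive rates, for which the analytic likelihood ratios are known
in closed form; it underpins the LR-recovery checks.

## Numerical choices and degenerate inputs

Sigmoid fitting uses Newton steps with backtracking line search, gradient
tolerance 1e-5 and a 1e-12 Hessian ridge; fits with a single label class
are rejected. Empty PSSM matrices, rows without exactly 20 scores,
sequences not longer than the AC lag, negative PSD values and cyclic
ontologies are hard errors. Scorers emit nothing (rather than zeros) for
domains without evidence, which the integrator handles through the absent
bin. Ties in bin assignment follow the left-closed convention; ties in
Fmax maximization resolve to the highest threshold attaining the maximum.

## Known limitations

Per-term priors are out of scope (priors are per aspect); inter-method
dependence is ignored by the product form; the cross-covariance feature
extension and RBF kernels are available but unexercised by the default
pipeline; identity-based decontamination relies on externally computed
identities.
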
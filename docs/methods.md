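# Methods

## Data model

The observation unit is a species × gene matrix of sex-specific PCR
outcomes: `M` (male-only amplification ⇒ Y-linked), `MF` (both sexes ⇒
autosomal or X-linked, written A/X), `F` (systematic failure in both
sexes ⇒ candidate genomic loss), `NA` (untested or failed assay). The
companion phylogeny is rooted, with optional branch lengths interpreted
as millions of years (Myr) throughout. Species matching between matrix
and tree is exact after whitespace trimming — no fuzzy matching, because a
silently mis-paired species corrupts the parsimony counts. Matrices are
tab-separated by default (comma via option) and common token synonyms
("male", "male+female", "fail", "-") are normalized on input.

## Ancestral reconstruction

Each gene is an independent three-state character, {Y, AX, absent}, with
tip states mapped from observations: M→Y, MF→AX, NA→free. `F` maps to
`absent` only when the failure is systematic — by default observed in at
least two species for that gene, or when explicitly confirmed — because a
single failed reaction cannot distinguish genomic loss from assay failure.

Reconstruction is generalized (Sankoff) parsimony: a bottom-up dynamic
program over an arbitrary transition-cost matrix, followed by a top-down
traceback. Three cost models are provided:

- **Dollo** (default for ancestrally Y-linked genes): `Y→AX`, `Y→absent`
  and `AX→absent` cost 1; `AX→Y` and every transition out of `absent`
  are forbidden (infinite cost); the root is fixed at `Y`. Y-linkage can
  only be lost, so the minimum cost is the number of independent loss
  events. The biological justification is asymmetry of the mechanism:
  a formerly Y-linked gene that moved or was lost has no plausible path
  back, whereas invoking repeated gains would require many more events.
- **Fitch**: unit costs everywhere, free root; for sensitivity analysis.
- **Sankoff**: arbitrary user costs (e.g. the "gains-only from an A/X
  root" model used to quantify the alternative hypothesis).

If the data require a forbidden transition under the chosen root
constraint, the reconstruction is reported as infeasible
(`InfeasibleReconstructionError`) rather than silently relaxed.

**Tie-breaking.** Among co-optimal assignments we use delayed
transformation (DELTRAN): during the top-down pass a child keeps its
parent's state whenever that choice is within 1e-12 of optimal, otherwise
the first optimal state in the fixed order (Y, AX, absent) is taken.
Children are visited in a canonical order (each node's subtree is keyed by
its lexically smallest tip name), so identical inputs give identical
reconstructions regardless of input rotation. Where an event could sit on
either of two adjacent edges (NA-heavy regions), DELTRAN pushes it toward
the tips; this is a convention, not an inference.

**Verification.** `brute_force_min_cost` enumerates every assignment of
the three states to internal nodes (≤ 14 tips) and is the oracle for the
dynamic program. NA tips are not enumerated: since `cost(s→s) = 0`, a
free leaf can always copy its parent at zero cost, which is the standard
"missing data are prunable" fact.

## Event classification

Per-gene state changes are aggregated into independent events per branch:

- **Incorporation**: on one branch, the set of `Y→AX` changes comprises at
  least `inc_fraction` (default 1.0) of the genes reconstructed Y-linked at
  the parent node, with at least `min_genes` (default 3) genes. The strict
  default corresponds to "all genes affected"; reports also carry a
  "nearly all" run at 0.9 because real incorporations can coincide with a
  prior individual loss of one gene. `min_genes = 3` guards against
  promoting coincident transfers of two genes into an incorporation.
- **Grouped transfer**: genes declared physically adjacent (user-supplied
  groups; adjacency is external evidence, never inferred) that change
  `Y→AX` on the same branch merge into one event.
- Remaining `Y→AX` changes are single-gene **transfers**; `Y→absent`
  changes are **genomic losses**; `AX→Y` changes (possible only outside
  Dollo mode) are **gains**. Every change belongs to exactly one event.

## Exposure and exact statistics

**Exposure** is the total time at risk: per gene, the sum of branch
lengths over branches whose parent node is reconstructed `Y`; the total
over genes is in gene-Myr. The branch on which a loss occurs is counted in
full — the event time within the branch is unobservable, and the
full-branch convention is the conservative (rate-lowering) choice; a
half-branch sensitivity option is provided. Rates are only reported for
trees with branch lengths in Myr; the unit-branch-length fallback disables
rate estimation and yields event counts only.

**Garwood interval.** For n events over exposure T, the exact central CI
is `[χ²(α/2, 2n)/2T, χ²(1−α/2, 2n+2)/2T]`, with lower bound 0 at n = 0.
Chi-square quantiles come from `scipy.stats.chi2.ppf`.

**Ratio of two Poisson means.** Conditional on n₁+n₂, n₁ is
Binomial(n₁+n₂, T₁/(T₁+T₂)) under equal rates. The two-sided p-value sums
outcomes whose point probability does not exceed the observed one
(minimum-likelihood convention); tail-doubling is available as an option.

**Fisher exact test.** Same minimum-likelihood convention over the
hypergeometric distribution with fixed margins. The minimum-likelihood
convention is the package default for both tests because it is the
standard two-sided definition for exact conditional tests; point
probabilities are compared with a relative tolerance of 1e-9 so that
floating-point noise cannot split exact ties. A zero margin leaves a
single admissible table and returns p = 1 rather than an error, so that
degenerate re-acquisition tables (no gene ever Y-linked) flow through.

## The duplicated-Y forward simulator

The simulator is the package's synthetic-data generator and the formal
statement of the duplicated-Y model. Per lineage and gene it tracks which
copies exist (Y, A/X, both, neither); events are independent Poisson
processes along branches, simulated exactly (Gillespie), with rates in
events per Myr:

| parameter | meaning | default |
|---|---|---|
| `lambda_transfer` | Y→A/X movement, per Y-only gene | 0 |
| `lambda_genomic_loss` | loss from the genome, per Y-only gene | 0 |
| `lambda_gain` | A/X→Y movement, per A/X-only gene | 0 |
| `mu_incorporation` | whole-Y incorporation, per lineage | 0 |
| `rho_resolution` | loss of one redundant copy, per redundant gene | 0 |
| `pi_keep_Y` | probability the Y copy survives a resolution | 0.5 |
| `pcr_fail_prob` | per-cell NA masking in the observation layer | 0 |

Rates default to 0 so every study switches on exactly the processes it
models. The reference magnitude for `lambda_transfer` is 0.001 /gene/Myr —
the empirical order of per-gene loss rates in the clade this assay targets
(about a dozen events over ~13,000 gene-Myr). Incorporation duplicates
every currently Y-only gene simultaneously (the model is
whole-chromosome; partial incorporations are not modelled), and is active
only while at least one gene is Y-only — with no gene-bearing free Y left
there is nothing to incorporate. No empirical estimate of
`rho_resolution` exists; its defaults in examples are illustrative, with
the observation that redundant copies must persist for ~13 Myr in some
lineages serving as an anecdotal lower bound on persistence, not a
calibration. `pi_keep_Y = 0.5` encodes the model's "more or less random
loss of either copy".

The observation layer maps the true copy state to assay codes: `M` iff
only the Y copy exists, `MF` whenever an A/X copy exists (a redundant Y
copy is invisible to the assay — this is precisely why "re-acquired"
Y-linkage surfaces only after the A/X copy is lost, and why only formerly
Y-linked genes can ever show it), `F` when no copy exists, with
independent NA masking. Forced incorporations can be pinned to a chosen
clade stem at a chosen fraction of the branch, for scenario studies and
round-trip tests.

**Determinism.** One integer seed drives a single `numpy` generator;
branches are traversed in canonical pre-order and genes scanned in input
order, so identical configurations give byte-identical outputs.

**Tree generation.** Pure-birth (Yule) trees: lineages split at
`birth_rate` per Myr; after the n-th lineage appears the process runs one
further exponential epoch and all tips are sampled. The recovery
experiments use 100-tip trees at birth rate 0.1/Myr (expected total length
≈ 990 Myr), giving roughly nine transfer events per replicate at the
reference rate — the same order as the empirical dataset, at a problem
size that keeps a 500-replicate experiment near one minute of CPU.

**What the generator does not emulate.** The PCR layer has no
false-positive amplification or female-DNA contamination (real protocols
control these by repeat testing and sequencing); branch lengths are taken
as known without error; the tree is complete (no unsampled extinct
lineages); genes evolve independently except through shared incorporation
events (no synteny-driven co-movement — adjacency groups exist only on the
inference side as user input). Passing recovery tests therefore shows the
inference is correct under the model's own assumptions, not that real
phylogenies or real PCR panels satisfy them.

## Parameter recovery and known behaviour

`recovery_experiment` simulates, observes, re-infers with Dollo parsimony
and scores: CI coverage of the true transfer rate, mean signed rate error,
exact agreement of inferred transfer (branch, gene) pairs with the truth
log, and incorporation detection sensitivity. A replicate is
*homoplasy-free* when no two true losses of the same gene sit on sister
lineages such that parsimony would merge them; this flag is computed from
the truth log alone (stems of maximal lost-from-Y subtrees), and in
homoplasy-free replicates inference recovers the truth log exactly — a
theorem-like property of Dollo parsimony that the tests assert at 100%.

Two deliberate conservatisms are worth knowing. First, the Garwood
interval over-covers at small counts (all exact intervals do); its
guarantee is coverage ≥ nominal, which the test suite asserts by
simulation, and realized coverage at ~9 expected events runs a few points
above 95%. Second, minimum-change inference merges independent losses of
the same gene on sister branches into one event; this undercounts in
exactly the replicates with many events, pulling high rate estimates back
toward the truth and adding roughly another point of coverage. Both
effects make the pipeline's intervals honest but conservative at small
event counts.

## Degenerate inputs and edge cases

- A gene with no informative (non-NA) tip raises `UninformativeGeneError`
  (skipped with a warning in the pipeline).
- Trees without branch lengths: event counting works; exposure and rates
  raise `ExposureError` pointing at the unit-length option.
- `fisher_exact_2x2` on a zero margin returns p = 1 (single admissible
  table); `poisson_ratio_test` requires at least one event in total.
- Simulation requires a seed; running the `simulate` command without one
  is an error, not a warning.

## Limitations

- Parsimony, not likelihood: no rate estimation on branches during
  reconstruction, and co-optimal solutions are resolved by convention
  (DELTRAN) rather than integrated over.
- Gains are detectable by the machinery (non-Dollo modes) but are not a
  headline output: the male-limited assay design cannot detect them
  without bias, so the simulator's `lambda_gain` exists mainly to probe
  robustness.
- The re-acquisition table treats "Y-linked in ≥ 1 clade species" as the
  unit of evidence, following the contingency design it implements;
  phylogenetic non-independence within the clade is not modelled.
- Packaged datasets cover the worked examples only (an 8-species single
  gene matrix, a partial *montium*-subgroup matrix restricted to facts
  stated in running text, the 2×2 re-acquisition counts, and a two-species
  primary-data example); full-scale multi-hundred-species analyses are
  expected to come from user data or the simulator.
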
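# Methods

## The estimator contract

Every model follows the scikit-learn lifecycle: hyperparameters at
construction (introspectable via `get_params`/`set_params`, so `clone`,
pipelines and grid search work unchanged), data only at `fit`, fitted state
in trailing-underscore attributes. Embedders return a pandas DataFrame with
one row per input sequence in input order and named feature channels, all
finite; scorers return one float per sequence. `score(data, labels)` is the
Spearman rank correlation between predictions and labels — zero-shot
outputs are rank-scale quantities, so rank correlation is the natural
framework-wide goodness measure, and it keeps supervised and zero-shot
models comparable on one axis.

Capabilities are immutable declarations made by mixing marker classes into
a model: needs an MSA at fit, needs structures, needs a wild type, needs
fixed-length input. `fit` runs the corresponding remediation hooks;
`check_compatibility` reports unmet requirements without raising, which
drives the registry's "what can run on my data?" discovery. The report
describes the data as given: a requirement that remediation could satisfy
at fit time (auto-alignment) is still listed, because the user asked what
the data provides, not what could be repaired.

## Alphabet and notation

The canonical alphabet is the 20 amino acids in the fixed order
`ACDEFGHIKLMNPQRSTVWY`; `X` is unknown, `-` is gap. Every channel layout in
the package derives indices from this one ordering, with the gap channel
last where present. Mutations are written `wt-residue, 1-based position,
mutant residue` (`"A2C"`), positions on the ungapped wild type — the
universal deep-mutational-scanning convention — with `:` separating
multiple substitutions. `X` may appear in sequences but is never a
mutagenesis target and is never produced by mutation application.

## Independent-sites profile model

An MSA of width W is summarized by per-column frequencies over 21 symbols
(gap included, `X` excluded from counts):

    f_j(a) = (c_j(a) + α) / (n_j + 21α)

with n_j the column's effective depth (family depth minus `X` occurrences)
and pseudocount α ≥ 0 (default 1.0, Laplace — guarantees finite log
scores; α = 0 gives maximum-likelihood frequencies but scoring an unseen
symbol then raises rather than returning −∞). Sequence log-likelihood is
the sum of column log frequencies (natural log, `X` positions skipped with
a warning); no length normalization or E-value calibration is applied —
scores are raw summed log-likelihoods, which is all the rank-based
downstream use requires. A variant's score is the mutant-minus-wild-type
log-likelihood, which telescopes to a sum over mutated columns. The
wild-type-to-column mapping comes from the wild type's own gap pattern when
it is a member of the fitted family, otherwise from aligning it to the
profile; a mutation at a position consumed as an insertion has no column
and is a hard error rather than a silently dropped term.

This is deliberately an independent-column site-frequency model, not a full
profile HMM: there are no insert/delete states or transition probabilities.
It is the model the alignment-based scorer here actually implements;
wrapping an external profile-HMM engine is a deployment concern outside
this package's scope, and pairwise-coupling (epistatic) models are likewise
out of scope.

## Marginal scoring protocols

A conditional sequence model exposes
`residue_distribution(context, position, masked)` → a probability vector
over the 20 canonical residues. Three protocols turn such a backend into a
variant score (natural log, empty variant = 0):

- **masked**: Σᵢ [ln p(mutᵢ | wt masked at i) − ln p(wtᵢ | wt masked at i)]
- **wildtype**: contexts are the unmasked wild type
- **mutant**: contexts are the full unmasked mutant sequence

The built-in backend renormalizes a profile column's canonical frequencies
and ignores the context entirely; under context independence the three
protocols coincide and equal the direct Δ log-likelihood (the shared
normalizer cancels in the difference). That collapse is asserted to 1e−9 in
the tests — it is the analytic signature that the protocol plumbing is
correct, and it is exactly the property that breaks (informatively) for a
real context-dependent language model. Backends returning distributions
that are negative or do not sum to 1 (tolerance 1e−12) trigger a contract
violation; marginal modes score canonical residues only — the gap symbol
participates in profile likelihoods but not in marginals, matching the
language-model contract.

## Alignment choices

Two deterministic dynamic programs, both with fixed tie-breaking so results
are reproducible bit-for-bit:

**Center-star auto-alignment** (the "attempt to align" remediation when an
MSA-requiring model receives unaligned sequences): pairwise global
alignment with match +1, mismatch 0, linear gap −1; the center is the
sequence maximizing summed pairwise score (lowest index on ties); pairwise
alignments merge under "once a gap, always a gap". Traceback prefers match,
then gap-in-second-sequence, then gap-in-first. Uniform-length inputs are
wrapped directly as a width-L family without realignment — fixed-length
variant sets are already trivially aligned, and rerunning DP on them buys
nothing. This is remediation machinery, adequate for small inputs; it is
not a substitute for a real MSA tool on large diverged families, and a
logged warning says automatic alignment occurred.

**Align-to-profile** (embedding new sequences in MSA coordinates and
mapping wild types to columns): global DP of a gap-free query against the W
columns. Match score is the log-odds of the column frequency against a
uniform background, ln(f_j(a) + ε) − ln(1/20) with ε = 1e−9; a deletion
(gap emitted in a column) costs −1.5, an insertion (query residue consumed
without a column) costs −1.5 per residue; `X` matches neutrally at 0.
Output width is always W. Ties prefer match, then deletion, then insertion.
The penalties are documented hyperparameters of the function; the defaults
penalize an indel roughly as much as a strongly conserved match rewards, so
alignment structure is driven by the conserved columns. Optimality is
verified against exhaustive enumeration of all monotone alignment paths on
small instances.

## Registry and tiers

Descriptors are grouped by dependency tier: *base* (this package only —
the two one-hot embedders, k-mer counts, the site-frequency scorer and the
profile-backed marginal scorer), *extra* (methods needing additional
pip-installable deep-learning dependencies) and *external_env* (methods
needing a separately built environment). Non-base entries are stubs: they
resolve `available=False` statically and raise a not-installed error naming
the missing dependency if instantiated, but their capability flags are
real, so compatibility checking exercises the full toolbox. MSA subsampling
is uniform without replacement, order-preserving and seeded; no sequence
weighting scheme is applied.

## Synthetic generator

`make_profile` draws each column's canonical frequencies from a symmetric
Dirichlet (default concentration 0.5 — sub-uniform concentration yields
peaked, conserved-looking columns, which keeps variant ranks
well-separated) scaled by (1 − gap_rate), with a fixed gap mass (default
0.1, a realistic order for homolog alignments). Default fixture seed is 42
and default depth 200; the parameter-recovery checks sample 2000 sequences,
deep enough that binomial error keeps the max-abs frequency error across
all columns and symbols under 0.05. `labeled_variants` emits random single
and double substitutions labeled with their true Δ log-likelihood plus
optional Gaussian noise.

The generator emulates column-wise conservation and gap content only.
Real families additionally have phylogenetic correlation between rows,
epistatic coupling between columns, and structured indels — none of which
independent column draws produce. Passing tests therefore demonstrate
correctness of the estimators and protocols under the independent-sites
generating model, not predictive performance on real proteins; epistatic
landscape simulation is explicitly out of scope because scoring it
honestly would require coupling machinery this package does not implement.

## Structure handling

A PDB chain is reduced to its residue sequence: one residue per distinct
(residue number, insertion code) bearing a CA atom, in file order, HETATM
ignored, alternate locations collapsed to one residue, unknown residue
names mapped to `X`. Author numbering is reported verbatim —
`check_sequence_structure_match` reports mismatch positions and length
differences but never renumbers; resolving numbering offsets is left to the
user, who knows the provenance of both. This is the minimal contract that
makes structure-requiring capability checks (including the wild-type
structure fallback, which warns once per fallback) testable; coordinates
and geometry are out of scope.

## Command-line interface

Subcommands mirror the notebook-scale tasks as scriptable units:
`check-models`, `embed` (onehot | onehot-aligned | kmer), `score` (profile
| marginal with the three modes), `mutate` (saturation), `sample-msa`.
Parsing produces a fully serializable plan; outputs are written atomically
with a JSON manifest (plan + version + seed) beside them, so identical
plans on identical inputs give byte-identical outputs. In mutation-list
files a line `WT` denotes the empty variant (score 0), `#` starts a
comment. Usage errors exit 2; domain errors exit 1 with a one-line message.

## Problem sizes and determinism

Test and acceptance computations use desk-scale sizes chosen to make the
assertions sharp: width 12–30 profiles, families of 60–2000 sequences,
100-variant rank checks, and ≥ 200 random instances (W ≤ 6, L ≤ 6) for the
exhaustive-enumeration alignment oracle. All randomness flows through
seeded numpy generators; property tests run derandomized. Known
limitations: the auto-aligner is O(n²·L²) and meant for small inputs; k is
capped at 3 to keep dense k-mer output manageable; scoring assumes
substitution-only variants (no indel scoring); and the profile scorer's
treatment of `X` (skip, with warning) biases absolute log-likelihoods for
X-rich sequences, though variant deltas are unaffected unless the mutated
position itself is unknown.
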
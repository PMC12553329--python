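# protmodel

Protein property prediction — both sequence featurization for supervised
learning and zero-shot (label-free) variant-effect scoring — suffers from
every method shipping its own interface, input conventions, and dependency
stack. `protmodel` puts a zoo of lightweight protein models behind one
scikit-learn-compatible contract: construct with hyperparameters, `fit` on
protein data, then `transform` (embedders) or `predict` (scorers), with
declared **capabilities** (needs an MSA, needs a structure, needs a
wild-type sequence) that are checked and, where possible, remediated
automatically. Models drop straight into scikit-learn pipelines,
cross-validation and grid search.

It is aimed at protein engineers and computational biologists who want to
compare featurization and zero-shot strategies on their own variant or
homolog data in a single reproducible script.

## What is implemented

**Data types** — `ProteinSequence`, `ProteinSequenceSet`, `AlignedFamily`
(an MSA), `MutationSpec` (`"A2C"` notation, 1-based on the ungapped wild
type, `:`-separated multiples), with FASTA/A2M I/O, mutation application and
diffing, saturation mutagenesis, and minimal PDB chain extraction for
structure-consistency checks.

**Embedders** —

| model | features | dimension |
|---|---|---|
| `OneHotEmbedding` | binary indicators per position, 20 canonical residues | 20·L |
| `AlignedOneHotEmbedding` | per MSA column, 20 residues + gap channel; new sequences aligned to the column profile | 21·W |
| `KMerEmbedding` | k-mer counts, k ≤ 3, lexicographic channels | 20ᵏ |

**Zero-shot scorers** — the independent-sites (site-frequency) model over
an MSA: column frequencies with pseudocount smoothing

    f_j(a) = (c_j(a) + α) / (n_j + 21α),

sequence log-likelihood `Σ_j ln f_j(s_j)`, and variant scores
`Δ = log L(mutant) − log L(wild type) = Σ_i [ln f_{j(i)}(mut_i) − ln f_{j(i)}(wt_i)]`.
Plus the three **marginal protocols** (masked, wild-type, mutant marginal)
that turn any conditional residue-probability model — the contract protein
language models expose — into a variant score; the built-in backend is the
context-free profile model, under which all three protocols coincide
exactly. All scores are natural-log units, higher = more favorable, and the
empty variant scores exactly 0.

**Registry** — descriptors for the full toolbox, including stubs for
GPU/external-environment methods (ESM2-, SaProt-, MSA-transformer-style
models, coupling and VAE scorers) that carry real capability metadata, so
`available_models(bundle)` answers "which models could run on my data?"
without any heavy dependency installed.

**Synthetic data** — `protmodel.synthetic` draws ground-truth column
profiles (symmetric Dirichlet per column plus a gap mass), samples
alignment families from them and generates labeled variant sets whose
labels are true Δ log-likelihoods, enabling exact parameter-recovery and
rank-consistency tests with zero downloads.

## Worked example

```python
from protmodel import (
    DataBundle, ProfileLikelihoodScorer, MarginalLikelihoodScorer,
    parse_mutation_string,
)
from protmodel.synthetic import (
    SyntheticFamilySpec, make_profile, sample_family, consensus_wt,
)

spec = SyntheticFamilySpec(width=12, depth=60, seed=42)
profile = make_profile(spec)              # ground-truth column frequencies
family = sample_family(profile, 60, seed=42)
wt = consensus_wt(profile)
print("wild type:", wt.residues)

scorer = ProfileLikelihoodScorer(alpha=1.0).fit(family)
variants = [parse_mutation_string(s) for s in ("H3C", "H3C:A7W", "A7W")]
for v in scorer.score_variants(wt, variants):
    print(f"{v.variant_id:10s} {v.score:+.3f}")

marginal = MarginalLikelihoodScorer(mode="masked").fit(
    DataBundle(sequences=family.members, alignment=family, wild_type=wt)
)
print("masked marginal H3C:", f"{marginal.score_mutations(variants[:1])[0]:+.3f}")
```

prints

```
wild type: MQHCGGAPPEYF
H3C        -1.674
H3C:A7W    -3.689
A7W        -2.015
masked marginal H3C: -1.674
```

Each number is the natural-log likelihood ratio of mutant to wild type
under the profile fitted on the 60-sequence family: all three substitutions
move away from the consensus, so all score negative, and the double mutant
is the sum of its parts (the independent-sites model is additive). The
masked-marginal protocol over the profile backend reproduces the direct
Δ log-likelihood — the expected collapse for a context-free model.

## Command line

```sh
protmodel check-models --fasta seqs.fasta --msa family.fasta
protmodel embed --method kmer --k 2 --fasta seqs.fasta --out emb.tsv
protmodel score --msa family.fasta --wt wt.fasta --variants muts.txt --out scores.tsv
protmodel mutate --fasta wt.fasta --positions 1,2 --out library.fasta
protmodel sample-msa --msa family.fasta --n 100 --seed 7 --out sub.fasta
```

Outputs are tab-delimited; every run writes a `*.manifest.json` with the
full serialized plan, package version and seed for reproducibility.

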
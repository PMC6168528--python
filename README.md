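# solpot

Solubility-dependent statistical distance potentials for globular proteins.

Protein solubility is a basic biophysical property and a recurring
bottleneck in structural biology and recombinant protein production.
`solpot` probes it with the knowledge-based potential formalism: given a set
of protein structures labeled with experimental solubility (percent soluble
fraction), it derives distance-dependent residue-pair potentials separately
from the soluble and the weakly soluble halves of the set, asks which pair
interactions differ significantly between the two — i.e. which interactions
*promote* or *reduce* solubility — and scores whole proteins by a
solubility-linked folding free-energy difference.

## The model

For residue types s, s′ at side-chain centroid distance d, the inverse
Boltzmann relation converts observation frequencies F in a structure set
into an effective energy

    ΔW(s, s′, d) = −k_B T · ln [ F(s, s′, d) / ( F(s, s′) · F(d) ) ]

Distances are binned on [3, 10) Å in 0.2 Å bins with one overflow bin for
d ≥ 10 Å; sequence separations |i − j| = 2…8 each get their own potential
and |i − j| > 8 a single long-range one. The solubility-dependent variants
take the joint frequency F(s, s′, d) and the distance marginal F(d) from
the soluble (or insoluble) half, while keeping the pair-composition
frequency F(s, s′) from the full set:

    ΔW^sol(s, s′, d)  = −k_B T · ln [ F(s,s′,d | D^sol)  / ( F(s,s′ | D^tot) · F(d | D^sol) ) ]
    ΔW^insol(s, s′, d) = −k_B T · ln [ F(s,s′,d | D^insol) / ( F(s,s′ | D^tot) · F(d | D^insol) ) ]

Small-dataset noise is handled by two layers: a 5-tap neighbour smoothing
of the counts (weights 1/α², 1/α, 1, 1/α, 1/α² with α = 4/3) and an
occurrence threshold (counts ≤ 10 ⇒ the bin's potential is set to 0).

Per residue pair, the two potentials are compared over the distance bins
of the long-range class by

    M = ⟨ ΔW^insol − ΔW^sol ⟩_d        V = ⟨ (ΔW^insol − ΔW^sol)² ⟩_d

so M > 0 marks a *solubilizing* pair (more favourable in soluble proteins)
and M < 0 an *insolubilizing* one. Significance comes from a
randomization null: the full set is randomly re-split into equal halves
100 times and the pipeline re-run; Sig M (Sig V) is the fraction of null
|M| (V) values below the actual one, with a strict criterion
Sig M ≥ 0.95 ∧ Sig V ≥ 0.95 and a relaxed one using ∨.

Finally each protein is scored by the folding free-energy difference

    score = ΔW^insol_{S,C} − ΔW^sol_{S,C},   ΔW_{S,C} = Σ_{i<j−1} ΔW(s_i, s_j, d_ij)

computed with strict leave-one-out (the protein's own pair counts are
removed from every derivation set first). Larger scores predict higher
solubility.

## Worked example

Real structure sets are user-supplied (annotation table + PDB/mmCIF
files); the built-in generator produces geometric surrogate proteins with
plantable contacts, which is what the tests run on. Here the soluble
class carries planted Lys-Glu salt bridges at 4 Å and the insoluble class
planted Trp-Trp stacking at 6.3 Å:

```python
import numpy as np
from solpot import (
    GeneratorParams, RECOVERY_BIASES, RunConfig, BinningScheme,
    generate_dataset, stack_counts, run_significance, loo_energies, pearson,
)
from solpot.alphabet import pair_index

cfg = RunConfig(seed=1)
dataset, proteins, truth = generate_dataset(
    GeneratorParams(seed=1, planted_biases=RECOVERY_BIASES)
)
stack = stack_counts(dataset.records, BinningScheme.from_config(cfg))
results, table, _ = run_significance(
    stack, dataset.sol_indices, dataset.insol_indices, cfg
)
ke = results[pair_index("K", "E")]
ww = results[pair_index("W", "W")]
print(f"Lys-Glu: M = {ke.M:+.3f} kcal/mol, SigM = {ke.sig_m:.2f}, "
      f"strict = {ke.strict}, {ke.direction}")
print(f"Trp-Trp: M = {ww.M:+.3f} kcal/mol, SigM = {ww.sig_m:.2f}, "
      f"strict = {ww.strict}, {ww.direction}")

energies = loo_energies(dataset, cfg, stack)
scores = np.array([e.score for e in energies])
solubility = np.array([r.solubility for r in dataset.records])
print(f"r(score, solubility) = {pearson(scores, solubility):.2f}")
```

Output:

```
Lys-Glu: M = +0.739 kcal/mol, SigM = 1.00, strict = True, solubilizing
Trp-Trp: M = -0.763 kcal/mol, SigM = 1.00, strict = True, insolubilizing
r(score, solubility) = 0.89
```

The planted salt bridge is recovered as significantly solubilizing, the
planted aromatic stacking as insolubilizing, and the leave-one-out score
correlates strongly with the (pseudo-)solubility labels.

The same workflow is available from the shell:

```sh
solpot simulate --out-dir data --seed 1
solpot derive --annotation data/annotation.tsv --structure-dir data --out-dir pots
solpot significance --annotation data/annotation.tsv --structure-dir data --out-dir sig
solpot score --annotation data/annotation.tsv --structure-dir data --loo --out-dir scores
```

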
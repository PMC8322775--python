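# wgrmf — lncRNA–protein interaction prediction by weighted graph-regularized matrix factorization

Long non-coding RNAs act largely through the proteins they bind, but
experimentally validated lncRNA–protein interactions (LPIs) are sparse:
a typical curated matrix has hundreds of lncRNAs, a few dozen proteins,
and ~15 % known pairs. `wgrmf` ranks the unobserved pairs of such a
binary interaction matrix by combining three ingredients:

1. **Multi-source similarity kernels.** For lncRNAs: linear-neighborhood
   similarity (LNS) over 20-dimensional nucleotide-composition
   descriptors, Pearson-correlation similarity of expression profiles,
   and a Gaussian kernel on interaction profiles. For proteins:
   normalized Smith–Waterman alignment scores, LNS over grouped k-mer
   (conjoint-triad) descriptors, and the interaction-profile kernel.
2. **Similarity kernel fusion (SKF).** The kernels of each entity type
   are merged by iterative cross-diffusion through their k-nearest-
   neighbor structure, then down-weighted where the sources disagree,
   and sparsified through a p-NN graph (mutual neighbors keep weight 1,
   one-sided 0.5, others 0).
3. **Weighted graph-regularized matrix factorization (WGRMF).** Latent
   factors A (n×k) and B (m×k) minimize

   ```
   Σ_ij W_ij (Y_ij − a_i·b_j)²  +  λ_f (‖A‖_F² + ‖B‖_F²)
        +  λ_l Tr(Aᵀ L̃_l A)  +  λ_p Tr(Bᵀ L̃_p B)
   ```

   where W down-weights unobserved pairs (W_ij = 1 for known
   interactions, 0.1 otherwise) and L̃_l, L̃_p are normalized Laplacians
   of the sparsified similarity graphs. The solver alternates exact
   row-wise ridge least-squares updates from a truncated-SVD start;
   predicted scores are A·Bᵀ. Defaults: k=50, p=7, λ_f=0.5, λ_l=0.3,
   λ_p=0.005.

The package ships a seed-controlled synthetic-scenario generator
(planted low-rank structure with sequences and expression profiles that
carry signal about the planted factors), so every stage is testable
without downloading any database.

## Worked example

Generate a synthetic study, fit the pipeline, and score the hidden
interactions:

```python
from wgrmf import recovery_experiment

result = recovery_experiment(
    n=60, m=60, rank_true=4, density=0.15, noise=0.0,
    hide_fraction=0.2, seed=0,
)
print(result)
```

prints

```
{'auc': 0.9149479544904381, 'aupr': 0.4666522741465708,
 'n_hidden': 108.0, 'n_evaluated': 3168.0}
```

meaning: of a 60×60 matrix with 540 planted interactions, 108 were
hidden, the pipeline was fit on the remainder, and the hidden pairs were
ranked against 3060 true unknowns with AUC 0.91 — the hidden positives
sit near the top of the candidate list (AUPR 0.47 against a ~0.03
prevalence baseline).

The same flow from the shell:

```bash
wgrmf simulate --out sim --n 60 --m 60 --seed 0
wgrmf fit-predict --out run \
    --interactions sim/interactions.tsv \
    --lncrna-fasta sim/lncrna.fasta \
    --protein-fasta sim/protein.fasta \
    --expression sim/expression.tsv
head -3 run/top_candidates.tsv
```

`run/scores.tsv` holds the dense score matrix and
`run/top_candidates.tsv` the top-5 proteins per lncRNA with a flag for
already-known pairs. `wgrmf evaluate` adds cross-validated
precision/recall/accuracy/F1/AUC/AUPR, and `wgrmf grid-search` sweeps
hyper-parameter grids by mean CV AUC. All commands accept a flat YAML
config; the resolved configuration is echoed next to the outputs.

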
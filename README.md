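# fragbayes

Ligand-based binary activity classification for small molecules. The package
featurizes compounds with **atom-center fragments** (ACFs: rooted subgraphs of
bounded radius around every heavy atom) and sparse **circular fingerprints**,
trains **Laplacian-corrected naive Bayesian** and **depth-bounded
recursive-partitioning (CART)** classifiers, ranks favorable/unfavorable
fragments by Bayesian weight, and evaluates everything with the standard
confusion-matrix suite (SE, SP, Q_i, Q_ni, Q, Matthews C, ROC/AUC).

A seeded synthetic-library generator plants class-defining substructures
(a nitrogen-in-saturated-ring motif for actives, a lactam motif for
inactives) so the whole pipeline is testable without any external dataset.

## Modules

| module | role |
| --- | --- |
| `fragbayes.chemio` | SMILES/SDF reading, standardization (salt stripping, H folding), activity labelling against a potency cutoff, duplicate collapsing, train/test splitting |
| `fragbayes.featurize` | 13-descriptor panel (count descriptors native; AlogP/logS/MPSA/MSA via a pluggable RDKit-backed provider), circular fingerprints (diameter 4/6), ACF enumeration (levels 1–6) with a canonical rooted-subgraph key |
| `fragbayes.nbayes` | Laplacian-corrected naive Bayes: fit/score/predict, uncertainty zones, fragment ranking, equal-frequency descriptor binning, exact leave-one-out fast path, JSON persistence |
| `fragbayes.rpart` | Greedy Gini decision trees over mixed binary/numeric features, depth sweep with stratified 5-fold CV selection |
| `fragbayes.evalx` | Confusion metrics, ROC/AUC (tie-aware trapezoid = Mann–Whitney), CV drivers, Welch t test, Pearson r |
| `fragbayes.synthdata` | Synthetic library generator + packaged published confusion-table fixtures |
| `fragbayes.cli` | `fragbayes` command with `simulate`, `featurize`, `train`, `predict`, `rank-fragments`, `evaluate` |

## CLI walkthrough

```bash
# 500-compound synthetic library (80% actives, planted-fragment fidelity 0.9)
fragbayes simulate --n 500 --seed 7 --out lib.smi

# Laplacian-corrected NB on multilevel ACFs (levels 1..2)
fragbayes train --library lib.smi --model nb --features acf --acf-level 2 \
    --seed 1 --outdir run_nb

# recursive partitioning with a CV-selected depth from the 3..20 sweep
fragbayes train --library lib.smi --model rp --features acf --acf-level 2 \
    --depths 3:20 --outdir run_rp

# score new compounds, rank privileged fragments
fragbayes predict --model run_nb/model.nb.json --library lib.smi \
    --features acf --acf-level 2 --out preds.tsv
fragbayes rank-fragments --model run_nb/model.nb.json --top-k 20 --out frags.tsv
```

Every command echoes its configuration as JSON next to its outputs; rerunning
from the same configuration reproduces outputs byte-identically.

## Conventions and caveats

- Activity labels use a *strict* cutoff: a value exactly equal to the cutoff
  is a non-inhibitor. Ki and IC50 values are pooled without conversion.
- Bayesian weights use natural log and the Laplacian correction
  `K = 1/P_active`, so features never seen in training contribute exactly 0.
- The default score uncertainty zone is (−20, 0).
- The ACF canonical key is a reconstruction (deterministic
  individualization–refinement labelling with attachment-point markers); the
  original vendor encoding is unpublished.
- logD has no backing model in the default descriptor provider and is
  reported missing; downstream learners drop missing columns.
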
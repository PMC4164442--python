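# rfmqa

Random-forest model quality assessment for protein decoy pools.

Protein structure prediction produces a *pool* of candidate 3D models
("decoys") for each target sequence, and the practical question is which
candidate to trust: the single-model quality-assessment problem. `rfmqa`
ranks the decoys of a pool by a random-forest prediction of their
*relative* TM-score, learned from nine per-model features:

| # | feature | source |
|---|---------|--------|
| F1–F3 | three statistical-potential energies | imported score tables (dDFIRE/RWplus/GOAP slots) or the built-in contact pseudo-energy |
| F4–F6 | helix / sheet / coil match fractions | secondary structure observed in the model (Kabsch–Sander H-bonds) vs predicted from sequence |
| F7 | confidence-weighted SS consistency score | same, weighted by predictor confidence |
| F8–F9 | Pearson and cosine ASA consistency | solvent accessibility computed on the model (Shrake–Rupley) vs predicted from sequence |

Every feature column and the TM-score label are min-max normalised to
[0, 1] *within each pool*, so the forest learns relative quality and the
absolute units of imported energies never matter. The package contains
everything needed to run and test the pipeline without external
binaries or downloads: a PDB reader/writer, a TM-score engine
(Kabsch superposition plus fragment-seeded iterative extension), a
from-scratch regression random forest with out-of-bag permutation
importance, the full training protocol (screening, per-pool
normalisation, target-level cross-validation, hyperparameter grid
search), an evaluation metric suite (CC_TM, Spearman, TM_loss,
selection Z-scores, CC_rank, pairwise gain/loss), and a synthetic
target/decoy generator that stands in for the external data sources.

## Quickstart (Python)

```python
from rfmqa import (DecoyGeneratorParams, TrainingConfig, fit_final,
                   make_pools, normalize_pool, rank_pool, tm_loss)

template = DecoyGeneratorParams(n_residues=30, n_decoys=8)
pools = make_pools(12, base_seed=7, template=template)
train, test = pools[:10], pools[10:]

forest = fit_final(train, n_tree=300, m_try=1, config=TrainingConfig(seed=7))
print(f"trained on {len(train)} pools, OOB MSE = {forest.oob_error:.4f}")
for pool in test:
    ranked = rank_pool(forest, normalize_pool(pool))
    best, score = ranked[0]
    print(f"{pool.target_id}: picked {best} (score {score:.3f}), "
          f"TM loss {tm_loss(pool, best):.3f}")
```

Output:

```text
trained on 10 pools, OOB MSE = 0.0325
synth700031: picked decoy_000 (score 0.877), TM loss 0.000
synth700032: picked decoy_000 (score 0.895), TM loss 0.000
```

## Quickstart (command line)

```sh
printf 'n_residues: 30\nn_decoys: 8\n' > gen.yaml
rfmqa simulate --params gen.yaml --out-dir pools --n-pools 4 --seed 3
for d in pools/*/; do
    rfmqa extract --pool-dir "$d" --out "feat_$(basename $d).csv"
done
# concatenate the per-pool tables (strip the provenance headers)
python -c "import pandas as pd, glob; pd.concat(
    [pd.read_csv(f, comment='#') for f in sorted(glob.glob('feat_*.csv'))]
    ).to_csv('features.csv', index=False)"
rfmqa train --features features.csv --out model.json \
      --n-tree 300 --m-try 1 --seed 3
rfmqa rank  --model model.json --features features.csv --out ranking.csv
python -c "import pandas as pd; pd.read_csv('features.csv')[
    ['target_id','model_id','label']].to_csv('labels.csv', index=False)"
rfmqa eval  --rankings ranking.csv --labels labels.csv --report report.json
```

which reports (on the training pools themselves, hence the perfect
selection):

```text
ranking: CC_TM=1.000 TM_loss=0.000 CC_rank=0.9107142857142858
```

`ranking.csv` starts with a provenance header and one row per model:

```text
# rfmqa 0.1.0 seed=0 config_hash=6d160bbff9de0369
target_id,rank,model_id,predicted_score
synth300009,1,decoy_000,0.8024333499000998
synth300009,2,decoy_001,0.5187827202207186
...
```

`rfmqa tmscore reference.pdb decoy.pdb` prints the TM-score of a single
pair, and feature extraction also accepts externally produced inputs:
DSSP output files, PSIPRED `.ss2` files, two-column energy tables.

## Layout

```
src/rfmqa/
  structure_io.py       PDB parsing/writing, ProteinModel
  struct_features.py    secondary structure, ASA, DSSP/PSIPRED parsers
  tmscore.py            Kabsch superposition and TM-score
  potentials.py         energy tables and built-in contact potential
  features.py           9-feature assembly and per-pool normalisation
  random_forest.py      from-scratch regression forest + OOB importance
  training_pipeline.py  screening, CV, grid search, final fit, ranking
  evaluation.py         CC_TM, Spearman, TM_loss, Z-scores, CC_rank
  synthetic.py          backbone builder, decoy generator, predictor stand-ins
  cli.py                simulate / extract / tmscore / train / rank / eval
docs/methods.md         model description, parameter choices, limitations
scripts/acceptance.py   headline experiment, JSON output
tests/                  property-based suite incl. end-to-end acceptance tests
```

See `docs/methods.md` for the scientific background, all default
parameters and their rationale, and known limitations.
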
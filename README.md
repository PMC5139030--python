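# modelqa

Single-model protein quality assessment with a deep belief network.

Given a predicted 3D model of a protein — and nothing else, no pool of
alternative models to compare against — `modelqa` estimates how close that
model is to the (unknown) native structure, on the GDT-TS scale in [0, 1].
This is the model-ranking problem of structure prediction: an *ab initio*
pipeline produces thousands of candidate structures of mostly poor quality,
and a quality-assessment (QA) score must pick the few good ones. Consensus
QA methods need a deep, diverse pool; a single-model method like this one
works on each candidate in isolation.

## Method

Each model is described by 16 features, all mapped to [0, 1]:

* **7 physio-chemical scores computed from the structure** — surface score
  SU (exposed nonpolar area / total area), exposed mass EM, exposed surface
  ES, solvent-accessibility agreement SA, secondary-structure similarity SS,
  secondary-structure penalty SP, and Euclidean compactness EC. These use a
  deterministic Shrake–Rupley SASA, a dihedral-window secondary-structure
  assigner, and CA–CA distance matrices.
* **9 external potential / QA scores consumed as inputs** — DFIRE2, RWplus,
  RF_CB_SRS_OD, Dope, GOAP, OPUS, ProQ2, ModelEvaluator, Qprob. The three
  raw energies are normalized by fixed length-dependent maps, e.g.

  ```
  S_DFIRE2 = −P_DFIRE2 / (1.971 · L)
  S_RWplus = −P_RWplus / (232.6 · L)
  S_RF     = (700 − P_RF) / (1000 + 0.4823 · L)
  ```

  clamped to [0, 1]. Any feature that cannot be computed is imputed at the
  neutral value 0.5.

The regressor is a deep belief network: two stacked restricted Boltzmann
machines (default 20 and 10 hidden units) pretrained with one-step
contrastive divergence (learning rate 1e-4, weight cost 0.007, momentum
0.5 → 0.9), topped by a logistic output node, then fine-tuned end-to-end
against mean squared error with BFGS. Training quality is monitored by
five-fold cross-validation MAE.

QA performance is evaluated the way blind assessments score it: per-target
Pearson correlation between predicted and real GDT-TS, per-target loss
(GDT-TS of the pool best minus GDT-TS of the top-ranked model), best-of-
top-5 TM-score/RMSD, pool-standardized Z-score sums, and Wilcoxon
signed-rank tests between paired per-target metrics. GDT-TS and TM-score
are computed with an LGA-style iterative superposition search.

A synthetic-data module generates ideal-geometry natives, noise-graded
decoy pools and feature datasets with a known feature→quality mapping, so
the entire pipeline trains and evaluates with no external downloads.

## Worked example

Simulate two decoy pools (25 decoys each, L=20, noise 0.5–8 Å), train on
the first, rank the second:

```
$ modelqa simulate --preset pool --config pool.yaml --seed 5 -o pool
wrote pool of 25 decoys to pool
$ modelqa simulate --preset pool --config pool.yaml --seed 9 -o pool_eval
wrote pool of 25 decoys to pool_eval
$ modelqa train --features pool/features.tsv --targets pool/targets.tsv \
      --seed 7 -o modeldir
cross-validation mean MAE: 0.0335
model written to modeldir/model.json
$ modelqa predict --pool pool_eval/models --fasta pool_eval/target.fasta \
      --scores pool_eval/scores.tsv --ss pool_eval/pred.ss \
      --sa pool_eval/pred.sa --model modeldir/model.json -o predictions.tsv
wrote 25 predictions to predictions.tsv
```

The predictions track the true (held-out) GDT-TS of the unseen pool:

```
       model  predicted  gdt_ts
decoy_s0_000   0.972807  0.9625
decoy_s0_002   0.972639  0.9500
decoy_s0_003   0.972383  0.9500
```

and `modelqa evaluate --pred ... --truth pool_eval/truth.tsv -o evalout`
summarizes the ranking quality:

```
"average_r": 0.997,          # per-target Pearson r, predicted vs true GDT-TS
"average_loss": 0.025,       # GDT-TS given up by trusting the top-ranked model
"zscore_sum_tm": 1.78,       # selected models sit ~1.8 pool-sd above the mean TM-score
"zscore_sum_rmsd": -0.92     # and below the pool mean RMSD (lower is better)
```

A cross-validation MAE of 0.034 means the predicted quality of a held-out
decoy is off by about 3 GDT-TS points on average; a loss of 0.025 means the
model the method ranks first is within 0.025 GDT-TS of the best model
actually present in the pool.

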
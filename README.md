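# mutstab

Structure-based prediction of protein stability changes (ΔΔG, kcal/mol)
upon single and multiple point mutations, for protein engineers and
variant-interpretation pipelines. Missense mutations perturb the folding
free energy of a protein; predicting the sign and magnitude of that
perturbation from the wild-type structure is central to prioritising
variants and designing stabilised proteins. A long-standing failure mode
of such predictors is broken *anti-symmetry*: thermodynamics requires that
the reverse mutation (mutant → wild type) carries exactly the negated ΔΔG,
yet models trained on destabilising-heavy data systematically violate it.

## Method

The pipeline has three stages:

1. **Featurization.** The local environment of the mutated residue(s) —
   every residue with a heavy atom within 10 Å — is summarised by a
   cutoff-scanning graph signature: atoms are labelled with eight
   pharmacophore classes (hydrophobic, positive, negative, H-bond
   acceptor/donor, aromatic, sulphur, neutral), and cumulative counts of
   labelled atom pairs are taken at distance cutoffs 2, 4, 6, 8, 10 Å,
   giving 36 unordered pair categories × 5 bins. Signatures are computed
   for the wild type, for a deterministically built fixed-backbone mutant
   model, and as their difference. Complementary features add substitution
   deltas over curated physicochemical scales, BLOSUM/PAM scores, relative
   solvent accessibility (Shrake–Rupley), residue depth, a 3-state
   secondary-structure class from backbone torsions, and simplified atomic
   contact counts with their change upon mutation. All features are
   z-normalised with training-set statistics.

2. **Siamese network.** One sub-network maps a feature record to a raw
   score; the *same weights* are applied to the forward record and to the
   hypothetical-reverse record (mutant as reference, substitutions
   reversed), giving raw outputs f and r. Signature channels pass through
   1-D convolutions along the distance-bin axis and a transformer encoder
   attending over bins; complementary features pass through two dense
   layers; both are concatenated with a linear projection of the raw
   inputs (residual connection) and reduced by a dense head. The served
   prediction is ΔΔG = (f − r)/2, which is **exactly anti-symmetric under
   exchanging the two orientations, at any weights**.

3. **Training loss.**

       loss = logcosh((f − r)/2 − y) + |f + r|

   where y is the experimental forward ΔΔG (≥ 0 = stabilising). The first
   term scores accuracy, the second penalises anti-symmetry violation; the
   loss is zero exactly when f = y and r = −y. Datasets are deduplicated
   (keeping the record measured closest to pH 7, then 25 °C), augmented
   with hypothetical reverse mutations (ΔΔG_rev = −ΔΔG_fwd), and split into
   cross-validation folds at mutation or protein level (no protein ever
   crosses folds in the protein-level scheme).

## Worked example

Everything runs offline on synthetic fixtures:

```bash
mutstab fixtures --out-dir fx --n-residues 12 --seed 7   # toy PDBs + labels
mutstab featurize --pdb fx/helix.pdb --mutations muts.txt --out feats.tsv
mutstab train --features feats.tsv --labels labels.csv --out model.npz --epochs 40
mutstab predict --checkpoint model.npz --pdb fx/helix.pdb \
        --mutations "A F8W,A V4A" --out preds.tsv
```

The prediction table printed by the run above:

```
mutation  ddg_final  ddg_forward_raw  ddg_reverse_raw
A F8W      0.47169    0.94527          0.00193
A V4A     -0.67684   -0.28628          1.06741
```

`ddg_final` is the served prediction (f − r)/2 in kcal/mol — here F8W is
predicted mildly stabilising and V4A destabilising on the toy model;
`ddg_forward_raw`/`ddg_reverse_raw` are the two sub-network outputs whose
residual sum |f + r| measures how far training pushed the pair from perfect
anti-symmetry. Asking for `--include-reverse` adds rows whose predictions
are the exact negations. `mutstab evaluate` then reports Pearson/Spearman/
Kendall correlations, RMSE, MAE and mean signed error against a truth
table (on this 10-mutation toy set with random labels the correlations are
near zero, as expected — the example demonstrates the mechanics, not
learnable signal; see `tests/` for the n=2000 recovery experiment where the
held-out Pearson exceeds 0.9).

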
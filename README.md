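# skinsens

Quantum-descriptor modeling of skin-sensitization potential for the
mechanistically hard-to-classify aniline and phenol chemical space.

## The problem

Skin sensitization (type IV, T-cell-mediated allergic contact dermatitis)
is usually initiated when an electrophilic chemical — or its activation
product — covalently modifies nucleophilic side chains of skin proteins.
Most sensitizers fall into five reaction-mechanism classes (Michael
acceptors, SN2 and SNAr electrophiles, Schiff-base formers, acylating
agents) and are well predicted by structural alerts. Anilines and phenols
are a large, frequently sensitizing exception: many cannot be assigned to
any of those classes, and their potency is notoriously variable.

For that residual chemical space, sensitization potential tracks the energy
of the highest occupied molecular orbital, ε<sub>HOMO</sub> (hartree): a
higher ε<sub>HOMO</sub> means the molecule loses an electron more easily,
consistent with activation by autoxidation or direct reaction with
protein-associated free radicals. The package implements the linear
discriminant

P = 15.30 · ε<sub>HOMO</sub> + 5.08,  sensitizer ⇔ P > 0.50

equivalently ε<sub>HOMO</sub> > (0.50 − 5.08)/15.30 = −0.299 ≈ −0.30
hartree, together with everything around it:

- **Applicability-domain filtering** (`skinsens.domain`): aniline/phenol
  moiety detection and a curated, versioned SMARTS alert set for the five
  electrophilic classes plus quinone precursors (two OH/NH2 ortho/para on
  one aromatic ring) and, for the drug stage, sulfonamide drugs.
- **Descriptors** (`skinsens.descriptors`): the nine quantum descriptors
  (frontier orbital energies, Mulliken charge statistics, dipole), a parser
  for Gaussian-style output logs, and train-split min–max normalization.
- **Model fitting** (`skinsens.model`): 1/0 label coding, normal-equations
  OLS, backward stepwise abandonment of low-weight descriptors,
  de-normalization to raw units, and intercept calibration of the published
  reference model to full precision from any printed score.
- **Potency** (`skinsens.potency`): correlation of −log₁₀ EC3 (murine LLNA)
  with the continuous score P, with outlier exclusion.
- **Drug screening** (`skinsens.screen`): filter an approved-drug table to
  in-domain aniline/phenol drugs, score, and compare against
  allergic-dermatitis adverse-event flags.
- **Synthetic data** (`skinsens.simulate`): class-conditional Gaussian
  ε<sub>HOMO</sub> generator (defaults estimated from the packaged
  reference table) plus uninformative nuisance descriptors.

Two packaged fixtures transcribe the reference data: `table1` (30 labeled
anilines/phenols with printed ε<sub>HOMO</sub>, P, EC3 and a 15/15
train/test split) and `table2` (6 FDA-approved drugs with printed P values
and adverse-event flags). Structures are curated SMILES reconstructed from
the printed names/CAS numbers; each row carries a provenance note.

## Worked example

```python
import skinsens as sk

table = sk.load_fixture("table1")
model = sk.calibrated_published_model(table)   # slope 15.30, intercept 5.0780
print(model.intercept)                         # 5.078
print(sk.homo_threshold(model))                # -0.2992156862745098

preds = [sk.classify(sk.predict_score(model, r.epsilon_homo)) for r in table]
print(sk.evaluate_accuracy(preds, [r.label for r in table]))   # 30/30 (100.0%)

recs = sk.potency_records(table)               # the 9 chemicals with EC3
print(sk.potency_correlation(recs))            # (0.6725..., 9, ())
print(sk.potency_correlation(recs, exclude=["6"]))  # aniline out: (0.9064..., 8, ('6',))

report = sk.screen_drugs(sk.load_fixture("table2"), model)
print(report.predicted_sensitizers, sk.confusion_counts(report))  # 5 (5, 1, 0)
```

The intercept 5.0780 is recovered from the printed score of
4,4′-diaminodiphenyl ether (P = 1.0694 at ε<sub>HOMO</sub> = −0.262) and
reproduces every other printed score to 4 decimal places. The potency
correlation rises from r ≈ 0.67 to r ≈ 0.91 once aniline — whose measured
LLNA potency is far weaker than its score suggests — is excluded. Of the
six drugs with reported allergic dermatitis, five (clenbuterol, dapsone,
morphine, hydromorphone, raloxifene) score above 0.50; liothyronine
(P = −0.001) is the single miss.

The same pipeline is scriptable from the shell:

```bash
skinsens predict table1 -o preds.csv --published
skinsens evaluate preds.csv               # 30/30 (100.0%)
skinsens screen-drugs table2
skinsens simulate --n-pos 100 --n-neg 100 --seed 1 -o sim.csv
skinsens fit sim.csv -o model.json        # selected: epsilon_homo
```

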
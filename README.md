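# ctfold — circuit-topology fold analysis for disordered protein ensembles

`ctfold` analyzes conformational ensembles of intrinsically disordered
proteins (IDPs) through the *circuit topology* (CT) of their intrachain
contacts. Unlike geometric metrics (radius of gyration, SASA), which
fluctuate with every solvent-exposed loop movement, the arrangement of
contacts along the chain is a robust signature of transient compaction: it
detects *disordered compact states* — chains that look unstructured but
hold persistent nonlocal contacts.

The package is aimed at people analyzing MD ensembles of IDPs (or any
per-frame contact lists) who want a threshold-free, contact-level notion of
compaction, plus the standard downstream statistics: state-resolved contact
maps, dwell-time kinetics, autocorrelation, contact-space PCA with
free-energy landscapes, and Rg/SASA observables.

## The CT Folding Score

Any two contacts, viewed as closed intervals `[i, j]` on the residue index,
are in exactly one relation:

- **series (S)** — disjoint intervals,
- **parallel (P)** — one interval nested inside the other,
- **cross (X)** — partially overlapping (entangled) intervals.

For each frame, count the relations over all contact pairs and normalize by
their ensemble means:

```
Score = P/⟨P⟩ + S/⟨S⟩ + X/⟨X⟩
```

By construction the ensemble-mean score is 3 (one per relation type that
occurs at all), so a frame is **topologically compact (T-compact)** iff its
score strictly exceeds 3 — each relation type is, on average, over-represented.
An alternative threshold at the lowest-probability point between the two
modes of the score histogram is available for clearly bimodal ensembles.

## Worked example

Generate a synthetic two-state trajectory (a 58-residue chain switching
between a solvent-exposed coil and a compact state that adds 10 nonlocal
contacts; switching rates 0.01 and 0.02 /ns, 0.5 ns frames), then score it:

```
$ ctfold simulate --out contacts.csv --labels-out labels.csv --n-frames 5000 --seed 42
simulated 5000 frames, compact occupancy 0.290 -> contacts.csv

$ ctfold score contacts.csv --out scores.csv --dt-ns 0.5
threshold=3.000  compact fraction=0.355  -> scores.csv
```

The threshold is exactly 3 (the ensemble-mean score); 35.5% of frames score
above it, versus a true compact occupancy of 29.0% — the per-frame labels
recover the hidden state with balanced accuracy 0.94. `ctfold pipeline
contacts.csv --out-dir run --dt-ns 0.5` additionally writes dwell-time
records, exponential fits, the score autocorrelation (half-decay 11.5 ns for
this trajectory) and a reproducibility manifest.

The same works on structures: `ctfold contacts ensemble.pdb --out
contacts.csv --cutoff-nm 0.5` extracts residue contacts (minimum heavy-atom
distance ≤ 0.5 nm, sequence separation ≥ 3) from a multi-model PDB, with
optional equilibration/stride and periodic-image preprocessing filters.
`ctfold pca` and `ctfold maps` produce contact-space PCA projections with
free-energy landscapes and state-resolved mean contact maps.

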
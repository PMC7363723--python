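# linkscan

Analysis toolkit for two-domain p-loop ATPase protein families of the
Kti12/PSTK type, in which an N-terminal ATPase domain and a C-terminal
tRNA-binding domain are joined by a flexible linker. Some fungal Kti12
proteins (notably in *Eurotiomycetes*) carry dramatically elongated linkers
(~55-60 residues, versus the 18-22 residue animal type and ~30 residue
plant/yeast type) together with a substitution of the Walker A signature
lysine (K14 → L/I). `linkscan` implements the comparative-sequence pipeline
that exposes this kind of evolutionary coupling, plus the biophysical fits
used to characterise the variants:

- **Linker analysis** — reference-anchored NTD/linker/CTD delimitation on a
  curated alignment, length binning, regular/elongated classification, Welch
  *t* test between groups, and linker residue-composition profiling.
- **Co-segregation screen** — every alignment column is scored by the exact
  best symbol-to-class partition, `acc = Σ_s max(n_s,class0, n_s,class1)/n`
  (per-symbol majority is provably optimal for a single column), together
  with the Matthews correlation coefficient *r* of the induced prediction.
  A linear-SVM margin classifier on the one-hot column encoding is kept as a
  cross-check. A perfectly co-segregating p-loop column appears as
  `accuracy = 1.0, r = 1`.
- **Phylogenetics** — Poisson-corrected distances `d = −ln(1 − p)` with
  pairwise deletion of gaps/ambiguities, Saitou–Nei neighbor joining with
  deterministic tie-breaking, Felsenstein column-bootstrap supports, and
  Newick output.
- **Assay models** — one-site binding fits
  `P(c) = P0 + (Pmax − P0)·c/(Kd + c)` for fluorescence-polarization
  titrations (with an optional ligand-depletion form), Boltzmann-sigmoid Tm
  extraction from thermal-shift curves, ΔTm with propagated error, and
  relative ATPase activity from malachite-green endpoint data.
- **Synthetic data** — a planted-truth generator for families (three linker
  populations, a planted co-segregating p-loop column, Thr-enriched /
  Lys-depleted long linkers) and for binding/melt/ATPase datasets, so every
  stage is testable without external downloads.

The screen and the assay fits are scikit-learn style estimators
(`CosegregationScreen`, `OneSiteBindingModel`, `BoltzmannMeltModel`) and
compose with sklearn tooling; the module-level functions wrap them.

## Worked example

```python
from linkscan import (two_class_config, generate_family, partition_domains,
                      classify_linkers, compare_groups, screen_alignment)

fam, truth = generate_family(two_class_config(n_per_class=100, seed=7))
ref = fam.ids[0]
part = partition_domains(fam, ref, truth.ref_ntd_end, truth.ref_ctd_start(ref))
classing = classify_linkers(part)          # threshold 45 residues
print(classing.counts)

lengths = part.linker_lengths
t = compare_groups(lengths[classing.classes == "regular"],
                   lengths[classing.classes == "elongated"])
print(f"Welch t = {t.statistic:.1f}, p = {t.p_value:.3g}")

report = screen_alignment(fam, classing, ref_id=ref, seed=7)
best = report.best
print(f"best column {best.column} (residue {best.ref_residue}): "
      f"accuracy {best.best_accuracy:.2f}, r {best.r:.2f}, {best.partition}")
```

prints

```
{'regular': 100, 'elongated': 100}
Welch t = -162.5, p = 6.63e-202
best column 14 (residue 14): accuracy 1.00, r 1.00, {'K': 'regular', 'L': 'elongated'}
```

i.e. the regular and elongated linker populations are cleanly separated in
length, and a single alignment column — the p-loop position 14, lysine in
every regular-linker sequence and leucine in every elongated one — classifies
the two groups perfectly.

The same pipeline is available from the shell:

```bash
linkscan simulate --n-per-class 100 --seed 7 --out-prefix fam
linkscan linker --alignment fam.fasta --meta fam.meta.tsv \
    --ref-id regular_000 --ntd-end 120 --ctd-start 141 --out-prefix out
linkscan screen --alignment fam.fasta --classes classes.tsv --ref-id regular_000
linkscan phylo --alignment fam.fasta --bootstrap 1000 --seed 7 --out tree.nwk
linkscan assays fit-binding --in binding.csv --out fits.json
```

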
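# paravar

Variant interpretation for voltage-gated channel families: dataset
curation, paralogue annotation transfer, predictor benchmarking and
consensus reclassification of variants of uncertain significance (VUS).

## The problem

Defects in *CACNA1C*, the pore-forming α1 subunit of the cardiac L-type
calcium channel Cav1.2, cause long QT syndrome, Timothy syndrome and other
arrhythmias — yet the clinical significance is known for only a small
minority of the missense variants in public databases. `paravar` is for
computational geneticists and channel biologists who want to prioritize
those uncharacterized variants using two independent lines of evidence:

1. **In-silico pathogenicity predictors.** Given a dbNSFP-style score
   panel, the package benchmarks each tool against curated
   pathogenic/likely-pathogenic (P/LP) and frequency-defined benign
   variants: rank-form AUC, ROC curves and an optimal threshold.
2. **Paralogue annotation.** Voltage-gated Na⁺/Ca²⁺ channels share one
   body plan (four repeat domains DI–DIV of six transmembrane segments
   each). A P/LP variant at some position of one family member is evidence
   that the alignment-equivalent position of another member is intolerant
   to substitution — provided the alignment column is physicochemically
   conserved.

A VUS is promoted to *putative P/LP* only when both lines agree.

## The statistics at the core

**Benign-by-frequency rule.** An unasserted variant with population allele
frequency AF > 10⁻⁴ (strictly) is treated as benign; curated P/LP
assertions take precedence.

**Conservation score.** Each residue is a 10-bit vector over the Taylor /
Livingstone–Barton property classes (hydrophobic, polar, small, tiny,
aliphatic, aromatic, positive, negative, charged, proline). For an
alignment column,

```
Cs = (# properties whose presence/absence state is identical
      across all residues in the column) / 10  ∈ [0, 1]
```

so an identical column scores 1.0 and, e.g., {I, L, V} scores 0.9 (only
"small" disagrees). A mapped position is *supported* when ≥1 paralogue
P/LP variant lands on it and Cs > 0.3 (strict).

**Benchmark.** With P/LP as positives and benign as negatives, AUC is
computed in the Mann–Whitney rank form, `P(score_pos > score_neg)` with
ties counted ½ (equal to the trapezoidal area under the ROC curve). The
operating threshold maximizes Youden's `J = sensitivity + specificity − 1`
over midpoints of consecutive distinct scores; sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/total. Tools missing scores
for ≥30 % of the labelled variants are dropped; each retained tool is
evaluated on its own complete cases.

**Consensus.** `putative P/LP = {VUS : tool score > threshold} ∩
{VUS : paralogue-supported}` — both inequalities strict, unscored VUS are
never promoted.

## Worked example

```python
from paravar import (PredictorBenchmark, ToolPanel, ParalogueAnnotation,
                     ConsensusReclassification, assemble_dataset, Category)
from paravar.simulate import (SimulationConfig, simulate_family,
                              simulate_variants, simulate_scores)

cfg = SimulationConfig(seed=42, length=300, n_plp=15, n_benign=15, n_vus=80,
                       n_planted_support_positions=6, n_paralogues=12)
family = simulate_family(cfg)
tables = simulate_variants(cfg, family)
ds = assemble_dataset(tables.tables)
pathogenic = ({v.key for v in ds if v.category is Category.PLP}
              | {v.key for v in ds if v.gene == "CACNA1C"
                 and v.position in tables.planted_support_positions})
panel = ToolPanel.from_frame(simulate_scores(cfg, ds,
                                             pathogenic_keys=pathogenic))
bench = PredictorBenchmark(ds, panel).fit()
print(bench.summary())
```

```
Predictor benchmark: 29 P/LP vs 15 benign variants
==================================================
          tool   threshold   auc sensitivity specificity accuracy  n missing_fraction
          MCap   >0.861267 0.900       0.880       0.857    0.872 39            0.114
      ClinPred    >1.37116 0.919       0.815       0.867    0.833 42            0.045
         REVEL    >1.15192 0.883       0.750       0.867    0.791 43            0.023
          SIFT  <-0.503366 0.857       0.778       0.800    0.786 42            0.045
MutationTaster >-0.0791819 0.737       0.864       0.643    0.778 36            0.182
```

Each row is one tool evaluated on its complete cases (`n` labelled
variants scored): its rank AUC, the Youden-optimal threshold on the tool's
own scale (`<` marks SIFT-style tools where smaller means more
pathogenic), and the confusion-matrix metrics at that threshold. The table
is sorted by accuracy, then AUC. Continuing with annotation transfer and
the consensus:

```python
ann = ParalogueAnnotation(family[0], "CACNA1C", tables.paralogue_plp).fit()
best = bench.table().iloc[0]["tool"]
scores = {k: float(v) for k, v in panel.scores[best].items()}
res = ConsensusReclassification(ds, "CACNA1C", scores,
                                bench[best].threshold, ann.report,
                                tool_name=best).fit()
print(res.summary())
print(res.to_table().to_string(index=False))
```

```
Consensus reclassification of 80 CACNA1C VUS
==============================================
tool (MCap) threshold (oriented): > 0.861267
tool-positive:            20
paralogue-supported:      6
PUTATIVE_PLP          4
VUS_TOOL_ONLY         16
VUS_PARALOGUE_ONLY    1
VUS                   59
unscored (kept as VUS):   5

 # variant location                                                          paralogues
 1    V34Y                                         CACNA1A-L34A,CACNA1S-I34A,NALCN-L34H
 2    D47A                                                                   NALCN-D47P
 3   S213Y          CACNA1A-S212Y,CACNA1E-T210A,CACNA1F-T209L,CACNA1H-T211W,SCN2A-S211W
 4   M264H                                                    CACNA1H-M267Y,NALCN-M266H
```

Of the 6 positions planted with paralogue support, 4 clear both evidence
bars at MCap's threshold and are promoted; one supported VUS scored below
the threshold (`VUS_PARALOGUE_ONLY`) and one had no score (never
promoted). The `location` column is filled from a region table — the
packaged, reconstructed Cav1.2 topology via
`res.to_table(regions=paravar.default_cav12_regions())` — when positions
live on the real channel.

The same pipeline runs from the shell:

```bash
paravar simulate --seed 42 --out run/
paravar assemble --sources run/sources --out run/broad.tsv
paravar annotate --alignment run/family.fasta --target CACNA1C \
        --paralogue-variants run/paralogue_plp.tsv --out run/supports.tsv
paravar evaluate --dataset run/broad.tsv --scores run/panel.tsv --out run/bench
paravar reclassify --dataset run/broad.tsv --scores run/panel.tsv \
        --tool ClinPred --threshold 0.66 --supports run/supports.tsv \
        --out run/reclassified.tsv
```

## Layout

| module | contents |
| --- | --- |
| `paravar.variants` | protein-change parsing, source merging, category assignment, summaries |
| `paravar.topology` | region tables, position→region assignment, distributions |
| `paravar.msa` | aligned FASTA/Clustal I/O, residue⇄column position maps |
| `paravar.conservation` | property table, column Cs, per-alignment profiles |
| `paravar.annotation` | paralogue annotation transfer (`ParalogueAnnotation.fit()`) |
| `paravar.benchmark` | score orientation, AUC, thresholds (`PredictorBenchmark.fit()`) |
| `paravar.consensus` | consensus rule and reclassification table (`ConsensusReclassification.fit()`) |
| `paravar.simulate` | synthetic families, variant tables, score panels, scenario builders |
| `paravar.cli` | `paravar` command-line interface |

Methodological details, parameter defaults and known limitations are in
`docs/methods.md`.
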
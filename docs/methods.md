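# Methods

This note documents the models and procedures implemented in `paravar`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Dataset curation

Variants arrive as per-source TSV tables (`gene`, `change`, `label`, `af`,
`condition`) in four dialects named after the databases they emulate:
`clinvar`, `humsavar`, `ensembl`, `gnomad`. Protein changes use short
one-letter notation (`A180T`), 1-based protein coordinates throughout; no
transcript or genomic coordinates are handled.

Merging is on the identity `(gene, position, wt, mut)`; sources and
condition strings are unioned and the maximum reported allele frequency is
kept. Category assignment is a strict precedence:

1. **P/LP** — any row asserting `pathogenic`/`likely pathogenic`
   (ClinVar dialect, and only with a non-empty condition string, since an
   assertion without a named clinical condition is not a usable clinical
   claim) or `disease` (Humsavar/Ensembl dialects);
2. else **BENIGN** — allele frequency strictly above the threshold
   (default 1e-4). The boundary value itself is not benign;
3. else **VUS**.

A curated assertion outranks the frequency heuristic because a clinical
review carries more information than a population-frequency prior; the
(rare) conflicts are logged at INFO level rather than silently resolved.
When two sources disagree about the wild-type residue at a position, all
variants at that position are excluded and returned on
`BroadDataset.excluded` with a warning — a wt conflict means at least one
source used stale coordinates, and neither can be trusted.

Within-source duplicate rows collapse silently (exports routinely repeat
rows per transcript). Assembly iterates sources in sorted name order, so
the result is independent of the order in which tables are supplied.

The `ALL` category of the substitution statistics is the clinically
characterized subset (P/LP ∪ benign), not the full table including VUS;
rankings are sorted by descending count with an alphabetical tie-break for
determinism.

## Topology

Regions are non-overlapping, 1-based inclusive intervals with classes
{tm_segment, p_loop, linker, terminus, other}. The packaged
`cav12_regions.tsv` is a *reconstruction* of the Cav1.2 α1 topology
(UniProt Q13936-style: four repeat domains of six segments with S5/S6
P-loops, interdomain linkers, N/C termini over 2221 residues). The
published per-residue borders are not available at numeric precision, so
the reconstruction was fixed by requiring consistency with the full
36-row reference reclassification table (every variant's position falls
in its published region), which over-determines the borders far more than
the two obvious anchors (A180T in DI-S2/S3, A1617T in C-term). Users with
authoritative borders can supply their own table; all downstream code
takes the region set as an argument. Positions outside every region fall
into an explicit `unassigned` bucket so per-category counts always add up.

## Conservation score

Each of the 20 residues is described by ten binary property classes; the
packaged 20×10 table (`aa_properties.tsv`) is the Livingstone–Barton
rendering of the Taylor classification. The column score is

Cs = (number of properties whose presence/absence state is identical
across all counted residues) / 10.

Two consequences worth making explicit:

* a property **absent from every** counted residue counts as conserved
  (agreement on absence) — this is what makes an identical column score
  exactly 1.0;
* Cs depends only on the **set** of distinct residues present, so it is
  invariant under permutation and duplication — a deliberate property the
  tests check, and the reason Cs is insensitive to family size imbalance.

Gap handling is a genuine design choice the literature leaves open. The
default (`nongap`) scores the non-gap residues only; the `strict`
alternative treats any gap as breaking every property (a gapped column
scores 0.0). The default is the permissive reading: a deletion in one
distant paralogue should not erase conservation evidence carried by the
rest of the family. Cs is computed over all sequences present in the
alignment, not a per-position subset. An all-gap column has no defined
score and raises rather than returning a sentinel.

The support threshold is Cs > 0.3, strict, configurable.

## Paralogue annotation transfer

A paralogue P/LP variant at residue *i* maps through the alignment to the
target residue sharing its column, or to nothing when the target carries a
gap there. The transfer is **positional**: the target wild-type residue
may differ from the paralogue's, and the mutant residue is recorded but
never matched — the evidence is that the *position* is intolerant, not
that one specific substitution recurs. The variant's stated wild-type is
validated against the paralogue's ungapped sequence and a mismatch is an
error (it almost always means stale coordinates, e.g. a different
isoform).

The fitted results report three layers: every mapped variant, the distinct
target positions hit (many-to-one is common and expected), and — when the
target's existing categories are supplied — the cross-tabulation of mapped
positions over {P/LP, benign, VUS}, which is the bookkeeping shape used to
sanity-check the pipeline against published family-wide counts.

## Predictor benchmark

Positives are P/LP variants, negatives benign variants; VUS never enter.
Scores are first oriented so larger = more pathogenic (SIFT-style tools
are negated, thresholds transformed with them; orientation is an
involution). Per tool:

* **Missingness gate:** tools missing scores for ≥30 % (strict `<` to
  keep) of the labelled variants are dropped. Retained tools are
  evaluated on their own complete cases — per-tool complete-case analysis
  matches how sparse dbNSFP panels are used in practice, and an
  intersection-of-all-tools analysis would let the worst tool dictate the
  benchmark set. Per-tool `n` is reported so readers can see the subsets.
* **AUC** in the rank (Mann–Whitney) form with average ranks, which counts
  tied pairs ½ and equals the trapezoidal area under the ROC curve over
  all thresholds. Degenerate single-class inputs raise; 0.5 is never
  silently returned.
* **Threshold:** candidates are midpoints of consecutive distinct scores
  plus ±∞ sentinels; prediction is `score > t` (strict). The default
  criterion maximizes Youden's J; ties break toward the smallest
  threshold for determinism. A closest-to-top-left criterion is available
  (`criterion="topleft"`), and published per-tool thresholds can be used
  verbatim (`use_custom_thresholds=True`) so the consensus stage can run
  without re-deriving a threshold on the same data it will score.
* **Metrics:** sensitivity, specificity and raw (unweighted) accuracy.
  Accuracy is deliberately not class-balanced; with imbalanced classes it
  is bounded by the class-weighted mix of sensitivity and specificity,
  which the reader should keep in mind when comparing tools across
  different complete-case subsets. Zero-denominator metrics are NaN and
  flagged, not errors.

The packaged `tool_specs.tsv` carries orientation and published
family-optimized thresholds for the 16 commonly benchmarked tools
(ClinPred, REVEL, MetaLR, Eigen, MCap, PrimateAI, MetaSVM, FATHMM_XF,
SIFT, PROVEAN, CADD, MutationAssessor, Polyphen HVAR/HDIV, FATHMM,
MutationTaster).

## Consensus reclassification

Only VUS are eligible; P/LP and benign classifications are never touched.
The rule is the set intersection

putative P/LP = {tool score > threshold} ∩ {position paralogue-supported},

both inequalities strict. Unscored VUS keep status `VUS` with a
missing-score flag and can never be promoted — a deliberate asymmetry:
absence of a prediction is not evidence. One-line-of-evidence outcomes are
tagged (`VUS_TOOL_ONLY`, `VUS_PARALOGUE_ONLY`) so the two evidence sets
remain auditable. Promotion counts are monotone non-increasing in both
thresholds, and the output is independent of input order (calls are
sorted by position).

## Synthetic data

The generator produces the statistical structure the pipeline assumes,
with planted truth, at desk scale:

* **Family alignment** (`simulate_family`): a target plus up to 20
  paralogues named after the real voltage-gated channel family
  (CACNA1x/SCNxA/NALCN). Columns are designed invariant (30 %),
  property-conserved (40 %; substitutions within one physicochemical
  group such as {I,L,V} or {D,E}, giving Cs ≥ 0.8) or free (uniform over
  the 20 residues). Indels are confined to designated loop stretches
  (15 % of columns; per-paralogue deletion rate 0.10; 10 insertion
  columns where the target is gapped), so the target coordinate frame and
  region fixtures stay valid while gap handling is still exercised.
* **Variant tables** (`simulate_variants`): target P/LP planted at
  conserved positions, benign with AF drawn from (2e-4, 1e-2) — strictly
  above the 1e-4 rule — VUS elsewhere with occasional sub-threshold AFs,
  plus deliberate cross-source duplicates to exercise the precedence
  rules. Default target counts (22 P/LP, 21 benign, 309 VUS) mirror the
  composition reported for the real Cav1.2 curation. Paralogue P/LP
  variants are planted at a configurable number of VUS positions on
  conserved, gap-free columns (1–5 supporting variants each), defining
  the ground-truth supported set.
* **Scores** (`simulate_scores`): per tool, pathogenic variants draw from
  N(δ, σ²) and the rest from N(0, σ²), giving the closed-form
  AUC = Φ(δ/(σ√2)) used for calibration tests; missingness is MCAR at a
  per-tool rate; lower-is-pathogenic tools are emitted negated; a
  `bounded` family squashes scores through the normal CDF onto [0,1]
  (strictly increasing, so the closed-form AUC carries over — this is the
  bounded-score stand-in rather than a separately parameterized Beta
  model). Default deltas (2.66, 2.09, 1.90, 1.35, 0.58) span theoretical
  AUCs ≈0.97–0.66, the strong-to-weak range reported for real panels.
* **Streams:** family, variants and scores use three independent
  generators spawned from the master seed, so regenerating one artifact
  never perturbs another; a fixed seed makes the full chain
  byte-reproducible.

Scenario builders construct worked examples whose bookkeeping is fixed by
published counts taken as *inputs*: `variants_from_counts` realizes a
per-gene count table exactly; `planted_transfer_scenario` plants a
many-to-one variant→position mapping with a prescribed category split;
`consensus_scenario` builds a VUS set with prescribed tool-positive and
consensus-promoted counts around the packaged reference reclassification
table.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no phylogeny or substitution-rate matrix behind
the family (columns are i.i.d. given their design label), no linkage
between conservation and variant density beyond the planted positions, no
realistic ClinVar assertion semantics (review status, submitter conflict),
no correlated missingness or inter-tool score correlation (real
meta-predictors share training data; synthetic tools are independent given
the class), and no population structure behind allele frequencies.
Benchmarks on synthetic panels validate the *machinery* (orientation,
ranking, thresholds, bookkeeping), not any claim about how real tools rank
on real channels.

## Numerical choices and degenerate inputs

* Strict inequalities at all three decision boundaries (AF 1e-4, Cs 0.3,
  tool threshold), verified at the boundary values in tests.
* AUC uses average ranks (scipy `rankdata`), exact for ties; oracle tests
  compare against brute-force pairwise counting at `abs=1e-12`.
* Threshold candidates are midpoints, ±∞ sentinels included, smallest
  threshold wins ties.
* TSV readers use pandas' round-trip float parsing so write→read cycles
  preserve allele frequencies and scores bit-exactly.
* Empty categories yield empty rankings or all-zero tables, not errors;
  all-gap columns, single-class benchmarks, unknown sequence ids and
  malformed protein changes raise typed errors naming the offender.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own defaults: synthetic families of 12–21
sequences × 240–600 residues, variant sets of a few hundred, 200 random
oracle instances, and 2000 scores per class for Monte-Carlo calibration
(standard error of an AUC estimate at n = 2000/class is ≈0.006, well
inside the ±0.02 tolerance asserted).

## Known limitations

* Protein-level coordinates only; mapping from genomic VCF or between
  isoforms is out of scope, and wt-mismatch errors are the only guard
  against coordinate drift.
* The conservation score is the set-valued property score only; no
  entropy, rate4site or frequency-weighted alternatives, and no
  gap-fraction down-weighting beyond the two documented policies.
* The benchmark reports point estimates; AUC confidence intervals
  (DeLong) and cross-validated threshold selection are not implemented.
* The consensus stage intersects a single tool with paralogue support; no
  multi-tool voting or ACMG/AMP evidence-code aggregation.
* The packaged Cav1.2 region borders are reconstructed, not authoritative;
  analyses at segment-boundary resolution should supply curated borders.
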
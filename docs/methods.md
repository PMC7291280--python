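# Methods

## Screen model

A pooled toxicity-modifier screen measures the relative abundance of
barcoded deletion strains after growth under induction of one human kinase
per culture. Abundance is read out by Bar-seq: the 20-mer UPTAG barcode of
every strain is PCR-amplified with composite primers whose 3' halves are
the common barcode-flanking primers (forward `GATGTCCACGAGGTCTCT`, reverse
`GTCGACCTGCAGCGTACG`) and whose 5' halves carry a 6-mer indexing tag pair
identifying the kinase experiment. On the sequenced strand a read is

```
G · fwd-tag(6) · fwd-primer(18) · UPTAG(20) · rc(rev-primer)(18) · rc(rev-tag)(6) · G
```

## Read parsing and counting

The forward primer is used as an anchor. It is searched from offset 7
(one template base plus the tag) onward; the six bases 5' of the match are
the tag, the twenty bases 3' of it the barcode. Matching is exact by
default; an optional one-mismatch anchor budget selects the unique
minimal-distance offset and treats ties as failures, since an ambiguous
anchor cannot place the tag or barcode. The reverse tag is used when the
read reaches it and the reverse anchor verifies; otherwise demultiplexing
falls back to the forward tag alone, which must then be unique in the
sample sheet. Tag and barcode matching use Hamming distance with
configurable budgets (defaults 0; tags up to 1, barcodes up to 2). In all
cases a tie at the minimal distance is deliberately unassigned rather than
arbitrarily broken. Every failure mode (`no_anchor`, `ambiguous_tag`,
`ambiguous_barcode`, `unmatched_barcode`) is tallied per kinase so that
read totals always reconcile exactly; no read is silently dropped. Base
qualities are ignored by default (no quality filter is part of the
published procedure); counting is order-invariant.

## Normalization and calling

Counts are rescaled within each experiment by the mean count over strains,
making the per-experiment mean of the rescaled values exactly 1 and
cancelling sequencing depth (multiplying one experiment's counts by any
positive constant leaves all downstream Z-scores unchanged). Each strain's
rescaled profile is then standardized across the kinase experiments.
Choices the published description leaves open, and how this package
resolves them:

* **Standard deviation** — sample (n−1) by default, population optional
  (`CallingParams.sd_mode`). Sample sd is the conservative choice; the
  setting is recorded in the fit summary. Note an arithmetic consequence:
  with K experiments a sample-sd Z-score is bounded by (K−1)/√K, so with
  fewer than 6 experiments no score can exceed 1.96 at all — the
  threshold is only meaningful at roughly the study's scale of 28
  experiments.
* **Threshold semantics** — strict inequalities: Z exactly ±1.96 is a
  non-modifier.
* **Degenerate strains** (zero variance across experiments, e.g. absent
  from the pool) — Z is set to 0 and the strain flagged, keeping matrix
  shapes stable instead of dropping rows.
* **All-zero experiment columns** — rescaled to 0 with a warning.
* **Glucose (uninduced) controls** — the published statistic never uses
  them; if control columns are supplied they are rescaled for inspection
  but excluded from the across-experiment standardization. No pseudocount
  and no log transform are applied by default.

Calls are made per (strain, kinase) cell; calls for strains without a
catalog gene annotation keep the strain id as the gene name.

## Ortholog network

Suppressor calls are translated to human genes through a user-supplied
two-column yeast→human ortholog table (ortholog databases version-drift,
so the mapping is data, not code). Interactions are counted at the yeast
suppressor level — one per (kinase, yeast gene, human ortholog) triple —
which is the convention under which the per-kinase tallies sum to the
screen's total interaction count. The drawn graph deduplicates to one
edge per (kinase, human gene), retaining every contributing
(yeast gene, Z) pair as provenance, so collapsing can only decrease node
degree. Category subnetworks are induced subgraphs on the kinases plus the
partners whose single primary category label is selected; kinases that
lose all edges are removed. Category percentages are taken over the
annotated network members and sum to 100. Exports: edge TSV, SIF and
GraphML. Enrichment statistics and protein–protein interaction overlays
from proprietary databases are out of scope; the edge-type field leaves
room to merge such edges externally.

## Spot-assay consistency

Individual retests are summarised as 100·confirmed/tested per
(kinase, group), with the group figure being the **unweighted mean of the
per-kinase percentages** over kinases actually tested in that group —
this, not the pooled fraction, reproduces the reference table's group
averages (e.g. the suppressor group mean of 82.9 differs from the pooled
71/88). Kinases not tested in a group, or with no called enhancer, simply
contribute no row. Reported values are rounded half-up to one decimal at
output time only; internal arithmetic is exact.

## Synthetic screens

The generator emulates the screen's data-generating process:

* **Pool** — random 20-mer barcodes with pairwise Hamming distance ≥ 3
  (enforced by bounded rejection sampling), so a single sequencing error
  can never make one strain's barcode ambiguous with another's; distinct
  6-mer tag pairs per kinase.
* **Baseline abundance** — log2-normal across strains with standard
  deviation 0.5 (a realistic spread of deletion-pool fitness), drawn once
  and shared by all experiments, mirroring one pool transformed per
  kinase. This makes per-strain standardization across experiments the
  correct normalization axis.
* **Planted effects** — per (strain, kinase) cell, independent:
  suppressor with probability 2%, enhancer 1% (defaults), multiplying
  abundance by 2^±effect (default effect 2, i.e. 4-fold), followed by
  per-experiment renormalization.
* **Reads** — multinomial sampling of 100,000 reads per experiment
  (roughly 200× mean strain coverage, in line with pooled Bar-seq
  practice), then literal read assembly from the layout above, with
  optional i.i.d. substitution errors and constant base quality.

Default problem sizes (500 strains × 5 experiments) keep unit tests fast;
recovery analyses run at the study scale of 28 experiments, where the
threshold is attainable (see the sd bound above). All draws flow from one
seeded generator in a fixed order, so outputs are byte-reproducible.

What the simulator does *not* model — PCR jackpotting, transformation
bottlenecks (the real screen's ~50–100 transformants per kinase imply
coverage bottlenecks), indels, growth-curve dynamics, quality decay —
bounds what passing tests show: they validate the arithmetic and the
pipeline's bookkeeping on an idealized screen, not robustness to every
artefact of real libraries.

## Known limitations

* The fixed Z threshold controls no error rate: because per-strain
  standardization is scale-free, a fully neutral strain still has ~2–3%
  of its cells beyond |Z| = 1.96 at 28 experiments *regardless of depth or
  noise level*. At 2% planting this caps suppressor precision near
  0.6–0.7 even when recall is 1.0; the simulator's recovery report
  measures this directly. No multiple-testing correction is applied, by
  design fidelity to the screen's procedure.
* The statistic is relative across kinases: an effect common to all
  experiments (e.g. a universally protective deletion) is absorbed by the
  standardization and cannot be called — demonstrated by the saturated
  -suppression test.
* Enhancer recovery is weaker than suppressor recovery since strain
  depletion saturates at zero observed reads.
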
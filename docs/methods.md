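# Methods

## Problem and model

Fungal ITS amplicon studies assign each OTU a lineage over the seven ranks
Kingdom, Phylum, Class, Order, Family, Genus, Species using a reference
database and a classifier. The three widely used classifiers (the RDP naive
Bayesian classifier, UTAX, and SINTAX) disagree both in *power* (the
proportion of OTUs they assign at a rank) and occasionally in the names
they assign, and each reports a per-rank confidence in [0, 1] so low-quality
calls can be discarded at a cutoff.

`taxconsensus` merges the three filtered tables into one consensus table.
The merge is rank-wise: at each rank, the surviving calls are combined by

| calls present | names            | consensus                | rule id       |
|---------------|------------------|--------------------------|---------------|
| 3             | all identical    | that name                | `all-agree`   |
| 3             | two identical    | the repeated name        | `majority`    |
| 3             | all different    | highest confidence       | `score-break` |
| 2             | identical        | that name                | `majority`    |
| 2             | different        | highest confidence       | `score-break` |
| 1             | —                | that name                | `single`      |
| 0             | —                | unassigned               | `none`        |

Exact score ties in `score-break` are broken by a configurable source
priority (default RDP, SINTAX, UTAX); the order is arbitrary but pinned so
runs are reproducible. Because any single surviving call is adopted, the
per-rank consensus assigned count is at least each classifier's — this
dominance is the method's power gain, and it is a theorem of the rules, not
an empirical finding.

Confidence scores from the three classifiers are not on a common calibrated
scale (bootstrap support vs. posterior-like scores); `score-break` compares
them as raw numbers. This is a documented caveat, not a modelling claim.

## Filtering

Filtering precedes merging: a call below the cutoff is invisible to the
rules, so a classifier whose conflicting call failed the cutoff simply does
not vote. Filtering truncates hierarchically — scanning Kingdom to Species,
the first rank whose score falls below the cutoff is discarded together
with every deeper rank, because a child call under a rejected parent is
taxonomically meaningless. Raising the cutoff therefore never increases any
assigned count, and power is non-increasing from Kingdom to Species in any
filtered table.

Since ranks are merged independently, the consensus lineage can combine a
parent from one source with a child from another. When no single input
table contains that exact (parent, child) pair the record is flagged
chimeric in `combined_taxonomy.txt` and a warning is logged; the flag marks
records worth manual review, it does not alter the merge.

## Statistics

* **Power** at a rank: assigned OTUs / total OTUs.
* **Percent improvement** of the consensus over a classifier with `N`
  assigned OTUs: `100 * (1 - N / N_consensus)`, reported against both the
  best (max `N`) and worst (min `N`) classifier, optionally with sources
  excluded from the extremes; the raw ratio `100 * N / N_consensus` is
  carried alongside. The subtractive form is used because it is the one
  consistent with improvement being 0 when the best classifier matches the
  consensus count.
* **Agreement profile**: at each rank every OTU falls in exactly one of
  seven categories (3 identical / 3 with one unique / 3 all unique /
  2 identical / 2 unique / 1 classified, subdivided by source /
  unidentified); the categories partition the OTU set. The
  **differential-assignment rate** is the fraction of OTUs falling in a
  conflicting category (3-one-unique, 3-all-unique, 2-unique) at *any*
  rank; an OTU counts once however many ranks conflict, making it an
  OTU-level fraction.

## Reference-database formatting

The formatting stage turns a UNITE-style general FASTA release (pipe-
delimited headers with an accession, an `SH<digits>.<digits>FU` Species
Hypothesis code, and a `k__...;s__...` lineage) into classifier training
inputs. Header layouts vary across releases, so the lineage block is
located as the first field containing `k__` and the remaining fields are
treated position-tolerantly. Taxon names are sanitized to `[A-Za-z0-9_-]`
(other characters become underscores, runs collapse, ends are stripped);
species names claimed by more than one SH code get the sanitized SH code
suffixed so training sees one label per Species Hypothesis. Literal
`unidentified` payloads are treated as unassigned ranks by default
(configurable), so they cannot masquerade as taxon names downstream.

The RDP trainer needs a connected taxonomy tree, so lineages with an
internal gap (a named rank below an unassigned one) are bridged with
deterministic placeholder nodes `<parent>_unclassified_<rank>`; node ids
are assigned in first-seen order during an input-order walk, making the
tree file byte-reproducible. The k-mer classifiers use
`>seqid;tax=d:...,s:...;` headers with unassigned ranks omitted; writing
then re-parsing this dialect is the identity on lineages.

## Synthetic data

The generator emulates the comparative study design the tool targets —
datasets of 500 OTUs with known lineages — not real sequence data. A toy
taxonomy tree is drawn (default taxon counts 2/4/8/12/16/24/32 from Kingdom
to Species, each taxon with one uniformly drawn parent), each OTU's truth
is the rootward path of a uniformly drawn species, and each classifier
reports, per rank: no call with probability `dropout` (default 0.2,
truncating the lineage there — classifiers abstain hierarchically);
otherwise a wrong name with probability `error` (default 0.1), drawn from
the true taxon's siblings so wrong calls remain plausible and can agree
between classifiers, else the true name. Correct calls score uniform on
[0.85, 1.0]; wrong calls uniform on [0.55, 0.90], so the default 0.8 cutoff
removes most but not all of them — a generator whose errors were always
filtered would make accuracy checks vacuous. The default rates are chosen
to produce the qualitative regime the method addresses: near-complete
kingdom-level power decaying toward species level, with occasional
surviving conflicts.

All randomness flows from one integer seed through numpy `SeedSequence`
spawning (one stream for the tree/truth, one for classifier noise), so
fixtures, outputs, and the entire pipeline are bit-reproducible.

What the generator does *not* emulate: sequences, PCR/chimera artifacts,
classifier-specific biases, out-of-reference taxa, or correlated dropout
between classifiers. Passing tests therefore demonstrate the correctness
of the merging machinery and its invariants, not classifier behaviour on
real communities.

### A note on accuracy among assigned

On synthetic replicates the consensus accuracy-among-assigned is higher
than each single classifier's at every rank *on average* (differences of
about +0.02 at Kingdom shrinking to +0.003 at Species over 100 replicates
at the default settings). Strict per-replicate dominance at every rank
against every classifier does not hold, and cannot for any
coverage-increasing consensus: the consensus's additional assignments are
exactly the single-voter calls, whose per-OTU accuracy equals a single
classifier's, so at deep ranks the two accuracies are near-equal
proportions over different denominators and sampling noise decides the
sign of any one comparison. The dedicated test asserting strict dominance
documents this boundary and is expected to fail at these noise settings;
the power dominance test, by contrast, holds in every replicate by
construction.

## Numerical and formatting choices

* Cutoff comparison is strict (`score < cutoff` fails), so a call at
  exactly the cutoff survives — matching the classifiers' own convention
  of reporting calls *at* the threshold.
* OTU ids are normalized by stripping `;size=NN` abundance suffixes
  (abundance is deliberately unused) and tables are harmonized onto the
  lexicographically sorted union of ids, inserting fully unassigned rows
  for OTUs a classifier missed.
* Confidence values are serialized with four decimals in every dialect
  writer, which makes write -> parse -> write byte-identical.
* All output files are tab-delimited UTF-8 with LF endings; the run
  manifest contains no timestamps, so identical inputs and configuration
  give byte-identical output trees.
* Degenerate inputs: an empty reference FASTA is an error; a fully
  unassigned OTU is retained everywhere (it still counts in totals); a
  rank where the consensus assigned nothing has undefined improvement and
  is reported as absent rather than zero.

## Scale of the shipped checks

The shipped test suite and the reproduction script use the study-scale
fixture (500 OTUs per replicate; 100 replicates for invariant checks, 20
for the summary statistics; 1,000 small randomized fixtures for the
partition property). These sizes give stable statistics while keeping a
full run in the tens of seconds.

## Known limitations

* Exactly three classifiers: the rule table is ternary by design.
* Raw cross-classifier score comparison (above).
* The native output dialects are pinned grammars modelled on the
  classifiers' tabbed outputs; other ecosystems' taxonomy formats (QIIME,
  mothur) are not parsed.
* The placeholder-node naming scheme for gap lineages is this package's
  convention; other RDP-training pipelines may bridge gaps differently.
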
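# Methods

This note documents the models and procedures implemented in `eukbench`,
their assumptions and defaults, the design choices made where the design
was genuinely open, and what the synthetic generator does and does not
emulate.

## Label model and input normalization

All classifier outputs are collapsed to a three-way vocabulary
{`eukaryote`, `noneukaryote`, `unclassified`}. The task is binary
eukaryote identification; finer-grained tool outputs (bacteria, archaea,
organelle, plasmid, virus classes) map to `noneukaryote` through
per-dialect label maps that users can override at call time. Raw labels
outside a map are never dropped: they become `unclassified` with a
warning, so row counts are preserved. Reference-style tools (Kaiju, CAT)
simply emit no row for contigs without database hits; a missing
(contig, tool) pair is therefore read as an `unclassified` call. The CAT
dialect collapses lineages at the superkingdom rank; how sub-superkingdom
lineages should collapse is not standardized, which is exactly why the
map is editable.

## Hybrid ensemble classifier

Parameters (defaults): k-mer panel = (tiara, whokaryote,
deepmicrobefinder); reference tool = kaiju; minimum length for using a
reference call `min_len_ref_bp` = 1000 bp; minimum length for using the
k-mer vote `min_len_kmer_bp` = 3000 bp, with `min_len_ref_bp ≤
min_len_kmer_bp` enforced. The decision rule per contig:

1. length ≥ 1 kbp and the reference tool made a call → that call wins
   (`decided_by = reference`). This includes `noneukaryote` reference
   calls: downstream binning strategies depend on contigs being
   positively identified as non-eukaryotic, not only on eukaryote hits.
2. otherwise, length ≥ 3 kbp → majority vote of the k-mer panel, ties
   excluded: `unclassified` votes are discarded first, a strict majority
   of the remainder is required, and a tie (including a 1–1 split after
   one abstention) yields `unclassified`. No senior-tool tie-break is
   applied — ties are excluded, period.
3. otherwise `unclassified` (`decided_by = none`).

Consequences worth noting: contigs shorter than `min_len_ref_bp` are
never classified; raising `min_len_kmer_bp` can only move vote-decided
contigs to `unclassified`, never flip their label; and changing k-mer
votes never affects reference-decided contigs. These invariants are
property-tested.

## Mock-metagenome composition

Per sample, genome abundances are drawn i.i.d. `a_g ~ LogNormal(μ=1,
σ=2)` with μ, σ on the log scale — the standard parameterization and the
convention of community read simulators. The bp share of genome *g* is
`b_g = a_g · L_g` with `L_g` its total length. All eukaryotic abundances
are then multiplied by the single constant `c = r · Σ_prok b / Σ_euk b`
(default r = 0.05), which makes the realized eukaryote:prokaryote bp
ratio equal r *exactly in every sample* — a deliberate choice over
enforcing it in expectation, because the benchmark's imbalance is a study
condition, not a random variable. The rescaling leaves relative
abundances within each superkingdom untouched. Abundances are
renormalized to sum to one.

The default random catalog mirrors a 33-eukaryote / 216-prokaryote
benchmark collection, with eukaryotic genome sizes (10–50 Mbp) an order
of magnitude above prokaryotic ones (2–8 Mbp) and exponentially
distributed contig lengths (mean 100 kbp, min 5 kbp).

## Test fragments and emulated classifiers

Test contigs are fixed-length fragments (defaults 1, 3 and 5 kbp; 100
per genome per length) cut at uniformly random start positions from
source contigs at least as long as the target; the source contig is
chosen uniformly among eligible ones and fragments may overlap — with
100 fragments per genome, non-overlapping placement is not generally
feasible on small contigs. "100 per genome per length" (rather than 100
in total) keeps per-tool metric estimates stable. Genomes with no contig
long enough are skipped for that length with a warning.

Classifier behaviour is emulated by length-binned error profiles: on a
true eukaryote the tool answers `eukaryote` with probability
*sensitivity*, `unclassified` with probability *unclassified_rate*, and
`noneukaryote` otherwise; symmetrically via *specificity* for
non-eukaryotes. The unclassified rate is shared between classes within a
bin — a simplification; real reference tools skip eukaryotic contigs
more often than prokaryotic ones, which can be represented by giving the
two classes separate profiles if needed. The default panel has k-mer
tools whose accuracy rises with contig length (sensitivity 0.75–0.95)
and a reference-style tool that is nearly always right when it answers
but abstains on 40–50% of contigs.

What the generator does **not** emulate: read-level errors, assembly
chimerism and fragmentation biases, correlated errors between tools
trained on overlapping data, database contamination, and real sequence
composition. Passing benchmarks here therefore demonstrate correctness
of the decision logic and metrics under the declared error model, not
the field performance of any real tool.

## Classification benchmark

Scoring subsamples the labelled contig set to a eukaryote:prokaryote bp
ratio of 0.05 — the over-represented class (in bp, relative to the
target) is removed contig-by-contig in random order until the ratio
first crosses the target, leaving the realized ratio within one contig's
bp of it; the subsampling unit is the contig with a bp-weighted stopping
rule. Each of the default 100 repeats yields TP/FP/TN/FN (positive
class: eukaryote) and MCC, precision, recall; means and standard
deviations (ddof = 1) are reported. Any metric with a zero denominator
is reported as 0 with a degenerate flag rather than NaN, so repeats
remain averageable.

`unclassified` predictions are handled in two modes, reported side by
side where relevant: `as_negative` (default; an unrecovered eukaryotic
contig is a miss — the end-to-end view) and `exclude` (drop unclassified
contigs before counting — the view under which rarely-answering
reference tools score near-perfectly).

## Binning metrics

All metrics weight contigs by bp (the AMBER convention); contig-count
weighting is not the default anywhere. Eukaryotic bins are those with a
strict majority (> 50%) of bp from eukaryotic genomes. Purity of a bin
is its majority-genome bp share; completeness of a genome in a bin is
the genome's bp in that bin divided by the genome's bp **in the filtered
assembly** — not its full genome size, since fragments below the length
cutoff were never binning candidates. F1 is the harmonic mean, reported
either per recovered eukaryotic genome at its most complete bin or per
eukaryotic bin against its own majority genome (the latter variant is
not standardized elsewhere; both summaries are unweighted means). The
adjusted Rand index is computed on the genome × bin contingency table of
bp counts, excluding unbinned contigs (including them as singletons
changes values substantially; this exclusion matches AMBER). A
single-cell table returns 1 with a warning.

Input strategies: FULL (all contigs ≥ the length cutoff), EUK-only
(eukaryote-labelled only), OTHER-rem (eukaryote-labelled plus
unclassified). Cutoffs of 1, 1.5 and 3 kbp correspond to common binner
minimums; the cutoff applies in all three modes so the strategies nest.

## Community statistics

*Presence*: breadth of coverage ≥ 0.25, inclusive, per "at least 25% of
bases covered". *bp fractions*: present contigs weighted by mean depth ×
length (approximate mapped bp; assembled-length-only weighting available
via a flag), normalized per sample over {eukaryote, prokaryote, virus,
NA}; fractions sum to 1 wherever a sample has present contigs.
*Clustering*: k-means (k = 2, named clusters; k configurable) on
Nonpareil coverage and logit eukaryotic fraction, both z-scored; only
the fraction is logit-transformed. Zero fractions are replaced by half
the smallest nonzero fraction before the logit (fractions of exactly 1
symmetrically); the cluster with the lower mean eukaryotic fraction is
always named `deficient`, making the naming stable under k-means label
permutation. *Co-occurrence*: for each taxon pair, a one-tailed
hypergeometric enrichment p-value P(X ≥ x) for x co-presences given
prevalences K_A, K_B over N samples; edges at p < 0.05 with no
multiple-testing correction by default (a Benjamini–Hochberg option
exists but is off, matching the plain 0.05 threshold convention);
mutual-exclusion edges are out of scope. *Modules*: Leiden modularity
maximization (seeded) on the significant-edge graph; reported modules
have more than 10 members, though the full membership table partitions
every network node.

## Numerical and determinism choices

All randomness flows through `numpy.random.default_rng` seeds;
workflow-level seeds are spawned from one `SeedSequence` so stages are
independently reproducible. The end-to-end pipeline writes JSON with
sorted keys and floats rounded to 10 decimals, making reruns
byte-identical. The exact-ratio constraint is validated to relative
1e-12 (floating-point arithmetic, not an approximation of the model).
Hypergeometric p-values come from `scipy.stats.hypergeom.sf`; k-means
from scikit-learn; Leiden from `leidenalg` on `igraph` graphs.

## Problem sizes

The packaged workflow defaults (8 eukaryotic + 40 prokaryotic genomes,
15 samples, 30 fragments per genome per length, 100 subsampling repeats)
were chosen so a complete run finishes in seconds on one core while
keeping per-metric Monte-Carlo error well below the effects being
demonstrated; catalog-scale runs (33 + 216 genomes, 100 fragments) use
the same code paths and run in minutes.

## Known limitations

- Error profiles are independent across tools; real k-mer classifiers
  share training biases, so the ensemble's simulated gain is an upper
  bound on the correlated-error case.
- The shared unclassified rate per length bin cannot express
  class-asymmetric abstention within a single profile.
- The `all_bins` F1 variant and averaging conventions of external
  benchmarking tools vary by version; values here follow the definitions
  above and are not guaranteed to match any specific external tool's
  output.
- The co-occurrence test conditions on observed prevalences and assumes
  exchangeable samples; structured sampling designs (e.g. repeated sites)
  inflate significance.
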
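# Methods

This note documents the models and procedures implemented in `demeta`,
the defaults they use, the design choices made where the problem was
genuinely open, and what the synthetic-data tests do and do not show.

## Differential-expression calls

All analyses consume per-dataset DEA tables: per feature a log2 fold
change, a nominal p-value and an FDR-adjusted p-value. A feature is
called *up* iff `2^log2fc > min_abs_fc` and `p < max_p`, *down*
symmetrically for the reciprocal fold change, otherwise *non-DE*.
Defaults are a linear fold-change floor of 1.2 and a p ceiling of 0.05.
Both inequalities are strict: a feature sitting exactly on either
boundary is not called. Gene-level integration thresholds the
*nominal* p-value — the vote-counting consensus across datasets is
itself the guard against isolated false positives, and the corrected
per-dataset statistics are always carried through in the evidence
output — while miRNA integration uses the FDR-adjusted p-value
(`use_adjusted=True`).

Missing statistics (NaN) never satisfy a DE call; such features count
as detected but non-DE. Fold-change comparisons are performed on the
log2 scale against log2-converted cutoffs, so a value stored as
`log2(x)` lands exactly where linear `x` would.

Comparison labels follow a controlled `A_vs_B` vocabulary (also
`A vs B`), with an optional trailing `D<digits>` token on either
condition recording the sampling day (e.g. `BleomD14_vs_Ctrl`, day 14
of bleomycin treatment).

## Dataset star accreditation

Seven metrics summarise one dataset/comparison (detected count, DE
count, pro-fibrotic-panel representation as a *count*, the
low/intermediate/high fold-change bin triple, the up/down ratio, and
the p-value distribution areas). Choices the metric definitions leave
open:

* **p-value AUC** is the trapezoidal area under the empirical CDF on
  [0, 1], linearly interpolated through (0, 0), the sorted sample at
  heights i/n, and (1, 1). It is scale-free, bounded in [0, 1] and
  equals 0.5 under uniform p-values; larger values mean an excess of
  small p-values. An all-missing p-value vector makes the metric NaN
  and its star ineligible.
* **Up/down ratio** uses +1 pseudocounts, `(n_up+1)/(n_down+1)`, so a
  dataset with zero down-calls is still scoreable.
* **Fold-change bins** are computed over DE features only (the 1.2 bin
  floor coincides with the DE cutoff) with half-open boundaries:
  (1.2, 2), [2, 5), [5, ∞).

Datasets are grouped by species and technology; exclusively non-coding
collections always form their own groups, and grouping can optionally
include the comparison label (e.g. restricting to `IPF_vs_Ctrl`).
Within a group, each scalar metric component gets a closed band
`[quantile(q_lo), quantile(q_hi)]` with the default band (0.25, 0.75)
— the interquartile range — computed with linear interpolation between
order statistics (numpy's `method="linear"`). A dataset earns one star
per metric inside its band; the bin triple earns its single star only
when all three counts are inside theirs, preserving the 7-star
maximum. Groups with fewer than 3 members yield no distribution and
their members get an NA report: quantile bands over one or two points
are not meaningful. Whether the band is quantile-based or symmetric
about the median is configuration; the IQR default matches the
box-plot presentation conventional for these summaries.

## Vote-counting consensus

Given n same-species datasets and a support floor k (default ⌈n/2⌉,
"at least half"), a feature is consensus-up iff it is called up in ≥ k
datasets *and down in none* (the opposite-direction veto);
symmetrically for down. The consensus fold change averages the log2FC
of the supporting datasets only — averaging in non-significant values
would dilute the reported effect. Features absent from some tables
contribute neither support nor veto there, but k is always judged
against n so that the "out of n datasets" control stays predictable;
partially-observed features are logged.

Two structural properties hold and are property-tested: the consensus
set shrinks as k grows, and no feature is simultaneously consensus-up
and consensus-down. A third plausible-looking property does **not**
hold: tightening the DE cutoffs does not monotonically shrink the
consensus set, because a stricter cutoff can silence a weak
opposite-direction call and thereby release a veto, *adding* the
feature. This is an inherent consequence of the veto clause, not an
implementation artefact; the unit suite verifies that veto release is
the only route by which tightening can add a feature.

Cross-species integration applies the complete same-species rule
(including the veto) within each species, then pairs human and mouse
consensus genes of matching direction through the homology map after
strict 1:1 filtering (any gene appearing in more than one pair is
discarded with all its pairs). Consensus fold changes are reported per
species, not pooled — pooling effect sizes across species would imply
a comparability the data do not support. Exclusively non-coding
datasets are rejected from cross-species integration. miRNA–mRNA
integration reports exactly the (miRNA, target) pairs with opposite
consensus directions, the expected signature of miRNA repression.

Proteomic result tables can be integrated with the same machinery by
encoding the original publications' DE decisions in the table
statistics; no publication-specific re-thresholding is performed.

## Two-shell interaction networks

From a scored, undirected edge list (combined scores 0–1000), shell 1
holds at most 9 partners of the query with score strictly above 700,
ranked by score; shell 2 holds, per shell-1 protein, its 2 most
confident interactors excluding the query and shell-1 members, with
duplicates merged. The >700 floor applies to shell 1 only by default —
the high-confidence requirement attaches to the query's direct
partners — but an optional floor for shell 2 is exposed since the
convention varies. All table edges among included nodes are retained
(including shell-2–shell-2 edges), weighted by score. Score ties are
broken lexicographically by protein id, making construction fully
deterministic. Graph layout is out of scope; the weighted graph with
shell and label attributes is exported (TSV or GraphML) for any
renderer.

Node labels summarise the primary coding gene's DE calls across the
selected datasets: `Unknown` for unreviewed (TrEMBL-like) or
unannotated proteins; `NonDE` when no dataset calls the gene; a single
call, or two agreeing calls, keep their direction; two disagreeing
calls follow the *biggest* dataset (largest sample count, ties broken
by larger table size, then smallest dataset id); three or more calls
follow the most frequent direction, falling back to the biggest DE
dataset on a tie. "A couple" is read as exactly two DE datasets and
"multiple" as three or more. For proteins coding several genes the
first-listed (primary) gene is used.

## Co-expression subnetworks

WGCNA fitting is upstream; the inputs are a gene→module assignment,
per-gene module membership (MM) and gene significance (GS), and the
topological overlap matrix (TOM). Around a query gene, module members
with MM and GS strictly above the module's 60th percentiles (linear
interpolation, module-local) are retained together with the query;
edges join retained pairs with TOM strictly above the 75th percentile
of the module's off-diagonal TOM values; zero-degree non-query genes
are dropped (the query is the only node allowed to be edge-less).
Percentile 0 is interpreted as "no filter" so the whole module is
retained — a strict cut at the 0th percentile would arbitrarily drop
the minimum-ranked gene. Both the filtered graph and a maximum-TOM
spanning forest (Kruskal on weight = TOM, equivalent to a minimum
spanning forest under the 1−TOM distance) are emitted, since the
spanning structure is primarily a layout aid.

## Synthetic data

The generator emulates a collection of harmonised DEA tables: null
features draw Uniform(0, 1) nominal p-values and N(0, 0.2²) log2 fold
changes; planted features share one direction with per-dataset log2FC
~ N(±2, 0.3²) and p ~ Beta(0.1, 1), a standard left-skewed alternative
model; adjusted p-values are Benjamini–Hochberg within each table.
Defaults are 4 datasets × 2000 features with 5% planted, sample sizes
uniform on 6–20. Companion generators produce scored interactomes
(uniform integer scores on [1, 1000], planted unreviewed and
multi-gene annotations), positional homology maps with optional
planted one-to-many entries, random miRNA target maps, pro-fibrotic
panels drawn from the feature universe, and block-structured module
data (TOM uniform on (0.5, 0.9) within modules, (0, 0.2) between, MM
and GS uniform with almost-surely distinct ranks).

What this does not emulate: platform-specific microarray noise,
RNA-seq count distributions, correlated genes, batch effects, or
realistic effect-size spectra. Passing tests therefore demonstrate
that the *rules* are implemented exactly (against enumeration and
order-statistic oracles) and that recovery behaves sensibly under a
clean planted-signal model — not that the pipeline's operating
characteristics transfer to any particular real collection. Under the
default planted model the per-dataset pass probability is ≈ 0.74
(dominated by P(p < 0.05) = 0.05^0.1), so 2-of-4 support recovers
≈ 94% of planted features; the acceptance suite checks ≥ 90% across
three seeds. All randomness flows from one seeded
`numpy.random.Generator`; fixed seeds reproduce outputs exactly on a
fixed numpy version.

## Numerical choices and problem sizes

Quantiles everywhere use linear interpolation between order statistics
and are tested against an independent order-statistic oracle. Interval
membership is closed on both ends; DE and percentile cuts are strict.
Exhaustive consensus checks enumerate all 3ⁿ call patterns for n ≤ 5;
network-construction oracles enumerate ≤ 12-protein interactomes;
spanning-forest optimality is checked by full spanning-tree
enumeration on ≤ 7-gene modules; null-calibration and planted-recovery
simulations use 2×10⁴ and 4×2000 feature tables respectively. These
sizes keep the whole suite and the acceptance script to a few seconds
while leaving every rule exercised through the same public API used on
real data.
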
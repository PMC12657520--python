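# Methods

This note documents the models, conventions and design choices behind
`mechanotf`, in the spirit of a package reference manual: what is
computed, under which assumptions, with which defaults, and what the
synthetic benchmarks do and do not demonstrate.

## Network model

The interactome is tripartite. *TF nodes* are transcriptional regulators
that also appear in the PPI table; regulators without PPI information
cannot anchor a signaling path and are logged as unusable. *Protein
nodes* are the remaining PPI proteins. *RNA nodes* represent prized
target transcripts and are namespaced (`GENE:rna`) so that a gene
occurring both as a PPI protein and as a DE target yields two distinct
nodes — without this, TF self-edges would corrupt the tripartite
topology. RNA nodes are only created for prized genes reachable from at
least one usable TF, so the graph never has dangling endpoints.

Edge costs are `-log(score/1000)` with the STRING integer confidence
score in (0, 1000]; a score of 1000 is free, and a score of 0 would be
infinitely expensive and is rejected. The log base (10 by default,
natural log optional) only rescales all PPI costs by a constant; since
TF→target edges cost zero, changing the base is equivalent to rescaling
the prize multiplier β, and both are exposed.

Prizes: a target gene must be significantly up-regulated under load
*and* significantly down-regulated under ERK inhibition (defaults:
`padj < 0.05`, strict sign conditions; both configurable because the
upstream DE calling is an input, not part of this package). Its prize is
the mean of the two absolute log2 fold changes. Protein/TF node values
are the load log2 fold changes of significantly up-regulated genes, zero
otherwise. Gene identifiers are assumed pre-harmonized to symbols; only
STRING-style species prefixes (`9606.`) are stripped.

## PCST solver

The objective is the unrooted Goemans–Williamson form: minimize the cost
of the selected forest's edges plus β times the prizes of the nodes left
out, with at most `num_components` trees (default 1, since the method's
output of interest is a single connected regulatory network). β defaults
to 1.

*Exact solver* (`mode="exact"`, ≤ 15 nodes): enumerate node subsets
smallest-first in lexicographic order; for each subset compute the
cheapest spanning forest within the allowed number of trees by Kruskal
stopped early (with non-negative costs, using as many trees as allowed
never hurts). Ties therefore resolve toward fewer nodes, then the
lexicographically smallest node-id set — outputs are bit-reproducible.

*Heuristic* (any size): candidate trees are the shortest-path trees
grown from every node (capped at `max_roots = 256` highest-prize roots
on larger graphs) plus the minimum spanning forest; each candidate is
strong-pruned by the classic bottom-up dynamic program (keep a child
branch iff its net worth exceeds its attaching-edge cost), and the best
net-worth subtree wins. For multiple allowed components, trees are
extracted greedily. A final leaf-pruning pass (drop leaves with
`β·prize < cost`) is idempotent and never increases the objective. The
heuristic is deterministic for a given instance; on the test suite's
random small instances it matches the exhaustive optimum in ≈98% of
cases and by construction never reports a better objective than the
optimum.

TF ranking counts, for each selected TF, the prized RNA nodes adjacent
through selected TF→target edges (primary sort), breaking ties by the
TF's own load log2FC magnitude, then alphabetically. Counting against
the full network instead of the solution is available via
`within_solution=False`. The motif-based enrichment of external tools is
deliberately not reproduced; `enrich_tf_targets` is a transparent
hypergeometric set-overlap test (upper tail, BH-adjusted) and labels its
output `method=hypergeometric`.

## Image analysis

All percentiles and quartiles — `i80/i20`, box summaries — use linear
interpolation between order statistics, the common scientific-computing
default; the convention changes `i80/i20` only in the third decimal but
is fixed package-wide for exactness of the tests.

`i80/i20` is the ratio of the 80th to the 20th percentile of the
within-nucleus intensity distribution; it is ≥ 1 by construction and
invariant under multiplicative intensity rescaling, so bit depth and
acquisition gain do not matter (original dtype is kept as metadata
only). Nuclei need ≥ 10 pixels. A zero 20th percentile is floored at the
smallest positive within-nucleus intensity; if no positive pixel exists
the metric is reported missing rather than infinite.

Otsu thresholding maximizes the between-class variance
`w0·w1·(μ0−μ1)²` exhaustively over cuts between the observed unique
values, taking the lowest maximizer on ties and rejecting constant
input. Thresholds are computed **per nucleus**, not globally:
illumination varies across fields and the within-nucleus histogram is
what separates heterochromatin from euchromatin. Foci are the
above-threshold connected components of at least `min_focus_area = 5`
px; nuclei below `min_nucleus_area = 100` px are discarded at
segmentation. Segmentation itself is standard: Gaussian smoothing
(σ = 2), Otsu foreground, hole filling, distance-transform watershed to
split touching nuclei.

The peripheral fraction erodes the nucleus mask by a disk of
`shell_width = 3` px; the shell is the nucleus minus its erosion, and
the metric is the fraction of focus pixels in the shell (shell and core
partition the focus pixels exactly). A shell wider than the nucleus
radius returns 1.0 with a warning. These three pixel parameters are
deliberate, tunable defaults — reasonable for ~20 px-radius nuclei at
the simulated scale — and are logged with every run.

Spheroid spread area is the filled union of the Otsu foreground after a
morphological closing with a 1-px-radius disk. The union — not the
largest object — is measured because outward-migrating cells are
typically disconnected from the core and are precisely the signal. The
closing radius is kept minimal: larger radii bridge nearby cells and
inflate the area in dense fields in a density-dependent way (a ~1%
effect on an isolated disc, but several percent between sweep settings).
The core is reported independently as the largest connected region
surviving an opening with an 8-px disk, which erases migrated-cell
blobs; no attempt is made to infer a spheroid "center". The cytoskeleton
area ratio is actin-positive area outside the core divided by core
area, Otsu-thresholded and therefore intensity-scale invariant. Areas
are in pixels unless a micron/pixel size is supplied.

## Screen statistics

Groups are compared with the unpaired two-tailed **pooled-variance**
Student t test (`df = n₁ + n₂ − 2`); a Welch option exists but is not
the default, matching the screen's stated test. Zero pooled variance is
an error, not a silent p = 1. Box summaries put whiskers at the extreme
data points within 1.5·IQR of the quartiles and list outliers
explicitly. Star categories use strict inequalities (`*** < 0.001`,
`** < 0.01`, `* < 0.05`, else ns). No multiple-testing correction is
applied across conditions — each inhibitor comparison stands alone, as
in the screen — but a BH-adjusted column is emitted alongside for
transparency. The unit of replication defaults to the table's rows
(per nucleus or per spheroid); `per_field=True` averages within fields
of view first and uses fields as replicates, since with thousands of
nuclei per group per-nucleus tests overstate the effective sample size.

## Synthetic benchmarks: what they emulate, and what they do not

*Network benchmark.* An upstream hub kinase connects to the planted TFs
through high-confidence PPI edges (scores ≥ 800) while background edges
are Erdős–Rényi (density 0.08) with scores uniform in [150, 700] — the
cost structure favors but does not force the planted cascade, so
recovery is informative. Defaults: 40 background proteins, 6 TFs of
which 3 planted, 5 targets per planted TF (a desk-scale analog of the
119-target screen), 200 background genes. Planted effects are
`±|N(2.0, 0.4)|` log2FC with `padj ~ U(1e-8, 1e-3)`; null genes are
`N(0, 0.3)` with uniform padj. Two deliberate departures from a raw
null: (i) the null is conditioned — by rejection resampling — so that no
background gene double-passes both DE filters by chance, keeping the
prized set exactly the planted one at every seed; (ii) a planted effect
size of zero degenerates to a pure-null benchmark (planted genes drawn
like background), so "no signal" means what it says. The benchmark does
not emulate STRING's evidence-channel structure, hub-degree skew of real
interactomes, or correlated DE noise; recovery rates on it bound solver
and bookkeeping correctness, not performance on real interactomes.

*Nucleus images.* Elliptical nuclei (radius 16–24 px) at 16-bit
intensities with smoothed texture, additive Gaussian noise, and disk
foci at 3× background contrast; focus centers fall in the outer radial
zone (82–95% of the radius) with probability equal to the peripheral
bias, else in the core (< 40%). Foci are kept ≥ 2 px apart so planted
counts equal connected-component counts. Not emulated: chromocenter
texture statistics, optical point-spread functions, z-structure —
hence focus-recovery rates here validate the measurement chain, not
biological sensitivity.

*Spheroid images.* A dense core disc (radius 50 px) plus small cell
blobs (radius 3–5 px, 60 cells) scattered uniformly in the annulus up to
the migration radius, rendered in both a DAPI-like and a slightly
broader actin-like channel. Ground-truth spread area is the exact union
mask. Migrated-cell density falls with radius at fixed cell count, so
the radius→area signal is strong in per-radius means but noisy per
replicate; monotonicity is accordingly asserted per seed on the coarse
{60, 90, 120} sweep and via rank correlation of per-radius means on the
finer grid.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run at desk scale by choice:
200 random ≤ 10-node instances for the exact-oracle comparison, 50
planted benchmarks (~60-node graphs) for recovery, 100 random nuclei for
the Otsu oracle, 20 seeds for the peripheral-bias sweep, 10 replicates ×
5 radii for migration, and 10,000 null simulations for t-test
calibration. Every stochastic step takes an explicit seed;
`scripts/acceptance.py` derives all of its child seeds from `--seed`.

## Packaged supplementary stand-ins

The original screen's supplementary tables are not redistributable
here, so the packaged files are synthetic stand-ins at the real sizes,
marked `synthetic` in their filenames: `table_s2_genes.synthetic.txt`
holds 119 symbols of which six are the published DEG-overlapping TFs
(NR4A1, CEBPD, KLF9, ZNF331, IRF1, NR6A1) and 113 are clearly synthetic
placeholders; `table1_inhibitors.synthetic.tsv` carries the screen's 15
real target genes with placeholder inhibitor names and concentrations
(only Stattic→STAT3 is a published name). They exercise the loaders and
size checks; they do not reconstruct the unpublished lists.

## Known limitations

- The heuristic solver carries no approximation guarantee; its quality
  is bounded empirically by the exact oracle on small instances only.
- Exact reproduction of the original screen's network (774 regulators,
  ~4.4M TF–target interactions, STRING v11.5) is out of scope: those
  inputs are taken as files, and any additional filtering applied to
  them upstream is unknown.
- Image metrics are 2-D; confocal stacks are collapsed by max/mean
  projection before analysis.
- The hypergeometric enrichment is a set-overlap stand-in, not a
  motif-recovery method; its results are not comparable to NES values
  from motif-based tools.
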
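# Methods

## The problem and the signal

A shotgun metagenome assembly is a bag of contigs with no record of which
species each came from.  Hi-C supplies that record: formaldehyde
crosslinking happens *before* cell lysis, so every proximity-ligation read
pair joins two loci from the same cell — and therefore the same species.
`hicdecon` turns a Hi-C library aligned to a draft assembly into a
species-level partition of the contigs.

## Pair filtering

Proximity-ligation junctions form at restriction-enzyme cut sites, so a
genuine Hi-C read should align near one.  A pair is kept only if **both**
ends lie within `site_window` bp (default 500, inclusive) of a site.
Conventions worth stating because they are not forced by the biology:

* A site's position is the offset of the motif's first base; the distance
  is |5′ alignment position − site first base|.  The 5′ position of a
  minus-strand alignment is its rightmost aligned base.
* Matching is exact and case-insensitive; IUPAC ambiguity codes never
  match, which keeps site counts (the normalization denominator)
  conservative.  Overlapping occurrences are each counted.  For
  non-palindromic motifs, reverse-complement occurrences are merged in;
  HindIII (`AAGCTT`) and NcoI (`CCATGG`) are palindromic, so both-strand
  and forward-only searches coincide.
* Pairs touching a contig with zero sites are dropped and counted
  separately: such contigs cannot produce a genuine signal and are
  reported `unclustered` with reason `zero_sites`.
* Coordinate-level duplicates are kept by default (`--dedup` opts in);
  duplicate marking belongs to the alignment pipeline upstream.

The filter report satisfies, exactly, kept + dropped_window +
dropped_zero_site = total, and downstream, edge raw links + intra-contig
tally + dropped = total.

## The contact graph

Nodes are site-bearing contigs; each inter-contig edge carries the raw
pair count and a normalized weight

    w(u, v) = links(u, v) / (sites(u) * sites(v)).

The product is used because the number of ligatable fragment-end
combinations between two contigs scales multiplicatively with their site
counts; a sum denominator is available (`normalization: sum`) for
comparison.  Intra-contig pairs are tallied for diagnostics but form no
edge.  Only the single largest connected component is clustered; other
components are small and join the unclustered remainder (reason
`outside_largest_component`).

## Hybrid clustering

**Jarvis–Patrick reweighting** (k = 100 by default).  Each node's
neighborhood NN(v) is its top-k graph neighbors ranked by normalized
weight, ties broken by contig id; nodes with fewer than k neighbors use
all of them, and a node is never its own neighbor.  An edge (u, v) is
removed when |NN(u) ∩ NN(v)| < `min_shared` (default 1, i.e. only
zero-overlap edges go) and otherwise reweighted to |NN(u) ∩ NN(v)| / k
(`jp_weight_mode: count` keeps the raw count).  Because neighborhoods
depend only on weight *ranks*, multiplying every link of one species by a
constant — which is what differing abundance or lysis efficiency does —
leaves the reweighted graph unchanged on separable data.  Neighbor lists
are computed from the site-normalized weights, not raw counts.  Nodes
isolated by edge removal are reported unclustered (reason `jp_isolated`)
rather than force-merged.  k should be on the order of the expected
per-species contig count; with far fewer contigs than k, every neighbor
(including spurious ones) enters every list and the shared-neighbor
contrast degrades, so small test communities use a smaller k.

**Average-linkage agglomeration.**  Starting from singletons, repeatedly
merge the cluster pair with maximal

    linkage(A, B) = (sum of reweighted edge weights between A and B) / (|A| |B|)

(absent edges contribute zero) until the target cluster count is reached
or no pair with positive linkage remains — disconnected parts are never
force-merged, so if the reweighted graph has more components than the
target, the extra components simply remain separate clusters.  Ties are
broken deterministically: each cluster is keyed by its lexicographically
smallest member id, and among equal linkages the pair with the least key
pair merges first.  The engine maintains per-cluster neighbor sums and a
lazy max-heap (entries invalidated by per-cluster generation counters),
so a 1000-node graph agglomerates in well under a second; an O(n³)
full-matrix reference implementation exists in the test suite and the two
are checked to produce identical merge sequences.

## Estimating the number of species

The estimator runs the agglomeration to exhaustion once and looks for
the largest relative gap in the dendrogram's linkage sequence.  With
L(N) the average linkage of the merge that reduces the clustering to N
clusters,

    N* = argmax_N  L(N) / L(N−1)

over the scan range; an N below which merging is impossible (the
reweighted graph ran out of connected cluster pairs) scores as an
infinite gap.  Rationale: while merges reunite fragments of one species,
successive linkages are of the same order — strong within-species
connectivity — whereas the first merge that fuses two species has
near-zero linkage, so the ratio spikes at exactly the species count (on
separable communities the gap spans several orders of magnitude).
Linkage is normalized by cluster-pair size, which matters: statistics
built on the *gains* of the intracluster link-enrichment curve E(N) (the
fraction of raw links inside clusters at the N-cluster stage) are
confounded by merge size — early merges of large half-species fragments
move as much link mass as the elbow itself, and occasional near-zero
gains from link-poor merges fake elbows under ratio rules.  E(N) is
still computed from the same trace and always emitted as the diagnostic
curve: it rises steeply while merges reunite species fragments and
flattens at the true count, so a user can inspect it and override the
prediction.

## Bootstrap stability

B times, the filtered pair table is resampled with replacement to its
original size, the graph rebuilt, and the clustering rerun at the same N.
Each original cluster is matched to the replicate cluster sharing the
greatest sequence-length overlap (ties by cluster name); a contig is
stable in a replicate when it lands in its original cluster's match.
Per-contig stability is the fraction of stable replicates; the summary
reports the mean over originally clustered contigs and the adjusted Rand
index of every replicate against the original partition (replicate
unclustered contigs enter the ARI as their own label).  All resampling
randomness flows from a single integer seed through one generator; no
global RNG state is touched, so results are byte-reproducible.

## Evaluation against truth

Truth tables allow multi-membership: a contig belongs to every species
whose reference it aligns to anywhere, so contigs shared between close
relatives carry several labels.  The purity matrix gives, per cluster and
species, the fraction of the cluster's total contig length on contigs
carrying that species' label; rows can exceed 1 under multi-membership.
Each cluster is called as its length-weighted argmax species (ties by
label order — length is the natural weight because the validation
heatmaps are length-fraction displays), and a contig is correct when its
cluster's call is in its own label set, so a shared contig is correct in
either parent's cluster.  Accuracy is reported length-weighted and
count-weighted, both over clustered contigs only (the unclustered
remainder is summarized separately, by reason).  Clustered contigs with
no truth entry are scored under an `unknown` label by default;
`include_unknown=False` excludes them from the denominators instead, so
both readings of "accuracy over placed sequence" are available.

## The simulator

The generator reproduces the statistics the method consumes and nothing
else:

* **Genomes** are i.i.d. uniform A/C/G/T, so a 6-bp motif occurs naturally
  every ~4.1 kb and roughly 9 % of 10-kb contigs carry no site — a
  realistic unclustered remainder.  No GC or codon structure is modeled:
  the method never reads composition.  Optionally, motif copies can be
  planted every `site_spacing` bp (jittered) to guarantee filterable
  coverage.
* **Contigs** are fixed `bin_size` bins of each replicon (default 10 kb,
  emulating reference genomes split into bins) or sequential lognormal
  fragments (emulating a real draft assembly).
* **Shared segments** are exact sequence copies between two species'
  first chromosomes; contigs overlapping the segment on either side carry
  both labels, reproducing the any-alignment truth semantics for
  near-identical relatives.  Mutation models are out of scope.
* **Pairs**: a cell's species is drawn ∝ abundance × lysis efficiency ×
  genome length.  Within a cell, a fraction `cis_fraction` of pairs are
  intra-replicon with separation ~ s^(−`cis_decay_exponent`) on
  [`min_separation`, replicon length), sampled by inverse CDF (the 1-kb
  floor avoids self-ligation artifacts); the rest join two replicons of
  the cell uniformly (a single-replicon cell falls back to two uniform
  positions).  A fraction `noise_fraction` of all pairs instead join two
  *different* species — spurious inter-cellular ligations.  Endpoints are
  snapped to within `site_window` of the nearest site on their replicon
  (disable with `snap_to_sites: false`), then mapped to (contig, offset).
* Genome synthesis and pair sampling use independent streams spawned from
  one seed, so two configs sharing a seed share genomes even when library
  parameters differ.

What passing on this data does **not** show: robustness to chimeric
assemblies, mappability artifacts, repeat-driven mis-alignments, uneven
coverage within a genome, or strain-level mixtures — none of which the
generator produces.  Conversely the distance-decay exponent, noise rate
and lysis spread are all configurable, so the separability regime is
explicit rather than accidental.

## Problem sizes used by tests and the acceptance script

The reference study conditions used throughout are 10 species × 1 Mb,
10-kb bins, 2×10⁵ pairs, cis fraction 0.9, noise fraction 0.01 — a
community at the same per-contig link depth as the designs that motivated
the method.  The test suite runs that configuration across 20 seeds
(homogeneous and 10×-lysis-spread variants); the acceptance script runs 3
seeds per variant plus 20 planted-graph estimator runs and a B=10
bootstrap, which keeps a full rerun under a minute while exercising every
stage.  CLI smoke tests use 3 species × 150 kb with k = 12 (see the k
guidance above).

## Known limitations

* Strain-level splitting within a species cluster is out of scope, as is
  ordering/orienting contigs within clusters (scaffolding).
* The estimator scans a user-set range and assumes the community is
  link-separable at some N in it; on graphs with no block structure the
  "elbow" is arbitrary (the curve is emitted for inspection).
* Read alignment and trimming are external; the package ingests
  name-grouped alignment records or `.pairs` tables.
* Zero-site contigs are unrecoverable by construction; they are reported,
  not rescued.
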
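# hicdecon

Species-level deconvolution of metagenome assemblies from Hi-C
proximity-ligation contacts.

A shotgun metagenome assembly yields contigs from every organism in a
mixed sample, with no record of which contig came from which species.
Hi-C read pairs carry exactly that record: crosslinking happens before
cell lysis, so the two ends of every proximity-ligation pair come from
the same cell.  `hicdecon` is for microbiome and metagenomics researchers
who have a draft assembly plus a Hi-C library and want one contig cluster
per community member — including unculturable species with no reference
genome.

## Method

1. **Filter.**  A pair is kept only if both ends align within 500 bp
   (inclusive, configurable) of a restriction site of the library's
   enzyme (e.g. HindIII `AAGCTT`, NcoI `CCATGG`); junctions form at cut
   sites, so reads far from any site are unlikely to be genuine
   ligation products.
2. **Graph.**  Contigs are nodes; an edge between contigs *u*, *v*
   carries weight *w(u,v) = links(u,v) / (sites(u) · sites(v))* — raw
   Hi-C link counts normalized by the contigs' restriction-site counts.
   Only the largest connected component is clustered.
3. **Jarvis–Patrick reweighting** (*k* = 100): each edge is rescored by
   the overlap of its endpoints' *k*-nearest-neighbor lists,
   |NN(u) ∩ NN(v)| / k, and edges with no shared neighbors are removed.
   Ranks are invariant to per-species link density, so clusters survive
   unequal abundances and lysis efficiencies.
4. **Average-linkage agglomeration** down to the expected species count
   *N*, with linkage(A,B) = Σ w(a,b) / (|A|·|B|).  If *N* is unknown it
   is predicted from the largest relative gap in the dendrogram's
   linkage sequence — within-species merges have strong linkage, the
   first cross-species merge almost none — and the intracluster link
   enrichment curve E(N) (fraction of links falling inside clusters at
   the N-cluster stage) is emitted for inspection.
5. **Evaluate** (optional, given a truth table): cluster × species
   length-fraction purity matrix, length- and count-weighted accuracy
   with multi-species contigs counted correct in any parent cluster, and
   a bootstrap stability score per contig.

A full synthetic community + Hi-C library simulator is included, so the
entire pipeline is testable offline.  See `docs/methods.md` for the
model, conventions, and limitations.

## Worked example

Simulate a 3-species community (150 kb each, 10-kb contigs, 30 000
pairs, 1 % inter-cellular noise) and deconvolve it:

```bash
cat > demo.yaml <<EOF
seed: 99
species:
  - {label: A, genome_length: 150000}
  - {label: B, genome_length: 150000}
  - {label: C, genome_length: 150000}
bin_size: 10000
n_pairs: 30000
cis_fraction: 0.9
noise_fraction: 0.01
EOF

hicdecon simulate -c demo.yaml -o demo
hicdecon run-all demo/sim.pairs demo/contigs.fasta -n 3 --k 12 \
         --truth demo/truth.tsv -o demo_out
```

which logs:

```
[hicdecon] filter: window=500 total=30000 kept=29312 dropped_window=688 dropped_zero_site=0
[hicdecon] graph: nodes=38 edges=434 intra_pairs=8774; largest component=38 nodes
[hicdecon] cluster: k=12 n_clusters=3 merges=35 clusters=3 unclustered=7
[hicdecon] unclustered: length=70000 zero-site fraction=1.0000 by-reason={'zero_sites': 70000}
[hicdecon] evaluate: length_weighted=1.0000 count_weighted=1.0000
```

Reading: of 45 contigs, 38 carry at least one `AAGCTT` site and enter the
graph; all 38 land in the correct species cluster (accuracy 1.0 by length
and by count).  The 7 contigs (70 kb) left unclustered all lack
restriction sites — with a 6-bp motif and ~4.1-kb expected spacing,
roughly 9 % of 10-kb contigs have none, and they cannot produce a Hi-C
signal by construction.  `demo_out/` holds the cluster table, the
normalized link table, the merge trace, and the purity matrix:

```
cluster      A    B    C
cluster_001  1.0  0.0  0.0
cluster_002  0.0  1.0  0.0
cluster_003  0.0  0.0  1.0
```

`--k 12` matches the neighborhood size to this tiny community (~13
contigs per species); at production scale the default `--k 100` applies.
With `-n auto`, `hicdecon estimate-k` prints the predicted species count
and writes the E(N) curve for inspection.

Library use mirrors the CLI:

```python
from hicdecon import SimConfig, SpeciesSpec, simulate_genomes, simulate_hic, deconvolve
from hicdecon.cluster import ClusterParams

cfg = SimConfig(seed=99, species=[SpeciesSpec(label=l, genome_length=150_000)
                                  for l in "ABC"],
                n_pairs=30_000, noise_fraction=0.01)
com = simulate_genomes(cfg)
pairs = simulate_hic(cfg, com)
result = deconvolve(com.contigs, pairs,
                    cluster_params=ClusterParams(k=12, n_clusters=3))
```

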
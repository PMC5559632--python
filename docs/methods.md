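# Methods

## Gene content as the unit of comparison

Phage genomes evolve by rampant horizontal exchange of gene-sized
segments, so a pair of genomes can be essentially identical over one half
and unalignable over the other. The pipeline therefore compares genomes by
*pham* membership — which protein families each genome carries — rather
than by nucleotide alignment. A genome's profile is the **set** of
distinct phams among its genes; within-genome duplicates collapse to
presence/absence.

### Pham construction

Genes are grouped into phams by the Jaccard index of their proteins'
amino-acid k-mer sets, with an edge between two genes when similarity
reaches a threshold and phams taken as connected components (single
linkage). Defaults: k = 4, threshold = 0.5, both configurable.

This metric is this package's own design. The published pham tables for
actinobacteriophage databases were built with profile-clustering tools
whose parameters are not described in a reproducible way; what downstream
stages need is only the contract — a deterministic partition of genes into
families of related proteins — and k-mer Jaccard with single linkage
satisfies it with an exactly checkable oracle (exhaustive pairwise
similarity + union-find). Consequences to keep in mind:

- Single linkage is deliberately transitive, mirroring phamily semantics:
  two dissimilar genes joined through an intermediate belong to one pham.
- A 4-mer Jaccard of 0.5 roughly corresponds to ≤ 10–15% scattered
  substitution divergence for proteins of length ≥ 100; the planted-family
  recovery tests run at 2–5% per-site divergence, comfortably inside it.
- Published pham partitions are **not** reproduced gene-for-gene; counts
  such as "11,035 phams from 77,955 genes" belong to the original
  database-scale analysis and are out of reach without those inputs.

Pham ids are assigned 1..N by each component's lexicographically smallest
gene id, so outputs are order-independent without a persistent registry.

### GCD and MaxGCDGap

For pham sets A and B with S = |A ∩ B| shared phams:

    GCD = 1 − (S/|A| + S/|B|) / 2

Averaging the two directed proportions keeps the measure symmetric for
genomes of unequal gene counts; GCD = 0 iff the sets are identical and 1
iff disjoint.

A phage's gap profile ranks its GCD against every other genome in the
dataset from largest to smallest and **appends the self-comparison value
0**; gaps are consecutive differences and MaxGCDGap is the largest gap.
Including the self value is a deliberate reading of the statistic's
intended behaviour: an isolated phage (all GCDs near 1) must show a
MaxGCDGap approaching 1, which only the final gap to self can produce —
without it, such a phage's gaps would all be near 0 and the statistic
would invert its meaning. Ties in GCD are ordered by genome id purely so
the reported flanking pair is stable; tie order cannot change any gap
value. MaxGCDGap values depend on the size and composition of the dataset
analysed and are not absolute quantities.

Band statistics count pairs with lo ≤ GCD ≤ hi (default 0.3–0.7,
inclusive at both ends — "between" is read inclusively as the reproducible
choice). Host-set sharing reports exclusive Venn regions: a pham counts
toward exactly the subset of hosts whose phage groups contain it, so
region counts sum to the total pham count.

## Cluster assignment

The clustering rule — same cluster iff a phage shares ≥ 35% of its genes
(GCD ≤ 0.65) with **at least one** other member — is exactly single
linkage, so clusters are connected components of the ≤-threshold graph and
a future genome can legitimately bridge two clusters. The averaged-
proportion reading of "35% shared" is the default because the threshold is
stated as a GCD value; a per-genome-denominator variant is available as a
switch. Labels C1, C2, … are ordered by smallest member id; components of
size 1 are singletons.

### ANI and subclusters

ANI is computed by a fragment method: the query is cut into consecutive
full windows (default 1,000 bp), each window is placed at its best
edit-distance location in the subject (infix alignment via edlib), windows
reaching 70% identity count as aligned, and ANI is the mean identity of
aligned windows. The measure is directional by construction (it depends on
which genome is fragmented); the pipeline always reports the mean of both
directions. Subclusters are connected components of the graph with edges
at mean ANI ≥ 95% and aligned fraction ≥ 0.5 — deliberate package
defaults, surfaced in config, since no published numeric cutoff exists; a
cluster whose ANI graph stays connected is reported undivided.

## Site finding

**Stoperator scanning.** Every window on either strand within a Hamming
distance of ≤ 2 substitutions (no indels) of the consensus is reported;
overlapping hits are all kept. The three published consensus strings
(Che12 `GGTGGTTGTCAAG`, Phlei `GCTTGGGTGTCAAG`, KatherineG
`GGGGATTGTCAAG`) ship verbatim as presets — including the 14-base Phlei
string, which is used unmodified. Minus-strand hits are reported at the
window's leftmost forward coordinate with the site read 5'→3' on the minus
strand. Intergenic annotation uses an any-overlap rule (a single base
inside any gene makes a hit genic) and by default annotates rather than
filters, since it is not established whether published scans were
restricted to intergenic space before or after matching.

**att cores.** Candidate attP/attB common cores are maximal exact common
substrings between phage and host, in both phage orientations, with
length ≥ 20; cores longer than 40 bp are flagged rather than truncated.
Exact matching is chosen because reported common cores are identical
segments and exactness admits an independent O(n·m) dynamic-programming
oracle; an optional post-pass tolerating 1 mismatch in cores ≥ 30 bp is
off by default. Implementation is seed-and-extend on a min-length host
index, reporting each maximal match once from its left edge. tRNA overlap
requires ≥ 1 bp intersection with a tRNA feature interval.

## Synthetic populations

The generator draws each genome's pham set from its cluster's core pool
(each core pham kept with probability `core_retention`), a single
accessory pool shared population-wide (each pham drawn with probability
`hgt_rate`), and ~Poisson(`orpham_rate`) private orphams. One shared
accessory pool (rather than pairwise pools) is the simplest mechanism that
moves the population from discrete clusters to a continuum with a single
knob. Defaults — 4 clusters × 5 genomes, 40 core phams/cluster, retention
0.9, pool 200, hgt 0.02, mutation 0.02 — define the well-separated regime
the recovery tests run in: expected within-cluster GCD ≈ 0.2, between ≈
0.99. Per-pham ancestor proteins are uniform-random over the 20 amino
acids, length 80–400; member genes get independently mutated copies.

Nucleotide genomes are uniform-random background (25% each base; GC skew
is deliberately not modelled) with motifs and att cores planted at
recorded positions. Background bases flanking an att plant are forced to
differ between phage and host so the planted core is maximal at exactly
its configured length. One global integer seed governs all randomness;
identical config + seed reproduces output bit-for-bit.

What passing tests on this generator do **not** show: behaviour on real
gene synteny, codon usage, %GC structure, shared sequence between
unrelated genes, or annotation noise. The generator validates the
statistics' contracts and the pipeline's plumbing, not biological
discovery performance.

## Packaged fixtures

`data/table1_gordonia.tsv` is a verbatim transcription of the published
79-phage profile table (name, host, cluster/subcluster, length, %GC,
genome-end type, accession); `data/table2_attB.tsv` transcribes the 13
predicted attB sites. Notes:

- Genome-end strings are parsed into typed values
  (`3′ 10-base ext.` → 3' extension of 10 bases; `1,182-bp DTR` → direct
  terminal repeat of 1,182 bp; `?` → unknown, retained, never dropped).
- attB rows printed with descending coordinates (minus-strand sites) are
  stored as (min, max) plus an orientation flag.
- The table's maximum GC is 68.6% while the accompanying text says 68.8%;
  the fixture transcribes the table and does not reconcile the text.
- A cluster counts as "subdivided into subclusters" when the records carry
  ≥ 2 distinct subcluster labels for it. Cluster A appears here only
  through its A15 members, so it is represented but not subdivided within
  this table, giving the expected count of 7 subdivided clusters.

## Numerical and scale choices

- All external coordinates are 1-based inclusive; any internal half-open
  arithmetic is invisible at interfaces.
- GC% excludes ambiguous bases from numerator and denominator; a stored GC
  within 0.15 of the recomputed value is accepted on load.
- Matrix TSV round-trips are exact to 10 decimal places
  (`%.12g` serialization); symmetry/zero-diagonal are validated with
  atol 1e-12.
- Test and acceptance problem sizes (populations of 20 genomes ≈ 800
  genes, 10–30 kb scan targets, 3–5 seeds per stochastic check) are chosen
  so each property is exercised well inside the regime where its
  expectation is sharp, while the whole suite stays fast enough to run on
  every change.

## Known limitations

- Pham construction is k-mer based: very short proteins (< k + ~10
  residues) and highly repetitive low-complexity proteins are grouped less
  reliably than globular ones.
- Fragment ANI underestimates identity for genomes with large
  rearrangements relative to fragment size, and is undefined when no
  fragment aligns.
- find_att_cores is exact-match; genuinely degenerate cores (as in
  serine-integrase systems, whose att sites share only a few identical
  bases) are out of scope by design.
- The cluster labels produced are structural (C1, C2, …); mapping them to
  published cluster letters requires the published assignments as input.
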
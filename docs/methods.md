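# Methods

This note documents the models and procedures implemented in `virago`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Scope and data model

The package covers the computational stages of a double-stranded-RNA
(dsRNA) virome survey of a trypanosomatid host: survey-level prevalence
bookkeeping, identification of viral genome segments from assembled
contigs, terminal-complementarity (panhandle) analysis of bunyavirus-like
segments, a tree-congruence test for reassortment between co-circulating
strains, and clone-level analysis of infection heterogeneity within
isolates. Read trimming, assembly, read mapping and homology searching
are upstream of the package and arrive as their outputs: contig FASTA,
per-base coverage TSV, and pre-aligned ORF FASTA.

All sequences are stored in the DNA alphabet (T, not U) even though the
viruses are RNA, matching deposited cDNA convention. Coordinates are
0-based half-open in memory and 1-based inclusive in files.

## Survey statistics

A survey table holds one row per isolate. Locality prevalence fractions
are summed (numerators and denominators separately), never averaged.
Viral identities can be co-detections of several leishbuvirus species in
one isolate (written `LBV1/2/4` in the source table); these expand to
the listed species. A bare `LBV` means the species could not be resolved
without sequence data; it is kept as the pseudo-species `LBV_unresolved`,
which counts toward the LBV family total but toward no individual
species. Detections seen only in sequencing data (no gel band) carry a
gel-negative flag and are included by default (`count_footnoted=True`),
matching the source table's totals row; they can be excluded to obtain
strictly gel-backed tallies.

Percentages are rounded half-up to the precision the survey reports:
integer percent for the two headline prevalences, one decimal for
per-virus prevalences. Raw fractions are always available alongside.

Data curation note: in one isolate (CZ-HM07) the row-level viral
identity of the source table disagreed by one tombus-like-virus
detection with the table's own totals row and with the same totals
restated twice elsewhere in the source; the bundled fixture follows the
repeatedly printed totals and leaves that row's identity empty (its gel
bands are retained, so the row remains dsRNA-positive). The row's gel
pattern (3.5 + 2.3 kb) is also the only one deviating from the canonical
3.5 + 2.2 kb pair.

## Segment identification

Candidate viral segments among assembled contigs are scored on three
criteria:

1. **length** — the contig length matches a dsRNA gel band. Bands are
   matched within a relative tolerance of 0.15 (gel sizing is coarse);
   ties break toward the larger band.
2. **coverage** — contig coverage tracks the band's visual brightness.
   Brightness is accepted as ranks, not intensities, avoiding
   densitometry assumptions; the Spearman correlation between contig
   RPKM and (inverted) brightness rank is computed over matched contigs
   and the criterion passes when the correlation reaches 0.5. Because
   RPKM is length-normalized, the informative contrast is *between*
   viruses of different abundance, so ranks should tie within a virus.
3. **terminus** — the contig carries the family-specific terminal
   sequence within 3 nt of either end, on either strand (assemblies may
   add or trim a few terminal bases). Orientation is recorded so
   contigs can be normalized to 5'-motif orientation.

RPKM is `reads / ((length/1000) * (total_mapped/1e6))`, computed in
exact arithmetic. The ORF finder scans all six frames for ATG-to-stop
readings under the standard code, reporting the first (longest) ATG per
stop-delimited stretch; protein lengths exclude the stop. Variable-site
percentages count alignment columns with more than one distinct non-gap
state (gap-only columns excluded from the denominator). Pairwise
identity counts matches over ungapped columns only — a stated
convention, since published identity figures rarely state theirs.

## Panhandle (terminal complementary sequence) analysis

The first `window` nucleotides of a segment are aligned globally against
the reverse complement of its last `window` nucleotides with an
affine-bulge dynamic program (Gotoh three-state). Defaults: window 30
(the duplex is described as 20–30 complementary nucleotides), match +1,
wobble +0.5, mismatch −1, bulge open −2, bulge extend −0.5; a bulge of
length L costs `open + (L−1)·extend`. Traceback ties break
pair > 5'-bulge > 3'-bulge, so the reported duplex is unique and
deterministic.

G·U wobble columns are scored at half weight, but symmetrically: the
unordered column pairs {G,A} and {T,C} count as wobble. Strictly
strand-physical wobble is not closed under reverse complement, and the
deposited orientation of segments varies, so orientation must not change
the score; the symmetric convention guarantees
`score(s) == score(revcomp(s))` exactly.

The terminal octamer is read from both termini and the better match to
the canonical `ACACAAAG` is reported with its Levenshtein distance.
Multi-branched loops and hairpins are deliberately not folded;
a complex internal structure surfaces as a long, low-scoring
interruption. Thermodynamic folding is out of scope.

Segment-size trajectories across clades report nucleotide and encoded
protein lengths in a supplied clade order and state whether each column
is monotonically decreasing — monotone reduction is reported, never
assumed; missing segments are recorded as absent.

## Phylogenetics and the reassortment test

The likelihood engine implements time-reversible nucleotide models (JC,
K80, GTR; rate matrices normalized to one expected substitution per site
per unit branch length), Felsenstein pruning over compressed site
patterns with per-node rescaling, coordinate-wise branch-length
optimization, and NNI hill climbing from a neighbor-joining start
(Saitou–Nei with deterministic tie-breaking by taxon label). Under JC
the per-branch site likelihood is affine in `exp(−4t/3)`, so each branch
update is a one-dimensional concave Newton problem; a dedicated kernel
(numba-compiled when available, plain numpy otherwise, identical
results) makes the bootstrap simulations below tractable. Branch lengths
are bounded to [1e-8, 10].

The reassortment test compares, over k partitions on a common taxon set:

* **unlinked** — independent topology and branch lengths per partition;
* **linked** — one shared topology, branch lengths still free per
  partition (whether the source analyses also linked branch lengths is
  unstated; free lengths are the weaker, safer null).

The statistic is `delta = 2(lnL_unlinked − lnL_linked) ≥ 0`; the
unlinked search always evaluates the linked topology per partition, so
the nesting inequality holds by construction plus optimization. A χ²
p-value with the heuristic df `(k−1)(n−3)` (internal branches freed per
extra topology) is reported with an explicit caveat — topology is not a
regular parameter — and the recommended measure is the parametric
bootstrap (default 200 replicates): simulate each partition under the
fitted linked model, recompute delta identically, and report the
fraction of replicate deltas at least as large as observed. Bayes-factor
comparison of the same hypotheses requires marginal likelihoods and is
out of scope; the likelihood-ratio half is implemented.

Calibration: with well-resolved trees every partition recovers the same
topology and delta sits exactly at 0, so the test never rejects — the
meaningful calibration regime is closely related strains with poorly
resolved internal structure (here terminal branches 0.03, internal
0.001 substitutions/site, i.e. ~2 expected substitutions per internal
branch at 2 kb), which is also what the surveyed virus strains look
like (≥93% pairwise identity). In that regime the measured bootstrap
type-I error at α = 0.05 is ~0.05–0.08. Power against planted
reassortment (two maximally discordant 6-taxon topologies, internal
branches 0.2) exceeds 0.95.

## Clone-level heterogeneity

Each clone is labeled by its exact virus subset; a screen is
heterogeneous when at least two distinct patterns occur. Per-virus
clone-positive fractions carry exact Clopper–Pearson 95% intervals, and
clone-level co-occurrence of the first virus pair is tested with
Fisher's exact test computed by explicit hypergeometric enumeration
(two-sided, summing tables no more probable than the observed one).
With eight clones the intervals are wide by design: the module reports
"no heterogeneity detected at n clones", never "pure". Degenerate 2×2
margins make the odds ratio undefined; a Haldane–Anscombe (+0.5)
corrected value is reported alongside.

## Synthetic data generator

The generator emulates the features the analysis depends on:

* **Genomes** — multi-segment genomes at the surveyed viruses' published
  segment sizes (e.g. the 3.5 + 2.2 kb two-segment tombus-like virus;
  the seven-segment, 21.5-kb satellite with the 5'-terminal
  `AAAGAAAAAAC` on every segment including the 1.27-kb one; the
  5.3 + 2.2 kb qinvirus whose ORFs encode 1679-, 375- and 231-aa
  proteins; leishbuvirus L/M/S layouts with canonical or variant
  octamers). Panhandle termini are planted by reverse-complementing the
  first `panhandle_len` nt onto the 3' end with single-nucleotide bulge
  insertions; every segment carries at least one ORF ≥ 300 nt planted
  behind a stop-codon guard so reported ORF lengths equal planted ones.
* **Strains** — co-circulating strains evolved segment-wise under JC
  along per-segment topologies (terminal branches = `mutation_rate`,
  internal = `internal_branch_scale`); mapping segments to different
  topologies plants reassortment, and the true trees are returned so
  test power is measurable against planted truth. A zero mutation rate
  returns exact copies. Trees whose deepest leaf pair exceeds 75% of
  the JC divergence ceiling (p > 0.5625) are rejected as saturated.
* **Coverage** — reads assigned multinomially to segments with weights
  abundance × length (so expected RPKM is proportional to abundance,
  reproducing the observed order-of-magnitude helper/satellite
  imbalances); per-base depth is uniform with Poisson noise. No
  read-level error model is simulated. Satellites are emitted only when
  their helper is present.
* **Surveys and clone screens** — default infection parameters are the
  surveyed rates (74% trypanosomatid prevalence; tombus-like virus in
  57.5% of tested isolates, leishbuviruses 12.3%, satellite 7.5%
  conditional on its helper, qinvirus 1.9%); clone screens draw i.i.d.
  from an explicit cell-mixture distribution, with an optional per-virus
  detection probability modeling bands below gel sensitivity.

A single integer seed fans out through per-operation independent streams
(seeded by operation label), so adding one generator call never perturbs
another's output, and identical (spec, seed) pairs are byte-identical.

What the generator does **not** emulate: sequencing error and chimeric
reads, assembly fragmentation, quasispecies variation, within-segment
recombination, and rate heterogeneity across sites. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated models, not robustness to real-data artifacts upstream of it.

## Numerical choices

* Branch-length optimization tolerance 1e-6 lnL; sweeps in post-order;
  per-branch Newton safeguarded by bisection; optimizer never returns a
  tree worse than its input.
* NNI candidates are screened with a single branch sweep; accepted moves
  are re-optimized fully. The linked-topology search screens each
  partition's ML topology and their NNI neighbours on the summed
  one-sweep score and fully optimizes the winner.
* NJ Q-criterion ties break toward the pair whose smallest member label
  sorts first; traceback and sweep orders are deterministic throughout.
* Pattern compression packs alignment columns into base-5 integer keys
  (up to 27 taxa), making compression a single integer sort.
* Band matching uses relative size difference; Spearman via ranks with
  ties handled by the standard mid-rank convention.
* Rounding of printed percentages is decimal half-up, not banker's.

## Problem sizes

The test suite and the acceptance script run the statistical
simulations at the sizes stated above: type-I calibration with 100 outer
replicates × 200 bootstrap replicates (k = 3 partitions, 6 strains,
2 kb segments), power with 50 replicates × 200 bootstraps, model-nesting
checks on 1000 random partition sets (5 taxa, 100 sites), property
checks on 500 random termini and all ≤5-taxon topologies, and
planted-truth segment recovery over 100 simulated isolates.

## Known limitations

* Only the likelihood-ratio half of the congruence analysis is
  implemented; Bayes factors are not.
* Models are JC/K80/GTR without rate heterogeneity by default; the
  source analyses used auto-selected models with codon partitioning,
  which is not replicated.
* The coverage criterion reduces gel brightness to ranks; a quantitative
  densitometry model is out of scope.
* Accession-based checks against deposited sequences require network
  access and are not part of the test suite; the same machinery is
  exercised on synthetic sequences built to the published sizes.
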
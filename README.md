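# virago

Analysis toolkit for double-stranded-RNA (dsRNA) virome surveys of
trypanosomatid parasites — prevalence and coinfection statistics,
viral genome-segment discovery from contigs, bunyavirus panhandle
(terminal complementarity) analysis, a tree-congruence test for
reassortment, and clone-level infection heterogeneity.

## The problem

Monoxenous trypanosomatids such as *Leptomonas pyrrhocoris* (a gut
parasite of the cosmopolitan firebug) can host a remarkable range of RNA
viruses at once: a two-segment tombus-like virus, a seven-segment
satellite virus that never appears without its helper, negative-sense
leishbuviruses with L/M/S segments, and a qin-like virus. Surveying such
a system raises recurring computational tasks that this package
implements as a tested, reusable library:

* **Survey statistics** — per-locality prevalence fractions summed into
  survey totals; per-virus prevalence among positive and among tested
  isolates; coinfection structure; satellite/helper containment.
* **Segment identification** — a contig is called as a viral segment
  when (i) its length matches a dsRNA gel band, (ii) its coverage
  (RPKM = reads per kilobase per million mapped) tracks the band's
  brightness, and (iii) it carries the family-specific terminal
  sequence, e.g. the 5'-terminal `AAAGAAAAAAC` that recruits all seven
  satellite-virus segments.
* **Panhandle analysis** — a global affine-bulge dynamic program aligns
  a segment's 5' terminus against the reverse complement of its 3'
  terminus (the polymerase-binding "panhandle" of 20–30 complementary
  nucleotides with kinks and bulges) and classifies the conserved
  terminal octamer against the canonical `ACACAAAG`.
* **Reassortment test** — per-segment maximum-likelihood trees
  (Felsenstein pruning, NJ + NNI search) compared between a linked model
  (one shared topology) and an unlinked one (free topology per segment):
  `delta = 2(lnL_unlinked − lnL_linked)`, with a heuristic χ² reference
  and a parametric bootstrap as the recommended calibration.
* **Clone screens** — exact small-sample statistics (Clopper–Pearson
  intervals, Fisher's exact test by hypergeometric enumeration) for
  eight-clone presence/absence screens of mixed isolates.
* **Synthetic data** — a generator that emulates all of the above
  (segmented genomes with planted termini and ORFs, strains with planted
  reassortment, multinomial read coverage, surveys, clone screens) so
  every stage is testable against planted truth.

The bundled survey table of 106 isolate records from 27 European
localities ships with the package (`virago.bundled_survey_path()`).

## A worked example

```python
import virago

table = virago.read_survey(virago.bundled_survey_path())
rep = virago.prevalence_summary(table)
print(rep.formatted()["trypanosomatid"])   # 374/508 (74%)
print(rep.formatted()["dsRNA"])            # 64/106 (60%)
print(rep.virus_counts["TLV"])             # (61, 95.3, 57.5)
print(virago.coinfection_profile(table).max_species)   # 5
```

The tombus-like virus appears in 61 isolates — 95.3% of the 64
dsRNA-positive cultures and 57.5% of all 106 tested — and one isolate
carries five viral species at once. Running
`python examples/reassortment_test.py` simulates six strains of a
two-segment virus whose segments evolved along maximally discordant
topologies and prints

```
2*delta-lnL = 2637.9  (df heuristic 3)
chi^2 p = 0.00e+00;  bootstrap p = 0.0
```

a discordance none of 200 concordant bootstrap replicates can match:
the reassortment signature. The other scripts under `examples/` show
segment discovery from coverage, panhandle/octamer comparison across
leishbuvirus clades, clone-screen analysis, and the survey tallies.

A thin command-line wrapper is included:

```bash
virago survey                       # tallies from the bundled table
virago segments --contigs c.fasta --coverage c.tsv --bands "3.5,2.2" \
    --motif AAAGAAAAAAC
virago panhandle --fasta segments.fasta --window 30
virago congruence --partitions orf1.fasta orf2.fasta --bootstrap 200 --seed 7
virago clones --matrix screen.tsv
```

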
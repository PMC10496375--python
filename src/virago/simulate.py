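"""Synthetic data with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here: segmented viral
genomes with family-specific terminal motifs and complementary
(panhandle) termini, co-circulating strains evolved segment-wise along
per-segment tree topologies (planted reassortment), per-isolate read
coverage with order-of-magnitude abundance differences, survey tables,
and clone screens drawn from cell-mixture models.

Sequences use the DNA alphabet (T, not U) although the viruses are RNA;
deposited cDNA sequences follow the same convention.

Randomness: a single integer seed fans out into independent per-operation
streams keyed by operation name, so adding one generator call does not
perturb the output of the others.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .genome import ORF, Segment, SegmentedGenome, revcomp
from .segments import Contig, ContigSet
from .survey import IsolateRecord, SurveyTable
from .phylo.likelihood import make_model, simulate_alignment
from .phylo.tree import Tree, random_topology

NT = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream derived from (seed, operation label)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


# -- specs -------------------------------------------------------------------

@dataclass(frozen=True)
class VirusSpec:
    """Blueprint of a segmented virus for the generator.

    ``terminal_octamer`` is the conserved 8-nt bunyavirus-style terminal
    sequence; ``terminal_motif_5p`` is an arbitrary-length 5'-terminal
    motif shared by all segments (the Ostravirus-style signature).
    ``panhandle_len`` first-nucleotides of each segment are reverse-
    complemented onto its 3' end, with ``n_bulges`` single-nucleotide
    unpaired insertions planted on the 3' side. ``orf_plan`` optionally
    pins the protein lengths (aa) planted per segment.
    """

    name: str
    n_segments: int
    segment_lengths: tuple[int, ...]
    terminal_octamer: str | None = None
    panhandle_len: int = 0
    n_bulges: int = 0
    satellite_of: str | None = None
    terminal_motif_5p: str | None = None
    segment_names: tuple[str, ...] | None = None
    orf_plan: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 1 or len(self.segment_lengths) != self.n_segments:
            raise ValueError("segment_lengths must list one length per segment")
        if not 0 <= self.panhandle_len <= 30:
            raise ValueError("panhandle_len must be in [0, 30]")
        if self.n_bulges < 0:
            raise ValueError("n_bulges must be >= 0")
        if self.terminal_octamer is not None:
            oct_ = self.terminal_octamer.upper().replace("U", "T")
            if len(oct_) != 8 or set(oct_) - set("ACGT"):
                raise ValueError("terminal_octamer must be 8 nt over ACGT/U")
        for L in self.segment_lengths:
            if L < 2 * (self.panhandle_len + 8):
                raise ValueError(
                    f"virus {self.name}: segment of {L} nt cannot carry two "
                    f"{self.panhandle_len + 8}-nt termini; need >= "
                    f"{2 * (self.panhandle_len + 8)} nt"
                )

    def seg_name(self, i: int) -> str:
        if self.segment_names:
            return self.segment_names[i]
        return f"seg{i + 1}"


@dataclass(frozen=True)
class ReassortmentSpec:
    """Co-circulating strains with per-segment tree topologies.

    Terminal branches have length ``mutation_rate`` and internal branches
    ``internal_branch_scale`` (both in expected substitutions/site).
    Reassortment is planted by mapping at least two segments to different
    topology labels.
    """

    n_strains: int
    per_segment_topologies: dict[str, str]
    internal_branch_scale: float = 0.2
    mutation_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("need at least two strains")
        if self.internal_branch_scale < 0 or self.mutation_rate < 0:
            raise ValueError("branch scales must be non-negative")


@dataclass(frozen=True)
class IsolateSimSpec:
    """One simulated isolate: which viruses it carries, their relative
    abundances, and the mixture of cell infection patterns it contains."""

    viruses_present: frozenset[str]
    abundance: dict[str, float] = field(default_factory=dict)
    cell_mixture: dict[tuple[str, ...], float] = field(default_factory=dict)
    total_reads: int = 5_000_000

    def __post_init__(self) -> None:
        for v in self.viruses_present:
            if self.abundance.get(v, 1.0) <= 0:
                raise ValueError(f"abundance of {v} must be strictly positive")
        if self.cell_mixture:
            tot = sum(self.cell_mixture.values())
            if abs(tot - 1.0) > 1e-9 or any(
                p < 0 or p > 1 for p in self.cell_mixture.values()
            ):
                raise ValueError("cell_mixture proportions must sum to 1")
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")


# -- study-condition virus blueprints ----------------------------------------
# Segment sizes follow the gel band patterns and genome schemes of the
# surveyed viruses; octamers and motifs are the family-specific terminal
# sequences.

TLV_SPEC = VirusSpec(
    name="TLV", n_segments=2, segment_lengths=(3500, 2200),
)
OSTRAVIRUS_SPEC = VirusSpec(
    name="OV", n_segments=7,
    segment_lengths=(5000, 4200, 4000, 3000, 2400, 1600, 1270),
    terminal_motif_5p="AAAGAAAAAAC", satellite_of="TLV",
)
QINVIRUS_SPEC = VirusSpec(
    name="QIN", n_segments=2, segment_lengths=(5300, 2200),
    orf_plan=((1679,), (375, 231)),
)
LBV1_SPEC = VirusSpec(
    name="LBV1", n_segments=2, segment_lengths=(6200, 800),
    segment_names=("L", "S"), terminal_octamer="AAGAAACA",
    panhandle_len=22, n_bulges=1,
)
LBV2_SPEC = VirusSpec(
    name="LBV2", n_segments=2, segment_lengths=(6200, 800),
    segment_names=("L", "S"), terminal_octamer="AAGAAACA",
    panhandle_len=22, n_bulges=1,
)
LBV3_SPEC = VirusSpec(
    name="LBV3", n_segments=3, segment_lengths=(6200, 1900, 1500),
    segment_names=("L", "M", "S"), terminal_octamer="ACACAAAG",
    panhandle_len=24, n_bulges=3,
)
LBV4_SPEC = VirusSpec(
    name="LBV4", n_segments=3, segment_lengths=(6300, 2900, 1000),
    segment_names=("L", "M", "S"), terminal_octamer="ACACAAAG",
    panhandle_len=26, n_bulges=1,
)
#: crown-group leishbuvirus with fully reduced M and S segments
CROWN_LBV_SPEC = VirusSpec(
    name="LBVcrown", n_segments=3, segment_lengths=(6000, 1300, 700),
    segment_names=("L", "M", "S"), terminal_octamer="ACACAAAG",
    panhandle_len=24, n_bulges=1,
)

STUDY_VIRUSES = {
    s.name: s
    for s in (TLV_SPEC, OSTRAVIRUS_SPEC, QINVIRUS_SPEC, LBV1_SPEC,
              LBV2_SPEC, LBV3_SPEC, LBV4_SPEC, CROWN_LBV_SPEC)
}


# -- genome generation -------------------------------------------------------

def _codon_string(n: int, rng) -> str:
    idx = rng.integers(0, len(_CODONS), size=n)
    return "".join(_CODONS[i] for i in idx)


def _plant_orf_block(aa_lengths: tuple[int, ...], rng) -> tuple[str, list[int]]:
    """TAA guard + consecutive ATG..stop ORFs of the requested protein
    lengths; returns the block and the aa lengths (for annotation)."""
    parts = ["TAA"]
    for aa in aa_lengths:
        parts.append("ATG" + _codon_string(aa - 1, rng) + "TAA")
    return "".join(parts), list(aa_lengths)


def gen_virus(spec: VirusSpec, seed: int) -> SegmentedGenome:
    """Realize a virus blueprint into concrete segment sequences.

    Each segment starts with the terminal motif/octamer (when specified),
    carries a 3' terminus reverse-complementary to its first
    ``panhandle_len`` nt except at the planted bulges, and contains at
    least one ORF of >= 300 nt. Identical (spec, seed) give identical
    output.
    """
    rng = stream(seed, f"gen_virus/{spec.name}")
    segments = []
    for i, L in enumerate(spec.segment_lengths):
        seg_rng = np.random.default_rng(rng.integers(2**31))
        prefix = ""
        if spec.terminal_motif_5p:
            prefix = spec.terminal_motif_5p.upper().replace("U", "T")
        elif spec.terminal_octamer:
            prefix = spec.terminal_octamer.upper().replace("U", "T")
        p = spec.panhandle_len

        seq = list("".join(NT[seg_rng.integers(0, 4, size=L)]))
        seq[: len(prefix)] = list(prefix)

        # complementary 3' terminus with planted single-nt bulge insertions
        tail_src = "".join(seq[:p])
        tail = list(revcomp(tail_src))
        if p > 0 and spec.n_bulges > 0:
            if p < 2 * (spec.n_bulges + 2):
                raise ValueError(
                    f"virus {spec.name} segment {spec.seg_name(i)}: panhandle "
                    f"of {p} nt too short for {spec.n_bulges} bulges"
                )
            sites = 2 + seg_rng.choice(
                np.arange(0, p - 4, 2), size=spec.n_bulges, replace=False
            )
            for pos in sorted(sites, reverse=True):
                tail.insert(int(pos), str(NT[seg_rng.integers(0, 4)]))
        tail_len = len(tail)

        # plant the ORF block between the termini
        margin5 = max(p, len(prefix)) + 3
        interior = L - margin5 - tail_len - 3
        plan = (
            spec.orf_plan[i]
            if spec.orf_plan is not None
            else (max(100, int(interior * 0.6) // 3),)
        )
        block, aa_lens = _plant_orf_block(tuple(plan), seg_rng)
        if len(block) > interior:
            raise ValueError(
                f"virus {spec.name} segment {spec.seg_name(i)}: {L} nt too "
                f"short to host ORFs of {plan} aa plus {p}-nt termini; need "
                f">= {len(block) + margin5 + tail_len + 3} nt"
            )
        start = margin5
        seq[start : start + len(block)] = list(block)
        if tail_len:
            seq[-tail_len:] = tail
        sequence = "".join(seq)

        orfs = []
        at = start + 3  # skip the TAA guard
        for aa in aa_lens:
            orfs.append(ORF(start=at, end=at + 3 * (aa + 1), frame=at % 3,
                            strand="+", aa_len=aa))
            at += 3 * (aa + 1)
        segments.append(Segment(name=spec.seg_name(i), sequence=sequence,
                                orfs=orfs))
    return SegmentedGenome(
        name=spec.name,
        segments=segments,
        meta={"satellite_of": spec.satellite_of, "spec": spec, "seed": seed},
    )


# -- strain evolution / reassortment -----------------------------------------

def gen_strains(genome: SegmentedGenome, rspec: ReassortmentSpec, seed: int,
                topologies: dict[str, Tree] | None = None
                ) -> tuple[dict[str, SegmentedGenome], dict[str, Tree]]:
    """Evolve co-circulating strains segment-wise under Jukes-Cantor.

    Each segment follows the topology its label maps to; with at least
    two distinct labels this plants a reassortment signal. Returns the
    strains and the true per-segment trees (so test power against the
    planted truth is measurable). ``mutation_rate == 0`` returns exact
    copies.
    """
    strains = [f"{genome.name}_st{i + 1}" for i in range(rspec.n_strains)]
    labels = sorted(set(rspec.per_segment_topologies.values()))
    if topologies is None:
        topologies = {}
        for lab in labels:
            rng = stream(seed, f"gen_strains/topology/{lab}")
            topologies[lab] = random_topology(
                strains, rng,
                internal_length=rspec.internal_branch_scale,
                terminal_length=rspec.mutation_rate,
            )
    missing = [s.name for s in genome.segments
               if s.name not in rspec.per_segment_topologies]
    if missing:
        raise ValueError(f"segments without topology label: {missing}")

    if rspec.mutation_rate == 0:
        out = {
            st: SegmentedGenome(
                name=st,
                segments=[Segment(s.name, s.sequence, list(s.orfs))
                          for s in genome.segments],
                meta=dict(genome.meta),
            )
            for st in strains
        }
        seg_trees = {s.name: topologies[rspec.per_segment_topologies[s.name]]
                     for s in genome.segments}
        return out, seg_trees

    # saturation guard: JC divergence approaches 0.75 asymptotically;
    # reject trees whose deepest leaf pair is expected beyond 75% of that
    # ceiling (effectively unalignable noise)
    for lab in labels:
        d_max = max(topologies[lab].leaf_path_lengths().values())
        p_exp = 0.75 * (1.0 - np.exp(-4.0 * d_max / 3.0))
        if p_exp > 0.75 * 0.75:
            raise ValueError(
                f"topology {lab!r}: expected divergence {p_exp:.2f} is "
                "saturated (> 75% of the JC ceiling); lower the rate"
            )

    model = make_model("JC")
    seg_trees: dict[str, Tree] = {}
    per_strain: dict[str, list[Segment]] = {st: [] for st in strains}
    for seg in genome.segments:
        tree = topologies[rspec.per_segment_topologies[seg.name]]
        seg_trees[seg.name] = tree
        rng = stream(seed, f"gen_strains/evolve/{seg.name}")
        aln = simulate_alignment(tree, model, len(seg.sequence), rng,
                                 root_seq=seg.sequence)
        for st in strains:
            per_strain[st].append(Segment(name=seg.name, sequence=aln[st]))
    out = {
        st: SegmentedGenome(name=st, segments=per_strain[st],
                            meta={"parent": genome.name})
        for st in strains
    }
    return out, seg_trees


# -- read coverage -----------------------------------------------------------

def gen_isolate_reads(genomes: list[SegmentedGenome], sim: IsolateSimSpec,
                      read_len: int = 150, seed: int = 0,
                      host_reads: int = 0) -> ContigSet:
    """Assign reads to segments and emit contigs with per-base coverage.

    Reads are distributed multinomially over segments with weights
    abundance x length, so expected RPKM is proportional to abundance;
    per-base depth is uniform with Poisson noise. Satellite viruses are
    emitted only when their helper is present.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    rng = stream(seed, "gen_isolate_reads")
    by_name = {g.name: g for g in genomes}
    active: list[SegmentedGenome] = []
    present = {n for n in sim.viruses_present if n in by_name}
    for name in sorted(present):
        g = by_name[name]
        helper = g.meta.get("satellite_of")
        if helper is not None and helper not in present:
            warnings.warn(
                f"satellite {name} requested without its helper {helper}; "
                "omitted", stacklevel=2,
            )
            continue
        active.append(g)
    segs = [(g.name, s) for g in active for s in g.segments]
    if not segs:
        return ContigSet(contigs=[], total_mapped_reads=host_reads)

    weights = np.array(
        [sim.abundance.get(name, 1.0) * len(s) for name, s in segs], float
    )
    counts = (
        rng.multinomial(sim.total_reads, weights / weights.sum())
        if sim.total_reads > 0
        else np.zeros(len(segs), dtype=int)
    )
    contigs = []
    for (name, s), n_reads in zip(segs, counts):
        lam = n_reads * read_len / len(s)
        depth = rng.poisson(lam, size=len(s)) if lam > 0 else np.zeros(len(s), int)
        contigs.append(
            Contig(id=f"{name}|{s.name}", sequence=s.sequence, depth=depth,
                   mapped_reads=int(n_reads))
        )
    return ContigSet(contigs=contigs,
                     total_mapped_reads=sim.total_reads + host_reads)


# -- survey simulation -------------------------------------------------------

@dataclass(frozen=True)
class SurveyParams:
    """Infection parameters of a simulated survey.

    Defaults mirror the surveyed study system: ~74% trypanosomatid
    prevalence in firebugs, tombus-like virus in 57.5% of tested
    isolates, leishbuviruses in 12.3%, Ostravirus in 7.5% (only ever
    alongside its helper), qinvirus in 1.9%.
    """

    bugs_per_locality: int = 19
    p_trypanosomatid: float = 0.74
    virus_probs: dict = field(
        default_factory=lambda: {"TLV": 0.575, "LBV3": 0.123, "QIN": 0.019}
    )
    #: satellite -> (helper, unconditional probability)
    satellite_probs: dict = field(
        default_factory=lambda: {"OV": ("TLV", 0.075)}
    )
    virus_bands: dict = field(
        default_factory=lambda: {
            "TLV": (3.5, 2.2),
            "OV": (5.0, 4.2, 4.0, 3.0, 2.4, 1.6, 1.3),
            "LBV3": (6.2, 1.9, 1.5),
            "QIN": (5.3, 2.2),
        }
    )

    def __post_init__(self) -> None:
        probs = [self.p_trypanosomatid, *self.virus_probs.values()]
        probs += [p for _, p in self.satellite_probs.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")


def gen_survey(n_localities: int, isolates_per_locality: int,
               infection_params: SurveyParams | None = None,
               seed: int = 0) -> SurveyTable:
    """Simulate a survey table: per-locality trypanosomatid prevalence and
    per-isolate viral detections with band sizes taken from the simulated
    viruses' segment lengths."""
    params = infection_params or SurveyParams()
    rng = stream(seed, "gen_survey")
    records = []
    for loc in range(n_localities):
        city = f"L{loc:03d}"
        pos = int(rng.binomial(params.bugs_per_locality,
                               params.p_trypanosomatid))
        n_dsrna = 0
        recs_here = []
        for k in range(isolates_per_locality):
            viruses: set[str] = set()
            for v, p in params.virus_probs.items():
                if rng.random() < p:
                    viruses.add(v)
            for sat, (helper, p) in params.satellite_probs.items():
                p_helper = params.virus_probs.get(helper, 0.0)
                if helper in viruses and p_helper > 0:
                    if rng.random() < min(p / p_helper, 1.0):
                        viruses.add(sat)
            bands = sorted(
                {b for v in viruses for b in params.virus_bands.get(v, ())},
                reverse=True,
            )
            if viruses:
                n_dsrna += 1
            recs_here.append(
                IsolateRecord(
                    country="SIM",
                    city=city,
                    prevalence_pos=pos,
                    prevalence_n=params.bugs_per_locality,
                    isolate_id=f"{city}-{k:02d}",
                    band_sizes_kb=list(bands),
                    viral_ids=frozenset(viruses),
                    ngs=len(viruses) >= 2,
                )
            )
        for r in recs_here:
            r.dsrna_pos = n_dsrna
            r.dsrna_n = isolates_per_locality
        records.extend(recs_here)
    return SurveyTable(records=records)


# -- clone screens -----------------------------------------------------------

def gen_clone_screen(sim: IsolateSimSpec, n_clones: int, seed: int = 0,
                     detect_prob: dict[str, float] | None = None,
                     isolate_id: str = "SIM-01"):
    """Draw clones i.i.d. from the isolate's cell-infection mixture.

    ``detect_prob`` models band-level detectability: a virus present in a
    clone is observed with the given probability (default 1), mimicking
    low-abundance viruses whose bands fall below gel sensitivity.
    """
    from .clones import CloneScreen

    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    if not sim.cell_mixture:
        raise ValueError("IsolateSimSpec.cell_mixture is empty")
    rng = stream(seed, "gen_clone_screen")
    patterns = sorted(sim.cell_mixture)
    probs = np.array([sim.cell_mixture[p] for p in patterns])
    viruses = sorted({v for pat in patterns for v in pat} | set(sim.viruses_present))
    draws = rng.choice(len(patterns), size=n_clones, p=probs / probs.sum())
    mat = np.zeros((n_clones, len(viruses)), dtype=bool)
    for i, di in enumerate(draws):
        for v in patterns[di]:
            j = viruses.index(v)
            pd = 1.0 if detect_prob is None else detect_prob.get(v, 1.0)
            mat[i, j] = rng.random() < pd if pd < 1.0 else True
    return CloneScreen(isolate_id=isolate_id, viruses=viruses, presence=mat)
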
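"""Viral segment identification from assembled contigs.

Implements the contig-level evidence used to call genomic segments of
dsRNA viruses: coverage normalization (RPKM), recruitment of segments by
conserved terminal sequence motifs, reconciliation of contig lengths with
gel band sizes (with coverage-brightness rank correlation), six-frame ORF
finding, and alignment column statistics (variable sites, pairwise
identity).

Coordinates are 0-based half-open; gel band sizes are in kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .genome import ORF, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class Contig:
    id: str
    sequence: str
    depth: np.ndarray | None = None
    mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if len(self.depth) != len(self.sequence):
                raise ValueError(
                    f"contig {self.id}: depth vector length "
                    f"{len(self.depth)} != sequence length {len(self.sequence)}"
                )
        if self.mapped_reads < 0:
            raise ValueError(f"contig {self.id}: negative mapped_reads")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_depth(self) -> float:
        return float(np.mean(self.depth)) if self.depth is not None else 0.0


@dataclass
class ContigSet:
    """Assembled contigs with coverage; ``total_mapped_reads`` is the
    library total (host reads included), so it may exceed the per-contig
    sum."""

    contigs: list[Contig]
    total_mapped_reads: int

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass
class MotifHit:
    contig_id: str
    motif: str
    end: str          # "5p" or "3p": which contig end the hit sits at
    orientation: str  # "fwd" or "rc"
    offset: int       # distance from that end, in nt


@dataclass
class SegmentCall:
    contig_id: str
    matched_band_kb: float | None
    rpkm: float
    motif_hit: MotifHit | None
    criteria_passed: frozenset[str]  # subset of {"length", "coverage", "terminus"}
    orfs: list[ORF] = field(default_factory=list)


def rpkm(mapped_reads: int, segment_length_nt: int, total_mapped_reads: int
         ) -> float:
    """Reads per kilobase of segment per million mapped reads."""
    if segment_length_nt <= 0:
        raise ValueError("segment length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped reads must be non-negative")
    return mapped_reads / ((segment_length_nt / 1e3) * (total_mapped_reads / 1e6))


def find_terminal_motif(contigs: ContigSet | list[Contig], motif: str,
                        max_offset: int = 3) -> list[MotifHit]:
    """Find a conserved terminal motif near either end of each contig, on
    either strand.

    Orientation is recorded so callers can normalize contigs to put the
    motif at the 5' end: a ``(5p, fwd)`` hit is already normalized, while
    a ``(3p, rc)`` hit means the contig is deposited in the opposite
    orientation. The default ``max_offset`` of 3 nt tolerates a few
    spurious terminal bases from assembly.
    """
    motif = motif.upper()
    if len(motif) < 6:
        raise ValueError("motif must be at least 6 nt")
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    rc = revcomp(motif)
    hits: list[MotifHit] = []
    for contig in contigs:
        seq = contig.sequence.upper()
        L, m = len(seq), len(motif)
        head = seq[: max_offset + m]
        tail = seq[max(0, L - max_offset - m):]
        for probe, end, orient in (
            (motif, "5p", "fwd"),
            (rc, "5p", "rc"),
            (motif, "3p", "fwd"),
            (rc, "3p", "rc"),
        ):
            if end == "5p":
                idx = head.find(probe)
                if idx != -1 and idx <= max_offset:
                    hits.append(MotifHit(contig.id, motif, end, orient, idx))
            else:
                idx = tail.rfind(probe)
                if idx != -1:
                    off = len(tail) - (idx + m)
                    if off <= max_offset:
                        hits.append(MotifHit(contig.id, motif, end, orient, off))
    return hits


@dataclass
class BandMatch:
    #: contig id -> matched band (kb) or None
    assignments: dict[str, float | None]
    #: Spearman rho between contig RPKM and band brightness rank, if ranks
    #: were supplied
    spearman_rho: float | None
    #: contig id -> criteria passed so far ({"length"}, +"coverage")
    criteria: dict[str, frozenset[str]]


def match_bands(contigs: ContigSet, bands_kb: list[float],
                tolerance_frac: float = 0.15,
                brightness_ranks: dict[float, int] | None = None,
                min_rho: float = 0.5) -> BandMatch:
    """Assign contigs to gel bands by size and correlate coverage with
    band brightness.

    Each contig goes to the nearest band within ``tolerance_frac``
    relative size difference (ties break toward the larger band; gel
    sizing is coarse, so the default tolerance is generous). When
    ``brightness_ranks`` maps band size to visual brightness rank
    (1 = brightest), the Spearman correlation between contig RPKM and
    brightness is computed over matched contigs and the "coverage"
    criterion passes for them when the correlation reaches ``min_rho``.
    """
    if not bands_kb:
        raise ValueError("no bands supplied")
    if any(b <= 0 for b in bands_kb):
        raise ValueError("band sizes must be positive")
    assignments: dict[str, float | None] = {}
    criteria: dict[str, frozenset[str]] = {}
    for contig in contigs:
        kb = len(contig) / 1000.0
        best = None
        for band in sorted(bands_kb, reverse=True):  # ties -> larger band
            rel = abs(kb - band) / band
            if rel <= tolerance_frac and (best is None or rel < best[0] - 1e-12):
                best = (rel, band)
        assignments[contig.id] = best[1] if best else None
        criteria[contig.id] = frozenset({"length"} if best else set())

    rho = None
    if brightness_ranks is not None:
        matched = [c for c in contigs if assignments[c.id] is not None]
        if len(matched) >= 2:
            rpkms = [
                rpkm(c.mapped_reads, len(c), contigs.total_mapped_reads)
                for c in matched
            ]
            # brightness rank 1 = brightest; brighter bands should have
            # higher coverage, so correlate RPKM against inverted rank
            bright = [-brightness_ranks[assignments[c.id]] for c in matched]
            rho = float(spearmanr(rpkms, bright).statistic)
            if rho >= min_rho:
                for c in matched:
                    criteria[c.id] = criteria[c.id] | {"coverage"}
    return BandMatch(assignments=assignments, spearman_rho=rho, criteria=criteria)


def find_orfs(sequence: str, min_aa: int = 100) -> list[ORF]:
    """Six-frame ORF scan: ATG to the next in-frame stop, standard code.

    Within each stop-delimited stretch only the first (longest) ATG-
    initiated reading is reported. Coordinates are 0-based half-open on
    the forward strand and include the stop codon; ``aa_len`` excludes
    the stop. Results are sorted by protein length, longest first.
    """
    seq = sequence.upper().replace("U", "T")
    L = len(seq)
    out: list[ORF] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start_codon = None
            for pos in range(frame, L - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start_codon is not None:
                        aa = (pos - start_codon) // 3
                        if aa >= min_aa:
                            out.append(_mk_orf(start_codon, pos + 3, frame,
                                               strand, aa, L))
                        start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    out.sort(key=lambda o: (-o.aa_len, o.start))
    return out


def _mk_orf(start: int, end: int, frame: int, strand: str, aa: int, L: int
            ) -> ORF:
    if strand == "+":
        return ORF(start=start, end=end, frame=frame, strand="+", aa_len=aa)
    return ORF(start=L - end, end=L - start, frame=frame, strand="-", aa_len=aa)


def variable_sites(aligned: dict[str, str] | list[str], level: str = "nt"
                   ) -> float:
    """Percent of alignment columns with more than one distinct non-gap
    state.

    Gap-only columns are excluded from the denominator. ``level="aa"``
    translates every sequence in frame 0 (standard code) before scanning.
    """
    seqs = list(aligned.values()) if isinstance(aligned, dict) else list(aligned)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences have unequal lengths")
    if level == "aa":
        from Bio.Seq import Seq

        seqs = [
            str(Seq(s[: len(s) - len(s) % 3].replace("-", "N")).translate())
            for s in seqs
        ]
    elif level != "nt":
        raise ValueError("level must be 'nt' or 'aa'")
    mat = np.array([list(s.upper()) for s in seqs])
    is_gap = np.isin(mat, ["-", ".", "X"]) if level == "aa" else np.isin(mat, ["-", "."])
    informative = ~is_gap.all(axis=0)
    n_cols = int(informative.sum())
    if n_cols == 0:
        return 0.0
    variable = 0
    for j in np.nonzero(informative)[0]:
        states = set(mat[~is_gap[:, j], j])
        if len(states) > 1:
            variable += 1
    return 100.0 * variable / n_cols


def pairwise_identity(seq_a: str, seq_b: str, aligned: bool = True) -> float:
    """Percent identity over ungapped columns of an aligned pair.

    Columns with a gap in either sequence are excluded from the
    denominator. Unaligned sequences of unequal length are rejected;
    alignment itself is out of scope here (use an external aligner such
    as MAFFT first).
    """
    if len(seq_a) != len(seq_b):
        if not aligned:
            raise ValueError(
                "unaligned sequences of unequal length; align them first "
                "(e.g. with MAFFT) and pass aligned=True"
            )
        raise ValueError("aligned sequences must have equal length")
    a = np.array(list(seq_a.upper()))
    b = np.array(list(seq_b.upper()))
    keep = ~(np.isin(a, ["-", "."]) | np.isin(b, ["-", "."]))
    if keep.sum() == 0:
        return 0.0
    return float(100.0 * (a[keep] == b[keep]).mean())


def call_segments(contigs: ContigSet, bands_kb: list[float] | None = None,
                  motif: str | None = None, max_offset: int = 3,
                  tolerance_frac: float = 0.15,
                  brightness_ranks: dict[float, int] | None = None,
                  min_aa: int = 100) -> list[SegmentCall]:
    """Combine the three segment-identification criteria into per-contig
    calls: (length) gel-band match, (coverage) brightness correlation,
    (terminus) terminal-motif presence; plus RPKM and ORF annotation."""
    band_res = (
        match_bands(contigs, bands_kb, tolerance_frac, brightness_ranks)
        if bands_kb
        else None
    )
    motif_hits: dict[str, MotifHit] = {}
    if motif:
        for hit in find_terminal_motif(contigs, motif, max_offset):
            motif_hits.setdefault(hit.contig_id, hit)
    calls = []
    for contig in contigs:
        crit: set[str] = set()
        band = None
        if band_res is not None:
            band = band_res.assignments[contig.id]
            crit |= band_res.criteria[contig.id]
        hit = motif_hits.get(contig.id)
        if hit is not None:
            crit.add("terminus")
        calls.append(
            SegmentCall(
                contig_id=contig.id,
                matched_band_kb=band,
                rpkm=rpkm(contig.mapped_reads, len(contig),
                          contigs.total_mapped_reads),
                motif_hit=hit,
                criteria_passed=frozenset(crit),
                orfs=find_orfs(contig.sequence, min_aa=min_aa),
            )
        )
    return calls
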
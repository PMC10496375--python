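"""Survey-table records and the prevalence / coinfection statistics.

A survey table holds one row per trypanosomatid isolate: where it was
collected, the trypanosomatid prevalence at that locality (positive
firebugs / dissected firebugs), the double-stranded RNA bands its culture
displayed on a gel, the viral species identified in it, and whether it was
selected for next-generation sequencing (NGS).

Counting conventions
--------------------
* Locality prevalence fractions are summed (numerators and denominators
  separately), never averaged, when forming survey-wide totals.
* A viral identity like ``LBV1/2/4`` records the co-detection of several
  leishbuvirus species in one isolate and expands to the listed species.
  A bare ``LBV`` (species unidentifiable without sequence data) is kept as
  the single pseudo-species ``LBV_unresolved``; it counts toward the LBV
  group total but toward no individual LBV1-4 species.
* Detections flagged as gel-negative (virus seen only in NGS data, no
  band) are included by default and can be excluded via
  ``count_footnoted=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

#: Viral species labels a survey may contain.
KNOWN_VIRUSES = frozenset(
    {"TLV", "OV", "QIN", "LBV1", "LBV2", "LBV3", "LBV4", "LBV_unresolved"}
)
LBV_SPECIES = ("LBV1", "LBV2", "LBV3", "LBV4")

#: Record-level footnote flags.
GEL_NEGATIVE = "gel_negative_virus"
LARGE_SEGMENT_ONLY = "large_segment_only"
SPECIES_UNIDENTIFIED = "species_unidentified"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention of printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class IsolateRecord:
    """One surveyed isolate."""

    country: str
    city: str
    prevalence_pos: int
    prevalence_n: int
    isolate_id: str
    band_sizes_kb: list[float] = field(default_factory=list)
    viral_ids: frozenset[str] = frozenset()
    ngs: bool = False
    footnotes: frozenset[str] = frozenset()
    #: species detected only by NGS, with no corresponding gel band
    gel_negative_ids: frozenset[str] = frozenset()
    #: dsRNA-positive / tested at this record's locality
    dsrna_pos: int = 0
    dsrna_n: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.prevalence_pos <= self.prevalence_n):
            raise ValueError(
                f"isolate {self.isolate_id}: prevalence {self.prevalence_pos}"
                f"/{self.prevalence_n} out of range"
            )
        for b in self.band_sizes_kb:
            if not 0 < b < 50:
                raise ValueError(
                    f"isolate {self.isolate_id}: band size {b} kb outside (0, 50)"
                )
        unknown = set(self.viral_ids) - KNOWN_VIRUSES
        if unknown:
            raise ValueError(
                f"isolate {self.isolate_id}: unknown viral labels {sorted(unknown)}"
            )

    @property
    def locality(self) -> tuple[str, str]:
        return (self.country, self.city)

    def is_dsrna_positive(self) -> bool:
        return bool(self.band_sizes_kb) or bool(self.viral_ids)

    def species(self, count_footnoted: bool = True) -> frozenset[str]:
        """Viral species in this isolate, optionally dropping NGS-only calls."""
        if count_footnoted:
            return self.viral_ids
        return self.viral_ids - self.gel_negative_ids


@dataclass
class SurveyTable:
    """Ordered isolate records plus per-locality prevalence fractions."""

    records: list[IsolateRecord]
    locality_prevalences: list[tuple[tuple[str, str], int, int]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        ids = [r.isolate_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate isolate ids: {dupes}")
        if not self.locality_prevalences:
            self.locality_prevalences = self._derive_localities()
        locs = [loc for loc, _, _ in self.locality_prevalences]
        if len(locs) != len(set(locs)):
            raise ValueError("locality appears more than once in prevalence list")

    def _derive_localities(self) -> list[tuple[tuple[str, str], int, int]]:
        seen: dict[tuple[str, str], tuple[int, int]] = {}
        for r in self.records:
            seen.setdefault(r.locality, (r.prevalence_pos, r.prevalence_n))
        return [(loc, p, n) for loc, (p, n) in seen.items()]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PrevalenceReport:
    """Survey-wide tallies in the shape the study reports them."""

    trypanosomatid_pos: int
    trypanosomatid_n: int
    trypanosomatid_percent: float  # integer precision
    dsrna_pos: int
    dsrna_n: int
    dsrna_percent: float  # integer precision
    #: virus group -> (count, % of dsRNA-positive, % of tested), one decimal
    virus_counts: dict[str, tuple[int, float, float]]
    #: per-species LBV counts (LBV group total is in virus_counts["LBV"])
    lbv_species_counts: dict[str, int]
    n_coinfected: int
    max_species_per_isolate: int
    n_ngs: int
    band_count_range: tuple[int, int] | None
    band_size_range_kb: tuple[float, float] | None
    cooccurrence: pd.DataFrame

    def formatted(self) -> dict[str, str]:
        """Human-readable strings at printed precision."""
        out = {
            "trypanosomatid": (
                f"{self.trypanosomatid_pos}/{self.trypanosomatid_n} "
                f"({self.trypanosomatid_percent:.0f}%)"
            ),
            "dsRNA": f"{self.dsrna_pos}/{self.dsrna_n} ({self.dsrna_percent:.0f}%)",
        }
        for virus, (count, p_pos, p_all) in self.virus_counts.items():
            out[virus] = f"{count} ({p_pos:.1f}% of positive, {p_all:.1f}% of tested)"
        return out


def _species_groups(species: frozenset[str]) -> set[str]:
    """Collapse species to reporting groups: TLV, OV, QIN and the LBV family."""
    groups = set()
    for s in species:
        groups.add("LBV" if s.startswith("LBV") else s)
    return groups


def prevalence_summary(
    table: SurveyTable, count_footnoted: bool = True
) -> PrevalenceReport:
    """Tally the survey table the way the study's totals row does.

    ``count_footnoted=False`` drops detections seen only in NGS data
    (no gel band) before counting.
    """
    tryp_pos = sum(p for _, p, _ in table.locality_prevalences)
    tryp_n = sum(n for _, _, n in table.locality_prevalences)

    positive = [r for r in table.records if r.is_dsrna_positive()]
    n_pos, n_all = len(positive), len(table.records)

    group_counts: dict[str, int] = {g: 0 for g in ("TLV", "LBV", "OV", "QIN")}
    lbv_species: dict[str, int] = {s: 0 for s in LBV_SPECIES}
    species_per_isolate: list[int] = []
    n_coinf = 0
    for r in positive:
        sp = r.species(count_footnoted)
        for g in _species_groups(sp):
            group_counts[g] = group_counts.get(g, 0) + 1
        for s in sp & set(LBV_SPECIES):
            lbv_species[s] += 1
        k = len(sp)
        species_per_isolate.append(k)
        if k >= 2:
            n_coinf += 1

    def pct(cnt: int, denom: int, ndig: int) -> float:
        return round_half_up(100.0 * cnt / denom, ndig) if denom else 0.0

    virus_counts = {
        g: (c, pct(c, n_pos, 1), pct(c, n_all, 1)) for g, c in group_counts.items()
    }

    banded = [r for r in positive if r.band_sizes_kb]
    band_count_range = (
        (min(len(r.band_sizes_kb) for r in banded), max(len(r.band_sizes_kb) for r in banded))
        if banded
        else None
    )
    all_bands = [b for r in banded for b in r.band_sizes_kb]
    band_size_range = (min(all_bands), max(all_bands)) if all_bands else None

    species_order = ["TLV", "OV", "QIN", *LBV_SPECIES, "LBV_unresolved"]
    co = pd.DataFrame(0, index=species_order, columns=species_order, dtype=int)
    for r in positive:
        sp = sorted(r.species(count_footnoted))
        for a in sp:
            for b in sp:
                co.loc[a, b] += 1

    return PrevalenceReport(
        trypanosomatid_pos=tryp_pos,
        trypanosomatid_n=tryp_n,
        trypanosomatid_percent=pct(tryp_pos, tryp_n, 0),
        dsrna_pos=n_pos,
        dsrna_n=n_all,
        dsrna_percent=pct(n_pos, n_all, 0),
        virus_counts=virus_counts,
        lbv_species_counts=lbv_species,
        n_coinfected=n_coinf,
        max_species_per_isolate=max(species_per_isolate, default=0),
        n_ngs=sum(1 for r in table.records if r.ngs),
        band_count_range=band_count_range,
        band_size_range_kb=band_size_range,
        cooccurrence=co,
    )


@dataclass
class CoinfectionProfile:
    n_coinfected: int
    max_species: int
    #: (isolate_id, n_species, sorted species tuple), ordered by isolate id
    per_isolate: list[tuple[str, int, tuple[str, ...]]]


def coinfection_profile(
    table: SurveyTable, count_footnoted: bool = True
) -> CoinfectionProfile:
    """Per-isolate species counts and the number of coinfected isolates."""
    rows = []
    for r in table.records:
        sp = tuple(sorted(r.species(count_footnoted)))
        if sp:
            rows.append((r.isolate_id, len(sp), sp))
    rows.sort(key=lambda t: t[0])
    return CoinfectionProfile(
        n_coinfected=sum(1 for _, k, _ in rows if k >= 2),
        max_species=max((k for _, k, _ in rows), default=0),
        per_isolate=rows,
    )


@dataclass
class ContainmentResult:
    contained: bool
    vacuous: bool
    #: 2x2 counts [[x&y, x&!y], [!x&y, !x&!y]]
    counts: tuple[tuple[int, int], tuple[int, int]]


def cooccurrence_containment(
    table: SurveyTable, virus_x: str, virus_y: str, count_footnoted: bool = True
) -> ContainmentResult:
    """Is every isolate carrying ``virus_x`` also carrying ``virus_y``?

    Labels may be species (``OV``) or the family group ``LBV``. Satellite
    behaviour shows up as containment: a satellite's carriers are a subset
    of its helper's carriers.
    """
    for v in (virus_x, virus_y):
        if v not in KNOWN_VIRUSES and v != "LBV":
            raise ValueError(f"unknown virus label {v!r}")

    def has(r: IsolateRecord, v: str) -> bool:
        sp = r.species(count_footnoted)
        return v in _species_groups(sp) if v == "LBV" else v in sp

    a = b = c = d = 0
    for r in table.records:
        x, y = has(r, virus_x), has(r, virus_y)
        a += x and y
        b += x and not y
        c += (not x) and y
        d += (not x) and (not y)
    n_x = a + b
    return ContainmentResult(
        contained=(b == 0), vacuous=(n_x == 0), counts=((a, b), (c, d))
    )
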
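"""Readers and writers for the on-disk formats the pipeline consumes.

Formats are plain text throughout: TSV survey tables, FASTA sequences,
per-base coverage TSV (``contig<TAB>pos<TAB>depth`` with 1-based
positions), Newick trees, and clone presence/absence matrices. In memory
every coordinate is 0-based half-open; files keep their native 1-based
inclusive conventions.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources
from pathlib import Path

import numpy as np

from .survey import (
    GEL_NEGATIVE,
    LARGE_SEGMENT_ONLY,
    SPECIES_UNIDENTIFIED,
    IsolateRecord,
    SurveyTable,
)

_SURVEY_COLUMNS = [
    "country", "city", "tryp_pos", "tryp_n", "dsrna_pos", "dsrna_n",
    "isolate", "bands_kb", "viral_identity", "ngs",
]

_FOOTNOTE_FLAGS = {"a": GEL_NEGATIVE, "b": LARGE_SEGMENT_ONLY, "c": SPECIES_UNIDENTIFIED}


def bundled_survey_path() -> Path:
    """Path to the shipped isolate survey table."""
    return Path(resources.files("virago").joinpath("data/leptomonas_survey.tsv"))


def _parse_identity(text: str, isolate: str):
    """Expand a viral-identity cell into species, footnotes and NGS-only ids.

    ``LBV1/2/4`` is a co-detection of several leishbuvirus species and
    expands to the listed species; a bare ``LBV`` (species unidentifiable)
    becomes ``LBV_unresolved``. A ``^a`` marker flags species seen only in
    NGS data (no gel band); ``^b``/``^c`` become record-level flags.
    """
    ids: set[str] = set()
    gel_negative: set[str] = set()
    flags: set[str] = set()
    if not text:
        return frozenset(), frozenset(), frozenset()
    # footnote lists ("^b,c") use a bare comma; species are comma+space
    for token in re.split(r",\s+", text.strip()):
        m = re.fullmatch(r"([A-Za-z0-9/]+)((?:\^[a-c](?:,[a-c])*)?)", token)
        if not m:
            raise ValueError(f"isolate {isolate}: malformed viral identity {token!r}")
        name, notes = m.group(1), m.group(2)
        note_letters = re.findall(r"[a-c]", notes)
        if re.fullmatch(r"LBV[0-9](?:/[0-9])+", name):
            species = {f"LBV{d}" for d in re.findall(r"[0-9]", name)}
        elif name == "LBV":
            species = {"LBV_unresolved"}
        else:
            species = {name}
        ids |= species
        for letter in note_letters:
            flags.add(_FOOTNOTE_FLAGS[letter])
            if letter == "a":
                gel_negative |= species
    return frozenset(ids), frozenset(flags), frozenset(gel_negative)


def read_survey(path: str | Path) -> SurveyTable:
    """Read an isolate survey TSV into a :class:`SurveyTable`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _SURVEY_COLUMNS:
        raise ValueError(f"{path}: missing header (expected {_SURVEY_COLUMNS})")
    records = []
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        fields += [""] * (len(_SURVEY_COLUMNS) - len(fields))
        row = dict(zip(_SURVEY_COLUMNS, fields))
        isolate = row["isolate"]
        try:
            bands = [float(b) for b in re.split(r",\s*", row["bands_kb"]) if b.strip()]
            ids, flags, gel_neg = _parse_identity(row["viral_identity"], isolate)
            rec = IsolateRecord(
                country=row["country"],
                city=row["city"],
                prevalence_pos=int(row["tryp_pos"]),
                prevalence_n=int(row["tryp_n"]),
                isolate_id=isolate,
                band_sizes_kb=bands,
                viral_ids=ids,
                ngs=row["ngs"].strip().lower() in {"yes", "true", "1"},
                footnotes=flags,
                gel_negative_ids=gel_neg,
                dsrna_pos=int(row["dsrna_pos"] or 0),
                dsrna_n=int(row["dsrna_n"] or 0),
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {ln} ({isolate!r}): {exc}") from exc
        records.append(rec)
    return SurveyTable(records=records)


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write a survey table back to TSV (inverse of :func:`read_survey`)."""
    out = ["\t".join(_SURVEY_COLUMNS)]
    for r in table.records:
        bands = ", ".join(_fmt_kb(b) for b in r.band_sizes_kb)
        out.append(
            "\t".join(
                [
                    r.country, r.city,
                    str(r.prevalence_pos), str(r.prevalence_n),
                    str(r.dsrna_pos), str(r.dsrna_n),
                    r.isolate_id, bands,
                    _format_identity(r),
                    "Yes" if r.ngs else "",
                ]
            ).rstrip("\t")
        )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def _fmt_kb(b: float) -> str:
    s = f"{b:g}"
    return s


def _format_identity(r: IsolateRecord) -> str:
    tokens = []
    order = {"TLV": 0, "OV": 1, "QIN": 2}
    lbv_digits = sorted(s[-1] for s in r.viral_ids if re.fullmatch(r"LBV[0-9]", s))
    plain = sorted(
        (s for s in r.viral_ids if not s.startswith("LBV")),
        key=lambda s: order.get(s, 9),
    )
    for s in plain:
        tokens.append(s + ("^a" if s in r.gel_negative_ids else ""))
    if lbv_digits:
        name = "LBV" + "/".join(lbv_digits) if len(lbv_digits) > 1 else f"LBV{lbv_digits[0]}"
        notes = []
        if set(f"LBV{d}" for d in lbv_digits) & r.gel_negative_ids:
            notes.append("a")
        if LARGE_SEGMENT_ONLY in r.footnotes:
            notes.append("b")
        tokens.append(name + (("^" + ",".join(notes)) if notes else ""))
    if "LBV_unresolved" in r.viral_ids:
        notes = [
            letter
            for letter, flag in (("b", LARGE_SEGMENT_ONLY), ("c", SPECIES_UNIDENTIFIED))
            if flag in r.footnotes
        ]
        tokens.append("LBV" + (("^" + ",".join(notes)) if notes else ""))
    return ", ".join(tokens)


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased; characters outside ACGTN are N-masked with
    a warning.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN-")
        if bad:
            warnings.warn(
                f"{rec.id}: non-ACGTN characters {sorted(bad)} masked to N",
                stacklevel=2,
            )
            seq = re.sub(r"[^ACGTN-]", "N", seq)
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- coverage ---------------------------------------------------------------

def read_coverage_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-base coverage (``contig  pos  depth``, 1-based positions).

    Returns ``{contig: depth vector}`` with 0-based indexing in memory.
    """
    depths: dict[str, dict[int, int]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split()
            if len(parts) != 3:
                raise ValueError(f"{path} line {ln}: expected 3 columns")
            contig, pos, depth = parts[0], int(parts[1]), int(parts[2])
            if pos < 1:
                raise ValueError(
                    f"{path} line {ln}: position {pos} violates the 1-based contract"
                )
            depths.setdefault(contig, {})[pos - 1] = depth
    out = {}
    for contig, d in depths.items():
        vec = np.zeros(max(d) + 1, dtype=np.int64)
        for i, v in d.items():
            vec[i] = v
        out[contig] = vec
    return out


def write_coverage_tsv(depths: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for contig, vec in depths.items():
            for i, v in enumerate(vec):
                fh.write(f"{contig}\t{i + 1}\t{int(v)}\n")


# -- Newick -----------------------------------------------------------------

def read_newick(path: str | Path):
    """Read a Newick file into a :class:`virago.phylo.Tree`."""
    from .phylo.tree import Tree

    text = Path(path).read_text(encoding="utf-8").strip()
    return Tree.from_newick(text)


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


# -- clone screens ----------------------------------------------------------

def read_clone_matrix(path: str | Path):
    """Read a clone presence/absence TSV into a :class:`CloneScreen`.

    Layout: header ``clone<TAB>virusA<TAB>virusB...``; one row per clone
    with 0/1 entries. The isolate id is taken from the filename stem.
    """
    from .clones import CloneScreen

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("clone"):
        raise ValueError(f"{path}: missing header")
    viruses = lines[0].split("\t")[1:]
    clone_ids, rows = [], []
    for raw in lines[1:]:
        if not raw.strip():
            continue
        parts = raw.split("\t")
        clone_ids.append(parts[0])
        rows.append([bool(int(x)) for x in parts[1:]])
    return CloneScreen(
        isolate_id=Path(path).stem,
        viruses=viruses,
        presence=np.array(rows, dtype=bool).reshape(len(rows), len(viruses)),
        clone_ids=clone_ids,
    )


def write_clone_matrix(screen, path: str | Path) -> None:
    lines = ["clone\t" + "\t".join(screen.viruses)]
    for i, cid in enumerate(screen.clone_ids):
        lines.append(cid + "\t" + "\t".join(str(int(x)) for x in screen.presence[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
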
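"""Terminal complementary sequence (panhandle) analysis.

Bunyavirus-like genome segments carry complementary 5' and 3' termini
that base-pair into a "panhandle" duplex of roughly 20-30 nt, interrupted
by kinks and bulges, with a conserved family-specific terminal octamer
(canonically ``ACACAAAG`` in phenui- and leishbuviruses). This module
aligns the 5' terminal window of a segment against the reverse complement
of its 3' terminal window with an affine-bulge dynamic program, and
classifies terminal octamers against the canonical one.

Scoring counts Watson-Crick pairs as matches and G.U wobble columns at a
reduced weight. Wobble columns are scored symmetrically (unordered
{G, A} and {T, C} column pairs) so that a segment and its reverse
complement yield the same score; deposited sequence orientation varies,
so orientation must not change the verdict.

Multi-branched loops and hairpins are deliberately not folded: a complex
internal structure simply shows up as a long, low-scoring interruption in
the duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import SegmentedGenome, revcomp
from .segments import find_orfs

#: conserved terminal octamer of the L segment in phenui-/leishbuviruses
CANONICAL_OCTAMER = "ACACAAAG"

WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
            ("A", "A"), ("C", "C"), ("G", "G"), ("T", "T")}
# identity columns are WC pairs: y is the reverse complement of the 3'
# terminus, so x[i] == y[j] means x[i] is complementary to the 3' base
MATCH_COLUMNS = {("A", "A"), ("C", "C"), ("G", "G"), ("T", "T")}
WOBBLE_COLUMNS = {("G", "A"), ("A", "G"), ("T", "C"), ("C", "T")}


@dataclass
class Bulge:
    side: str   # "5p": unpaired 5'-terminus bases; "3p": unpaired 3' bases
    start: int  # offset of the first unpaired base (from its own end)
    length: int


@dataclass
class PanhandleDuplex:
    segment_id: str
    window: int
    #: (i5, i3): i5 = offset from the 5' end, i3 = offset from the 3' end
    paired_positions: list[tuple[int, int]]
    n_pairs: int
    n_mismatches: int
    bulges: list[Bulge]
    score: float
    octamer_5: str
    octamer_side: str  # "5p" or "3p": which terminus matched best
    canonical_octamer_match: bool
    octamer_distance: int

    def render(self) -> str:
        """Two-line text rendering of the duplex (| pair, : wobble,
        . mismatch, - bulge)."""
        top, marks, bottom = [], [], []
        events = _alignment_columns(self)
        for kind, a, b in events:
            if kind == "pair":
                top.append(a)
                bottom.append(b)
                col = (a, b)
                marks.append(":" if col in WOBBLE_COLUMNS else
                             ("|" if col in MATCH_COLUMNS else "."))
            elif kind == "5p":
                top.append(a)
                bottom.append("-")
                marks.append(" ")
            else:
                top.append("-")
                bottom.append(b)
                marks.append(" ")
        return "\n".join(("".join(top), "".join(marks), "".join(bottom)))


def _alignment_columns(d: PanhandleDuplex):
    """Reconstruct the column sequence from pairs+bulges (for rendering)."""
    cols = []
    x, y = d._x, d._y
    i = j = 0
    paired = dict(d.paired_positions)
    mism = dict(d._mismatch_positions)
    while i < len(x) or j < len(y):
        if i in paired and paired[i] == j:
            cols.append(("pair", x[i], y[j]))
            i += 1
            j += 1
        elif i in mism and mism[i] == j:
            cols.append(("pair", x[i], y[j]))
            i += 1
            j += 1
        elif any(b.side == "5p" and b.start <= i < b.start + b.length
                 for b in d.bulges):
            cols.append(("5p", x[i], None))
            i += 1
        else:
            cols.append(("3p", None, y[j]))
            j += 1
    return cols


def levenshtein(a: str, b: str) -> int:
    """Edit distance (unit costs) by dynamic programming."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def duplex_align(x: str, y: str, match: float = 1.0, wobble: float = 0.5,
                 mismatch: float = -1.0, bulge_open: float = -2.0,
                 bulge_extend: float = -0.5
                 ) -> tuple[float, list[tuple[str, int, int]]]:
    """Global affine-bulge alignment of a 5' window against the reverse
    complement of a 3' window.

    A bulge of length L costs ``bulge_open + (L - 1) * bulge_extend``.
    Returns the optimal score and the traceback column list
    ``(kind, i, j)`` with kind in {"pair", "5p", "3p"}; traceback ties
    break pair > 5'-bulge > 3'-bulge, giving a unique deterministic
    alignment.
    """

    def col_score(a: str, b: str) -> float:
        if (a, b) in MATCH_COLUMNS:
            return match
        if (a, b) in WOBBLE_COLUMNS:
            return wobble
        return mismatch

    m, n = len(x), len(y)
    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in y: unpaired 5' bases
    Y = np.full((m + 1, n + 1), NEG)  # gap in x: unpaired 3' bases
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = bulge_open + (i - 1) * bulge_extend
    for j in range(1, n + 1):
        Y[0, j] = bulge_open + (j - 1) * bulge_extend
    # traceback: which predecessor state; preference M > X > Y on ties
    ptr_M = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_X = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_Y = np.zeros((m + 1, n + 1), dtype=np.int8)
    STATES = ("M", "X", "Y")
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = col_score(x[i - 1], y[j - 1])
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))  # argmax prefers earlier on ties: M>X>Y
            M[i, j] = opts[k] + s
            ptr_M[i, j] = k
            opts = (M[i - 1, j] + bulge_open, X[i - 1, j] + bulge_extend,
                    Y[i - 1, j] + bulge_open)
            k = int(np.argmax(opts))
            X[i, j] = opts[k]
            ptr_X[i, j] = k
            opts = (M[i, j - 1] + bulge_open, X[i, j - 1] + bulge_open,
                    Y[i, j - 1] + bulge_extend)
            k = int(np.argmax(opts))
            Y[i, j] = opts[k]
            ptr_Y[i, j] = k

    finals = (M[m, n], X[m, n], Y[m, n])
    state = STATES[int(np.argmax(finals))]
    score = float(max(finals))

    # traceback
    i, j = m, n
    cols: list[tuple[str, int, int]] = []
    while i > 0 or j > 0:
        if state == "M":
            prev = STATES[ptr_M[i, j]]
            cols.append(("pair", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == "X":
            prev = STATES[ptr_X[i, j]] if j > 0 else ("X" if i > 1 else "M")
            cols.append(("5p", i - 1, j))
            i -= 1
        else:
            prev = STATES[ptr_Y[i, j]] if i > 0 else ("Y" if j > 1 else "M")
            cols.append(("3p", i, j - 1))
            j -= 1
        state = prev
    cols.reverse()
    return score, cols


def panhandle_align(sequence: str, window: int = 30, match: float = 1.0,
                    wobble: float = 0.5, mismatch: float = -1.0,
                    bulge_open: float = -2.0, bulge_extend: float = -0.5,
                    segment_id: str = "") -> PanhandleDuplex:
    """Panhandle duplex of one segment: align its first ``window`` nt
    against the reverse complement of its last ``window`` nt.

    See :func:`duplex_align` for the scoring conventions. The terminal
    octamer is read from both termini (deposited orientation varies) and
    the better match to the canonical ``ACACAAAG`` is reported.
    """
    seq = sequence.upper().replace("U", "T")
    if not 10 <= window <= 60:
        raise ValueError("window must be in [10, 60]")
    if len(seq) < 2 * window:
        raise ValueError(
            f"sequence of {len(seq)} nt too short for two non-overlapping "
            f"{window}-nt terminal windows"
        )
    x = seq[:window]
    y = revcomp(seq[-window:])  # y[j] pairs position j from the 3' end
    score, cols = duplex_align(x, y, match=match, wobble=wobble,
                               mismatch=mismatch, bulge_open=bulge_open,
                               bulge_extend=bulge_extend)

    paired, mismatches, bulges = [], [], []
    run: Bulge | None = None
    for kind, ci, cj in cols:
        if kind == "pair":
            run = None
            col = (x[ci], y[cj])
            if col in MATCH_COLUMNS or col in WOBBLE_COLUMNS:
                paired.append((ci, cj))
            else:
                mismatches.append((ci, cj))
        else:
            pos = ci if kind == "5p" else cj
            if run is not None and run.side == kind and \
                    run.start + run.length == pos:
                run.length += 1
            else:
                run = Bulge(side=kind, start=pos, length=1)
                bulges.append(run)

    oct5 = seq[:8]
    oct3 = revcomp(seq[-8:])
    d5 = levenshtein(oct5, CANONICAL_OCTAMER)
    d3 = levenshtein(oct3, CANONICAL_OCTAMER)
    side, octamer, dist = ("5p", oct5, d5) if d5 <= d3 else ("3p", oct3, d3)

    duplex = PanhandleDuplex(
        segment_id=segment_id,
        window=window,
        paired_positions=paired,
        n_pairs=len(paired),
        n_mismatches=len(mismatches),
        bulges=bulges,
        score=score,
        octamer_5=octamer,
        octamer_side=side,
        canonical_octamer_match=(dist == 0),
        octamer_distance=dist,
    )
    duplex._x = x
    duplex._y = y
    duplex._mismatch_positions = mismatches
    return duplex


@dataclass
class PanhandleComparison:
    per_group: pd.DataFrame
    #: group -> (consensus octamer, edit distance to canonical, flagged)
    octamer_table: dict[str, tuple[str, int, bool]]
    most_canonical_group: str | None


def compare_panhandles(duplexes: list[PanhandleDuplex], groups: list[str]
                       ) -> PanhandleComparison:
    """Summarize duplex shape and octamer conservation per group (e.g. per
    virus or per segment class); groups whose consensus octamer deviates
    from the canonical one are flagged."""
    if len(duplexes) < 2:
        raise ValueError("need at least two duplexes")
    if len(duplexes) != len(groups):
        raise ValueError("one group label per duplex required")
    rows = []
    octamers: dict[str, list[str]] = {}
    for d, g in zip(duplexes, groups):
        rows.append(
            {"group": g, "n_pairs": d.n_pairs, "n_mismatches": d.n_mismatches,
             "n_bulges": len(d.bulges), "score": d.score,
             "octamer_distance": d.octamer_distance}
        )
        octamers.setdefault(g, []).append(d.octamer_5)
    df = pd.DataFrame(rows).groupby("group").agg(["mean", "std"])

    table: dict[str, tuple[str, int, bool]] = {}
    for g, octs in octamers.items():
        consensus = "".join(
            max(set(col), key=lambda c: (col.count(c), c)) for col in zip(*octs)
        )
        dist = levenshtein(consensus, CANONICAL_OCTAMER)
        table[g] = (consensus, dist, dist > 0)
    best = min(table, key=lambda g: (table[g][1], g)) if table else None
    return PanhandleComparison(per_group=df, octamer_table=table,
                               most_canonical_group=best)


def segment_size_trajectory(genomes_by_clade: dict[str, SegmentedGenome],
                            clade_order: list[str],
                            segment_names: tuple[str, ...] = ("M", "S")
                            ) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Tabulate segment and encoded-protein lengths along a clade order
    and report whether each column decreases monotonically.

    Missing segments are recorded as absent (NaN) and skipped in the
    monotonicity check; monotone reduction is *reported*, never assumed.
    """
    rows = []
    for clade in clade_order:
        genome = genomes_by_clade.get(clade)
        row: dict[str, float] = {"clade": clade}
        for s in segment_names:
            try:
                seg = genome.segment(s) if genome else None
            except KeyError:
                seg = None
            if seg is None:
                row[f"{s}_len_nt"] = np.nan
                row[f"{s}_protein_aa"] = np.nan
            else:
                orfs = seg.orfs or find_orfs(seg.sequence, min_aa=50)
                row[f"{s}_len_nt"] = len(seg)
                row[f"{s}_protein_aa"] = (
                    max((o.aa_len for o in orfs), default=np.nan)
                )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("clade")
    monotone = {}
    for col in df.columns:
        vals = df[col].dropna().to_numpy()
        monotone[col] = bool(np.all(np.diff(vals) <= 0)) if len(vals) > 1 else True
    return df, monotone
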
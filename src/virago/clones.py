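"""Clone-level infection heterogeneity within an isolate.

An isolate culture can be a mixture of cells with different viral
infection statuses. Screening a handful of clones (the study used eight)
by gel electrophoresis gives a presence/absence matrix; this module
classifies the clone patterns, estimates per-virus infected fractions
with exact binomial confidence intervals, and tests virus co-occurrence
across clones with Fisher's exact test computed by explicit
hypergeometric enumeration.

With only eight clones the power to call an isolate homogeneous is
minimal, so the classification reports "no heterogeneity detected at n
clones" rather than "pure".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, inf

import numpy as np
from scipy.stats import beta


@dataclass
class CloneScreen:
    isolate_id: str
    viruses: list[str]
    presence: np.ndarray  # (n_clones, n_viruses) boolean
    clone_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 2:
            raise ValueError("presence must be a 2-D matrix")
        if self.presence.shape[1] != len(self.viruses):
            raise ValueError("presence matrix width != number of viruses")
        if self.presence.shape[0] < 1:
            raise ValueError("need at least one clone")
        if not self.clone_ids:
            self.clone_ids = [f"clone{i + 1}" for i in range(self.n_clones)]

    @property
    def n_clones(self) -> int:
        return self.presence.shape[0]


@dataclass
class CloneClassification:
    #: per-clone infection pattern (sorted tuple of virus names)
    patterns: list[tuple[str, ...]]
    #: pattern -> count over clones
    census: dict[tuple[str, ...], int]
    heterogeneous: bool
    n_clones: int

    def summary(self) -> str:
        if self.heterogeneous:
            return (
                f"heterogeneous: {len(self.census)} distinct infection "
                f"patterns among {self.n_clones} clones"
            )
        return f"no heterogeneity detected at {self.n_clones} clones"


def classify_clones(screen: CloneScreen) -> CloneClassification:
    """Label each clone by its exact virus subset and tally the patterns."""
    patterns = []
    census: dict[tuple[str, ...], int] = {}
    for row in screen.presence:
        pat = tuple(sorted(v for v, x in zip(screen.viruses, row) if x))
        patterns.append(pat)
        census[pat] = census.get(pat, 0) + 1
    return CloneClassification(
        patterns=patterns,
        census=census,
        heterogeneous=len(census) >= 2,
        n_clones=screen.n_clones,
    )


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def fisher_exact_p(table: tuple[tuple[int, int], tuple[int, int]]) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Enumerates all 2x2 tables with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (the standard two-sided convention), with a small tolerance for
    floating-point ties.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


@dataclass
class MixtureEstimate:
    #: virus -> (positive clones, fraction, (ci_lo, ci_hi))
    fractions: dict[str, tuple[int, float, tuple[float, float]]]
    #: for the first two viruses: 2x2 clone table, odds ratio, Fisher p
    cooccurrence_table: tuple[tuple[int, int], tuple[int, int]] | None
    odds_ratio: float | None
    odds_ratio_corrected: float | None  # Haldane-Anscombe +0.5 fallback
    fisher_p: float | None


def mixture_estimate(screen: CloneScreen, conf: float = 0.95
                     ) -> MixtureEstimate:
    """Per-virus clone-positive fractions with exact CIs, plus a clone-level
    co-occurrence test for the first virus pair.

    A degenerate 2x2 margin makes the odds ratio undefined; the
    continuity-corrected (+0.5) value is reported alongside in that case.
    """
    n = screen.n_clones
    fractions = {}
    for i, v in enumerate(screen.viruses):
        k = int(screen.presence[:, i].sum())
        fractions[v] = (k, k / n, clopper_pearson(k, n, conf))

    table = orr = orr_c = p = None
    if len(screen.viruses) >= 2:
        x = screen.presence[:, 0]
        y = screen.presence[:, 1]
        a = int((x & y).sum())
        b = int((x & ~y).sum())
        c = int((~x & y).sum())
        d = int((~x & ~y).sum())
        table = ((a, b), (c, d))
        orr = (a * d) / (b * c) if b * c > 0 else (inf if a * d > 0 else None)
        if b * c == 0:
            orr_c = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        p = fisher_exact_p(table)
    return MixtureEstimate(
        fractions=fractions,
        cooccurrence_table=table,
        odds_ratio=orr if orr not in (inf,) else None,
        odds_ratio_corrected=orr_c,
        fisher_p=p,
    )
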
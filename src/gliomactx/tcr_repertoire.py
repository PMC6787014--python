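"""TCR-Vbeta repertoire dominance and convergence statistics.

From an immunoSEQ-style clone table (CDR3 nucleotide and amino-acid
sequences, read counts, productive flag) this module computes the three
repertoire summaries used to compare tumor groups: productive frequency
(the fraction of unique clonotypes without a premature stop codon), the
dominant-clone count (the smallest number of top clonotypes whose
cumulative read mass reaches 30%, a diversity measure — few clones
reaching 30% means a narrowed repertoire), and top-10 abundance (the
cumulative read share of the ten most frequent clonotypes, a convergence
measure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group_stats import mann_whitney_u

__all__ = [
    "Clone",
    "Repertoire",
    "RepertoireStats",
    "productive_frequency",
    "dominant_clone_count",
    "top_n_abundance",
    "repertoire_stats",
    "compare_repertoire_stats",
]

DEFAULT_DOMINANCE_THRESHOLD = 0.30
DEFAULT_TOP_N = 10


@dataclass(frozen=True)
class Clone:
    """One clonotype: unique CDR3 nucleotide rearrangement with read support."""

    cdr3_nt: str
    cdr3_aa: str
    read_count: int
    productive: bool
    vb_gene: str = ""

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.productive and "*" in self.cdr3_aa:
            raise ValueError(
                f"productive clone {self.cdr3_nt!r} has a stop in its CDR3"
            )


@dataclass
class Repertoire:
    sample_id: str
    group: str
    clones: list[Clone] = field(default_factory=list)

    def __post_init__(self) -> None:
        nts = [c.cdr3_nt for c in self.clones]
        if len(set(nts)) != len(nts):
            raise ValueError("duplicate cdr3_nt within repertoire")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, sample_id: str = "", group: str = ""
    ) -> "Repertoire":
        clones = [
            Clone(
                cdr3_nt=row.cdr3_nt,
                cdr3_aa=row.cdr3_aa,
                read_count=int(row.reads),
                productive=bool(row.productive),
            )
            for row in df.itertuples()
        ]
        return cls(sample_id=sample_id, group=group, clones=clones)

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clones)


@dataclass(frozen=True)
class RepertoireStats:
    sample_id: str
    group: str
    total_reads: int
    productive_frequency_pct: float
    dominant_clone_count: int
    top10_abundance_pct: float


def _productive_sorted(rep: Repertoire, denominator: str) -> list[Clone]:
    """Clones ranked by read count (desc), ties broken by CDR3-nt order."""
    pool = (
        [c for c in rep.clones if c.productive]
        if denominator == "productive"
        else list(rep.clones)
    )
    return sorted(pool, key=lambda c: (-c.read_count, c.cdr3_nt))


def productive_frequency(rep: Repertoire, weight_by_reads: bool = False) -> float:
    """Percent of unique clonotypes (or of reads) that are productive."""
    if not rep.clones:
        raise ValueError("productive frequency undefined for an empty repertoire")
    if weight_by_reads:
        total = rep.total_reads
        productive = sum(c.read_count for c in rep.clones if c.productive)
        return 100.0 * productive / total
    return 100.0 * sum(c.productive for c in rep.clones) / len(rep.clones)


def dominant_clone_count(
    rep: Repertoire,
    cumulative_threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    denominator: str = "productive",
) -> int:
    """Smallest k such that the k most frequent clones reach the threshold.

    Read fractions are over productive reads by default (``denominator=
    'all'`` includes nonproductive reads in both ranking and total). The
    clone whose addition crosses the threshold is counted (>= crossing).
    """
    if not (0 < cumulative_threshold <= 1):
        raise ValueError("cumulative_threshold must be in (0, 1]")
    pool = _productive_sorted(rep, denominator)
    if not pool:
        raise ValueError("dominant clone count undefined: no clones in denominator")
    total = sum(c.read_count for c in pool)
    cum = 0
    for k, clone in enumerate(pool, start=1):
        cum += clone.read_count
        if cum / total >= cumulative_threshold:
            return k
    return len(pool)


def top_n_abundance(
    rep: Repertoire, n: int = DEFAULT_TOP_N, denominator: str = "productive"
) -> float:
    """Cumulative read percentage of the n most frequent clones.

    100% whenever the repertoire has n clones or fewer.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = _productive_sorted(rep, denominator)
    if not pool:
        raise ValueError("top-n abundance undefined: no clones in denominator")
    total = sum(c.read_count for c in pool)
    top = sum(c.read_count for c in pool[:n])
    return 100.0 * top / total


def repertoire_stats(
    rep: Repertoire,
    cumulative_threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    top_n: int = DEFAULT_TOP_N,
    denominator: str = "productive",
) -> RepertoireStats:
    """All three repertoire summaries for one sample."""
    return RepertoireStats(
        sample_id=rep.sample_id,
        group=rep.group,
        total_reads=rep.total_reads,
        productive_frequency_pct=productive_frequency(rep),
        dominant_clone_count=dominant_clone_count(
            rep, cumulative_threshold, denominator
        ),
        top10_abundance_pct=top_n_abundance(rep, top_n, denominator),
    )


def compare_repertoire_stats(
    group_a: list[RepertoireStats], group_b: list[RepertoireStats]
) -> pd.DataFrame:
    """Mann-Whitney comparison of each repertoire statistic between groups."""
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    rows = []
    for stat in (
        "dominant_clone_count",
        "top10_abundance_pct",
        "productive_frequency_pct",
    ):
        a = np.array([getattr(s, stat) for s in group_a], dtype=float)
        b = np.array([getattr(s, stat) for s in group_b], dtype=float)
        if a.size < 2 or b.size < 2:
            warnings.warn(
                f"{stat}: degenerate group sizes ({a.size} vs {b.size}); "
                "p reported missing",
                stacklevel=2,
            )
            u, p = np.nan, np.nan
        else:
            u, p = mann_whitney_u(a, b)
        rows.append({"statistic": stat, "n_a": a.size, "n_b": b.size, "U": u, "p": p})
    return pd.DataFrame(rows)
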
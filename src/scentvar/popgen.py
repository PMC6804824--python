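"""Within-group diversity statistics for haplotype panels.

Nucleotide diversity pi is Nei's average number of pairwise differences per
site, haplotype diversity Hd the unbiased estimator n/(n-1) (1 - sum p_i^2),
and S the count of segregating columns.  Gaps ('-') and ambiguity codes ('N')
are treated as missing; the default missing-data policy is pairwise deletion
(each pair compared over its mutually observed sites), with complete deletion
available for sensitivity analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .variants import SequenceRecord

MISSING = {"-", "N"}


class PanelError(ValueError):
    pass


@dataclass
class HaplotypePanel:
    """Equal-length haplotype sequences for one isoform group."""

    group_label: str
    sequences: list[SequenceRecord]

    def __post_init__(self) -> None:
        lengths = {len(r.seq) for r in self.sequences}
        if len(lengths) > 1:
            raise PanelError(
                f"{self.group_label}: sequences must have equal length, got {sorted(lengths)}"
            )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0].seq) if self.sequences else 0

    def matrix(self) -> np.ndarray:
        return np.array([list(r.seq) for r in self.sequences])


@dataclass
class DiversityStats:
    group: str
    n: int
    L: int
    S: int
    pi: float
    n_haplotypes: int
    hd: float
    missing_policy: str = "pairwise"

    def summary_row(self) -> dict:
        """Table-formatted row: pi to 3 decimals, Hd to 2 (full precision kept here)."""
        return {
            "group": self.group,
            "n": self.n,
            "L": self.L,
            "S": self.S,
            "pi": round(self.pi, 3),
            "n_haplotypes": self.n_haplotypes,
            "hd": round(self.hd, 2),
            "missing_policy": self.missing_policy,
        }


def _observed_mask(mat: np.ndarray) -> np.ndarray:
    return ~np.isin(mat, list(MISSING))


def _complete_columns(mat: np.ndarray) -> np.ndarray:
    return mat[:, _observed_mask(mat).all(axis=0)]


def nucleotide_diversity(panel: HaplotypePanel, policy: str = "pairwise") -> float:
    """Mean over all unordered pairs of (pairwise differences / sites compared)."""
    if panel.n < 2:
        raise PanelError(f"{panel.group_label}: nucleotide diversity needs n >= 2")
    if policy not in ("pairwise", "complete"):
        raise PanelError(f"unknown missing-data policy {policy!r}")
    mat = panel.matrix()
    if policy == "complete":
        mat = _complete_columns(mat)
        if mat.shape[1] == 0:
            raise PanelError(f"{panel.group_label}: no complete columns to compare")
    obs = _observed_mask(mat)
    total = 0.0
    for i, j in combinations(range(panel.n), 2):
        both = obs[i] & obs[j]
        compared = int(both.sum())
        if compared == 0:
            raise PanelError(
                f"{panel.group_label}: pair ({i}, {j}) shares no comparable sites"
            )
        diffs = int((mat[i][both] != mat[j][both]).sum())
        total += diffs / compared
    return total / (panel.n * (panel.n - 1) / 2)


def haplotype_diversity(panel: HaplotypePanel) -> tuple[int, float]:
    """(number of distinct haplotypes, unbiased Hd = n/(n-1) (1 - sum p_i^2))."""
    if panel.n < 2:
        raise PanelError(f"{panel.group_label}: haplotype diversity needs n >= 2")
    counts = Counter(r.seq for r in panel.sequences)
    n = panel.n
    freq_sq = sum((c / n) ** 2 for c in counts.values())
    hd = n / (n - 1) * (1.0 - freq_sq)
    return len(counts), hd


def segregating_sites(panel: HaplotypePanel) -> int:
    """Columns with at least two distinct non-missing bases."""
    mat = panel.matrix()
    obs = _observed_mask(mat)
    s = 0
    for col in range(mat.shape[1]):
        bases = set(mat[obs[:, col], col])
        if len(bases) >= 2:
            s += 1
    return s


def diversity_stats(panel: HaplotypePanel, policy: str = "pairwise") -> DiversityStats:
    n_hap, hd = haplotype_diversity(panel)
    return DiversityStats(
        group=panel.group_label,
        n=panel.n,
        L=panel.length,
        S=segregating_sites(panel),
        pi=nucleotide_diversity(panel, policy=policy),
        n_haplotypes=n_hap,
        hd=hd,
        missing_policy=policy,
    )
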
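"""Pairwise Pearson correlation screening.

An exploratory screen over all n(n-1)/2 variable pairs: Pearson r with a
two-sided P value from the t distribution on m-2 degrees of freedom.
Pairs with |r| below a cutoff (default 0.1) are flagged as lacking a
usable linear relationship. By default the screen is reported as
metadata only; an optional mode restricts the edge candidates of the
structure search to the retained pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats

from .dataio import Dataset
from .errors import ConfigurationError, DataError

__all__ = ["PairCorrelation", "CorrelationReport", "pearson_matrix", "filter_pairs"]


@dataclass(frozen=True)
class PairCorrelation:
    a: str
    b: str
    r: float
    p: float


@dataclass(frozen=True)
class CorrelationReport:
    """All pairwise correlations plus the subset retained by the screen."""

    pairs: tuple[PairCorrelation, ...]
    threshold: float | None = None

    @property
    def retained(self) -> tuple[PairCorrelation, ...]:
        if self.threshold is None:
            return self.pairs
        return tuple(pc for pc in self.pairs if abs(pc.r) >= self.threshold)

    @property
    def discarded(self) -> tuple[PairCorrelation, ...]:
        if self.threshold is None:
            return ()
        return tuple(pc for pc in self.pairs if abs(pc.r) < self.threshold)

    def retained_pair_names(self) -> set[frozenset[str]]:
        return {frozenset((pc.a, pc.b)) for pc in self.retained}

    def to_frame(self) -> pd.DataFrame:
        thr = self.threshold
        return pd.DataFrame(
            {
                "pairA": [pc.a for pc in self.pairs],
                "pairB": [pc.b for pc in self.pairs],
                "r": [pc.r for pc in self.pairs],
                "p": [pc.p for pc in self.pairs],
                "retained": [
                    True if thr is None else abs(pc.r) >= thr for pc in self.pairs
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pearson_matrix(data: Dataset) -> CorrelationReport:
    """Pearson r and two-sided P for every unordered variable pair.

    P values come from the exact t distribution with m-2 degrees of
    freedom, as returned by :func:`scipy.stats.pearsonr`.
    """
    pairs = []
    for i, j in combinations(range(data.n), 2):
        x, y = data.column(i), data.column(j)
        if x.std() == 0 or y.std() == 0:
            raise DataError(
                f"constant column among {data.variables[i]!r}, {data.variables[j]!r}"
            )
        res = stats.pearsonr(x, y)
        pairs.append(
            PairCorrelation(
                data.variables[i], data.variables[j], float(res.statistic), float(res.pvalue)
            )
        )
    return CorrelationReport(tuple(pairs))


def filter_pairs(report: CorrelationReport, threshold: float = 0.1) -> CorrelationReport:
    """Apply the |r| >= threshold retention rule.

    The screen is sign-agnostic: a strong negative correlation is as
    much evidence of a linear relationship as a positive one.
    """
    if not 0 < threshold < 1:
        raise ConfigurationError(f"threshold must lie in (0, 1), got {threshold}")
    return CorrelationReport(report.pairs, threshold=threshold)
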
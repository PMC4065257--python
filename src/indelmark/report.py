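"""Classification summaries: counts and integer percentages per inbred pair.

Percentages are rounded half-up to integers, the convention used when
reporting marker panel success rates.  Markers where neither allele
amplified (FAILED) carry no genotype information and are tallied
separately, outside ``n_tested``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .pcr import MarkerClassification, Verdict


def percent(count: int, total: int) -> int:
    """Integer percentage, rounded half-up (49.5 -> 50, 49.03 -> 49)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass(frozen=True)
class PairSummary:
    """Counts and derived percentages for one inbred pair."""

    pair: str
    n_tested: int
    co_dominant: int
    pav: int
    dominant: int
    non_polymorphic: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.n_tested <= 0:
            raise ValueError(f"pair {self.pair}: n_tested must be positive")
        parts = self.co_dominant + self.pav + self.dominant + self.non_polymorphic
        if parts != self.n_tested:
            raise ValueError(
                f"pair {self.pair}: counts sum to {parts}, not n_tested={self.n_tested}"
            )

    @property
    def pct_co_dominant(self) -> int:
        return percent(self.co_dominant, self.n_tested)

    @property
    def pct_pav(self) -> int:
        return percent(self.pav, self.n_tested)

    @property
    def pct_dominant(self) -> int:
        return percent(self.dominant, self.n_tested)

    @property
    def pct_non_polymorphic(self) -> int:
        return percent(self.non_polymorphic, self.n_tested)

    @property
    def pct_polymorphic(self) -> int:
        return percent(self.n_tested - self.non_polymorphic, self.n_tested)

    @property
    def pct_single_allele(self) -> int:
        """Markers scoring only one allele in mixed DNA: PAV + dominant."""
        return percent(self.pav + self.dominant, self.n_tested)


@dataclass(frozen=True)
class ClassificationSummary:
    per_pair: tuple[PairSummary, ...]

    def pair(self, name: str) -> PairSummary:
        for p in self.per_pair:
            if p.pair == name:
                return p
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.per_pair:
            rows.append(
                {
                    "pair": p.pair,
                    "n_tested": p.n_tested,
                    "co_dominant": p.co_dominant,
                    "pav": p.pav,
                    "dominant": p.dominant,
                    "non_polymorphic": p.non_polymorphic,
                    "n_failed": p.n_failed,
                    "pct_co_dominant": p.pct_co_dominant,
                    "pct_pav": p.pct_pav,
                    "pct_dominant": p.pct_dominant,
                    "pct_non_polymorphic": p.pct_non_polymorphic,
                    "pct_polymorphic": p.pct_polymorphic,
                    "pct_single_allele": p.pct_single_allele,
                }
            )
        return pd.DataFrame(rows)


def summary_from_counts(
    pair: str,
    n_tested: int,
    co_dominant: int,
    pav: int,
    dominant: int,
    non_polymorphic: int,
) -> PairSummary:
    """Build a pair summary directly from tallied counts."""
    return PairSummary(
        pair=pair,
        n_tested=n_tested,
        co_dominant=co_dominant,
        pav=pav,
        dominant=dominant,
        non_polymorphic=non_polymorphic,
    )


def summarize(
    classifications: list[tuple[str, MarkerClassification]]
) -> ClassificationSummary:
    """Tally per-pair marker verdicts into counts and percentages.

    ``classifications`` pairs an inbred-pair label (e.g. "B73/Mo17") with
    one marker classification.  FAILED markers are excluded from
    ``n_tested`` but reported in ``n_failed``.
    """
    if not classifications:
        raise ValueError("no classifications to summarize")
    tallies: dict[str, dict[Verdict, int]] = {}
    for pair_name, cls in classifications:
        tallies.setdefault(pair_name, {v: 0 for v in Verdict})[cls.verdict] += 1
    summaries = []
    for pair_name, counts in tallies.items():
        n_tested = sum(v for k, v in counts.items() if k is not Verdict.FAILED)
        if n_tested == 0:
            raise ValueError(f"pair {pair_name}: every marker failed; nothing to summarize")
        summaries.append(
            PairSummary(
                pair=pair_name,
                n_tested=n_tested,
                co_dominant=counts[Verdict.CO_DOMINANT],
                pav=counts[Verdict.PAV],
                dominant=counts[Verdict.DOMINANT],
                non_polymorphic=counts[Verdict.NON_POLYMORPHIC],
                n_failed=counts[Verdict.FAILED],
            )
        )
    return ClassificationSummary(per_pair=tuple(summaries))
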
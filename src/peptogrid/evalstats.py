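"""Stratified-bootstrap Spearman evaluation of a score ranking against IC50s.

A raw Spearman correlation over a full activity library is dominated by
whichever potency decade happens to be most populated.  The protocol here
stratifies instead: the IC50 range (1–1000 μM by default) is divided into
five 200-μM-wide intervals, each bootstrap replicate draws five peptides
uniformly without replacement from every interval, and Spearman's rho is
computed between the method's ranking of the drawn peptides and their IC50
values.  1000 replicates give a distribution of rho whose median and
quartiles summarize how well the ranking tracks potency.

Sign convention: rank 1 is the best-scored peptide and low IC50 is the most
potent, so a ranking that tracks potency gives *positive* rho between rank
number and IC50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "BootstrapConfig",
    "CorrelationResult",
    "spearman_rho",
    "assign_interval",
    "stratified_bootstrap",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Stratified-bootstrap protocol parameters.

    Defaults follow the standard protocol: IC50 range 1–1000 μM split into
    five 200 μM intervals, five draws per interval, 1000 replicates.
    """

    ic50_range: tuple[float, float] = (1.0, 1000.0)
    n_intervals: int = 5
    interval_width: float = 200.0
    per_interval_draws: int = 5
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ic50_range
        if not (self.n_intervals > 0 and self.interval_width > 0
                and self.per_interval_draws > 0 and self.n_bootstrap > 0):
            raise ValueError("all protocol counts must be positive")
        span = self.n_intervals * self.interval_width
        if span < hi - lo:
            raise ValueError(
                f"{self.n_intervals} intervals of {self.interval_width} μM "
                f"do not span the IC50 range {self.ic50_range}"
            )


@dataclass
class CorrelationResult:
    """Bootstrap distribution of Spearman's rho."""

    coefficients: np.ndarray
    median: float = field(init=False)
    quartiles: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.median = float(np.median(self.coefficients))
        q1, q3 = np.percentile(self.coefficients, [25, 75])
        self.quartiles = (float(q1), float(q3))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def assign_interval(ic50: float, cfg: BootstrapConfig) -> int:
    """0-based interval index for an IC50, or -1 when out of range.

    Interval edges sit at multiples of the interval width (200, 400, ...
    μM by default); each interval is left-open/right-closed except the
    first, which is closed at the range lower bound: [1, 200], (200, 400],
    ... (800, 1000].
    """
    lo, hi = cfg.ic50_range
    if not (lo <= ic50 <= hi):
        return -1
    idx = int(np.ceil(ic50 / cfg.interval_width)) - 1
    return min(max(idx, 0), cfg.n_intervals - 1)


def stratified_bootstrap(
    ranks: Mapping[str, float],
    ic50s: Mapping[str, float],
    cfg: BootstrapConfig | None = None,
) -> CorrelationResult:
    """Bootstrap distribution of Spearman's rho between ranking and potency.

    Parameters
    ----------
    ranks
        Method ranking per peptide sequence (rank 1 = best; any monotone
        score with the same orientation works).
    ic50s
        Experimental IC50 per sequence, μM.  Only sequences present in both
        mappings and inside the configured range participate.

    Raises when any interval holds fewer peptides than ``per_interval_draws``
    (sampling is without replacement within a replicate).
    Bit-reproducible for a fixed ``cfg.seed``.
    """
    if cfg is None:
        cfg = BootstrapConfig()
    common = sorted(set(ranks) & set(ic50s))
    intervals: list[list[str]] = [[] for _ in range(cfg.n_intervals)]
    for seq in common:
        ib = assign_interval(float(ic50s[seq]), cfg)
        if ib >= 0:
            intervals[ib].append(seq)
    for i, members in enumerate(intervals):
        if len(members) < cfg.per_interval_draws:
            lo = cfg.ic50_range[0] if i == 0 else i * cfg.interval_width
            raise ValueError(
                f"interval {i} ({lo:g}–{(i + 1) * cfg.interval_width:g} μM) "
                f"holds {len(members)} peptides; need >= {cfg.per_interval_draws}"
            )
    rng = np.random.default_rng(cfg.seed)
    coeffs = np.empty(cfg.n_bootstrap)
    for b in range(cfg.n_bootstrap):
        drawn: list[str] = []
        for members in intervals:
            picked = rng.choice(len(members), size=cfg.per_interval_draws,
                                replace=False)
            drawn.extend(members[j] for j in picked)
        coeffs[b] = spearman_rho(
            [ranks[s] for s in drawn], [ic50s[s] for s in drawn]
        )
    return CorrelationResult(coefficients=coeffs)
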
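"""Binned chi-square comparison of fitted consumption models.

Observed drinker volumes are binned with a 10 g/day bandwidth up to
100 g/day plus an open top bin, expected bin masses come from each fitted
family's CDF, and the per-bin chi-square cells are summed into a total and
a below-100 subtotal.  The chi-square values are descriptive fit indices
for ranking families, not hypothesis tests; no p-values are produced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import FittedModel, cdf

__all__ = [
    "BinnedComparison",
    "default_bin_edges",
    "bin_observations",
    "expected_bin_fractions",
    "chi_square",
    "compare_families",
    "rank_families",
]

logger = logging.getLogger(__name__)

DEFAULT_BANDWIDTH = 10.0
DEFAULT_TOP_EDGE = 100.0


def default_bin_edges(bandwidth: float = DEFAULT_BANDWIDTH, top_edge: float = DEFAULT_TOP_EDGE) -> np.ndarray:
    """Edges 0, bandwidth, ..., top_edge, inf. Bins are half-open [lo, hi)."""
    if bandwidth <= 0 or top_edge <= 0:
        raise ValueError("bandwidth and top_edge must be positive")
    inner = np.arange(0.0, top_edge + bandwidth / 2, bandwidth)
    return np.append(inner, np.inf)


def bin_observations(
    volumes,
    bandwidth: float = DEFAULT_BANDWIDTH,
    top_edge: float = DEFAULT_TOP_EDGE,
) -> np.ndarray:
    """Count drinker volumes per half-open bin [lo, hi); top bin is [top_edge, inf)."""
    x = np.asarray(volumes, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bin an empty set of volumes")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("volumes must be finite and positive")
    edges = default_bin_edges(bandwidth, top_edge)
    # np.histogram closes the last bin, which is already [top_edge, inf)
    counts, _ = np.histogram(x, bins=edges)
    return counts.astype(int)


def expected_bin_fractions(model: FittedModel, bin_edges: Sequence[float]) -> np.ndarray:
    """Model probability mass per bin: F(hi) - F(lo); the open top bin gets 1 - F(top)."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with at least 2 entries")
    finite = edges[np.isfinite(edges)]
    probs = cdf(model.params, finite)
    probs = np.atleast_1d(probs)
    if np.isinf(edges[-1]):
        probs = np.append(probs, 1.0)
    fractions = np.diff(probs)
    return fractions


def chi_square(
    observed_counts,
    expected_fractions,
    n: int,
    sub_edge_index: int | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-bin chi-square cells plus total and below-top-bin subtotal.

    cell_i = (obs_i - n*frac_i)^2 / (n*frac_i).  ``sub_edge_index`` is the
    number of leading bins included in the subtotal (default: all but the
    open top bin).
    """
    obs = np.asarray(observed_counts, dtype=float)
    frac = np.asarray(expected_fractions, dtype=float)
    if obs.shape != frac.shape:
        raise ValueError("observed counts and expected fractions must align")
    if n <= 0:
        raise ValueError("n must be positive")
    if abs(frac.sum() - 1.0) > 1e-6:
        raise ValueError("expected fractions must sum to 1")
    expected = n * frac
    bad = (expected == 0) & (obs > 0)
    if np.any(bad):
        raise ValueError(f"expected count 0 in occupied bin(s) {np.nonzero(bad)[0].tolist()}")
    low = (expected > 0) & (expected < 5)
    if np.any(low):
        warnings.warn(
            f"{int(low.sum())} bin(s) have expected count < 5; chi-square cells may be unstable",
            stacklevel=2,
        )
    cells = np.zeros_like(obs)
    nz = expected > 0
    cells[nz] = (obs[nz] - expected[nz]) ** 2 / expected[nz]
    if sub_edge_index is None:
        sub_edge_index = len(cells) - 1
    return cells, float(cells.sum()), float(cells[:sub_edge_index].sum())


@dataclass
class BinnedComparison:
    """One stratum's observed bins against the fitted families' expectations."""

    bin_edges: np.ndarray
    observed_counts: np.ndarray
    expected_fractions: dict[str, np.ndarray]
    chi_sq_cells: dict[str, np.ndarray] = field(init=False)
    chi_sq_total: dict[str, float] = field(init=False)
    chi_sq_sub100: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.chi_sq_cells = {}
        self.chi_sq_total = {}
        self.chi_sq_sub100 = {}
        n = int(self.observed_counts.sum())
        for family, frac in self.expected_fractions.items():
            cells, total, sub = chi_square(self.observed_counts, frac, n)
            self.chi_sq_cells[family] = cells
            self.chi_sq_total[family] = total
            self.chi_sq_sub100[family] = sub

    @property
    def n_obs(self) -> int:
        return int(self.observed_counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per bin, columns per family (fit %, chi-square)."""
        edges = self.bin_edges
        labels = [
            f"{int(lo)} - {int(hi)}" if np.isfinite(hi) else f"{int(lo)} +"
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        n = self.n_obs
        data = {
            "bin": labels,
            "count": self.observed_counts,
            "empirical_pct": 100.0 * self.observed_counts / n,
        }
        for family in sorted(self.expected_fractions):
            data[f"{family}_fit_pct"] = 100.0 * self.expected_fractions[family]
        for family in sorted(self.chi_sq_cells):
            data[f"{family}_chisq"] = self.chi_sq_cells[family]
        return pd.DataFrame(data)


def compare_families(
    volumes,
    models: Mapping[str, FittedModel],
    bandwidth: float = DEFAULT_BANDWIDTH,
    top_edge: float = DEFAULT_TOP_EDGE,
) -> BinnedComparison:
    """Bin the data once and lay every fitted family's expectations beside it."""
    if not models:
        raise ValueError("need at least one fitted model")
    edges = default_bin_edges(bandwidth, top_edge)
    observed = bin_observations(volumes, bandwidth, top_edge)
    fractions = {name: expected_bin_fractions(m, edges) for name, m in models.items()}
    return BinnedComparison(bin_edges=edges, observed_counts=observed, expected_fractions=fractions)


def rank_families(comparison: BinnedComparison, by: str = "total") -> list[str]:
    """Families ordered best-fitting first; ties broken alphabetically.

    ``by`` is "total" (all bins) or "sub100" (bins below the open top bin).
    """
    if by == "total":
        scores = comparison.chi_sq_total
    elif by == "sub100":
        scores = comparison.chi_sq_sub100
    else:
        raise ValueError("by must be 'total' or 'sub100'")
    return sorted(scores, key=lambda fam: (scores[fam], fam))
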
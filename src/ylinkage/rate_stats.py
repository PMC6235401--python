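"""Exposure accounting and exact small-count statistics.

Event counts in this pipeline are tiny (tens of events over thousands of
gene-Myr), so everything here is exact rather than asymptotic:

* **Garwood interval** for a Poisson rate: with ``n`` events over exposure
  ``T``, the exact central 100(1-a)% CI is

      lower = chi2.ppf(a/2, 2n) / (2T),   upper = chi2.ppf(1 - a/2, 2n + 2) / (2T)

  (lower bound 0 when n = 0).
* **Exact test for the ratio of two Poisson means**: conditional on
  ``n1 + n2``, ``n1 ~ Binomial(n1 + n2, T1/(T1 + T2))`` under equal rates;
  the two-sided p-value sums outcomes whose point probability does not
  exceed the observed one (minimum-likelihood convention; tail-doubling
  available via ``method="double"``).
* **Fisher exact test** on a 2x2 table, two-sided by the same
  minimum-likelihood convention over the hypergeometric distribution with
  fixed margins.

Exposure (gene-Myr) is the total time during which genes are at risk: per
gene, the sum of branch lengths over branches whose parent node is
reconstructed Y-linked.  The branch on which a loss occurs is included in
full by default (the event time within the branch is unknown); a half-branch
convention is available as a sensitivity option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .event_inference import ContingencyTable2x2, Reconstruction
from .phylogeny import Phylogeny

#: Relative headroom when comparing point probabilities in minimum-likelihood
#: two-sided p-values, to keep ties stable under floating point.
_TIE_EPS = 1e-9


class ExposureError(ValueError):
    """Raised when exposure cannot be computed (missing branch lengths)."""


@dataclass(frozen=True)
class RateEstimate:
    """A Poisson rate with its exact (Garwood) confidence interval."""

    n_events: int
    exposure: float
    rate: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    method: str = "garwood"

    def as_dict(self) -> dict:
        return {
            "n": self.n_events,
            "exposure": self.exposure,
            "rate": self.rate,
            "ci": [self.ci_low, self.ci_high],
            "conf": self.conf_level,
            "method": self.method,
        }


@dataclass(frozen=True)
class TestResult:
    """An exact-test outcome."""

    p_value: float
    method: str
    statistic: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {"p": self.p_value, "method": self.method, "statistic": self.statistic}


def exposure(
    tree: Phylogeny,
    reconstructions: Sequence[Reconstruction],
    change_branch: str = "full",
) -> tuple[float, dict[str, float]]:
    """Total gene-Myr at risk, and the per-gene breakdown.

    A branch contributes to a gene's exposure when the gene is reconstructed
    Y-linked at the branch's parent node.  ``change_branch="full"`` counts
    branches on which the gene leaves the Y in full; ``"half"`` counts half
    their length.
    """
    if change_branch not in {"full", "half"}:
        raise ValueError("change_branch must be 'full' or 'half'")
    if not tree.has_branch_lengths:
        raise ExposureError(
            "tree has missing branch lengths; supply a dated tree or use the "
            "unit-branch-length flag (which disables rate reporting)"
        )
    per_gene: dict[str, float] = {}
    for rec in reconstructions:
        total = 0.0
        for parent, child in tree.edges():
            if rec.node_state[parent.id] != "Y":
                continue
            length = child.length
            if change_branch == "half" and rec.node_state[child.id] != "Y":
                length = length / 2.0
            total += length
        per_gene[rec.gene or "?"] = total
    return sum(per_gene.values()), per_gene


def poisson_rate_ci(n: int, T: float, conf: float = 0.95) -> RateEstimate:
    """Exact (Garwood) confidence interval for a Poisson rate n/T."""
    if n < 0 or int(n) != n:
        raise ValueError("event count must be a non-negative integer")
    if not T > 0:
        raise ValueError("exposure must be positive")
    if not (0 < conf < 1):
        raise ValueError("conf must be in (0, 1)")
    alpha = 1.0 - conf
    low = 0.0 if n == 0 else stats.chi2.ppf(alpha / 2.0, 2 * n) / (2.0 * T)
    high = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * n + 2) / (2.0 * T)
    return RateEstimate(
        n_events=int(n),
        exposure=float(T),
        rate=n / T,
        ci_low=float(low),
        ci_high=float(high),
        conf_level=conf,
    )


def incorporation_rate(n_inc: int, total_myr: float, conf: float = 0.95) -> RateEstimate:
    """Rate of whole-Y incorporations per Myr of evolution (exposure in Myr)."""
    est = poisson_rate_ci(n_inc, total_myr, conf=conf)
    return RateEstimate(
        n_events=est.n_events,
        exposure=est.exposure,
        rate=est.rate,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        conf_level=est.conf_level,
        method="garwood (per Myr)",
    )


def poisson_ratio_test(
    n1: int, T1: float, n2: int, T2: float, method: str = "minlike"
) -> TestResult:
    """Exact two-sided test of equal Poisson rates n1/T1 vs n2/T2.

    Conditions on the total count: under H0, n1 ~ Binomial(n1+n2, T1/(T1+T2)).
    ``method="minlike"`` (default) sums outcomes no more probable than the
    observed one; ``"double"`` doubles the smaller tail.
    """
    for n in (n1, n2):
        if n < 0 or int(n) != n:
            raise ValueError("counts must be non-negative integers")
    if n1 + n2 < 1:
        raise ValueError("need at least one event in total")
    if not (T1 > 0 and T2 > 0):
        raise ValueError("exposures must be positive")
    total = int(n1 + n2)
    p0 = T1 / (T1 + T2)
    pmf = stats.binom.pmf(np.arange(total + 1), total, p0)
    obs = pmf[int(n1)]
    if method == "minlike":
        p = float(pmf[pmf <= obs * (1.0 + _TIE_EPS)].sum())
    elif method == "double":
        lower = float(pmf[: int(n1) + 1].sum())
        upper = float(pmf[int(n1):].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError("method must be 'minlike' or 'double'")
    return TestResult(
        p_value=min(1.0, p),
        method=f"exact ratio of two Poisson means ({method})",
        statistic=float(n1),
    )


def fisher_exact_2x2(table: ContingencyTable2x2, method: str = "minlike") -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Enumerates every table with the observed margins; the p-value sums
    hypergeometric point probabilities not exceeding the observed one
    (minimum-likelihood convention — the convention under which the
    re-acquisition table (9,2;0,4) gives P = 0.011).  A zero margin leaves a
    single admissible table, so p = 1.
    """
    a, b, c, d = table.as_tuple()
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or row1 == total or col1 == 0 or col1 == total:
        return TestResult(p_value=1.0, method="fisher exact (degenerate margin)")
    lo = max(0, col1 - (total - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, col1, row1)
    obs = pmf[support == a][0]
    if method == "minlike":
        p = float(pmf[pmf <= obs * (1.0 + _TIE_EPS)].sum())
    elif method == "double":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError("method must be 'minlike' or 'double'")
    return TestResult(
        p_value=min(1.0, p),
        method=f"fisher exact two-sided ({method})",
        statistic=float(a),
    )
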
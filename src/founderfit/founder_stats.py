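"""Founder-allele and lineage-frequency statistics.

Utilities around the population-genetic side statistics of a founder-event
analysis: binomial simulation of how many founder alleles should be observed
in a small pseudo-haploid ancient cohort, exact two-tailed binomial and
Fisher tests for lineage carrier frequencies, and the analytic bound on
per-generation gene flow implied by a cumulative replacement fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact

__all__ = [
    "FounderAlleleTable",
    "AlleleCountDistribution",
    "simulate_observed_allele_count",
    "binomial_test_two_tailed",
    "fisher_exact_two_tailed",
    "per_generation_replacement_bound",
    "lineage_frequency",
    "filter_founder_alleles",
]


@dataclass(frozen=True)
class FounderAlleleTable:
    """Per-allele modern frequency and ancient genotyping depth.

    ``p[i]`` is the allele's frequency in the modern founder population;
    ``n[i]`` the number of ancient individuals genotyped at that site.
    Because ancient genotypes are pseudo-haploid (one random allele per
    site), each genotyped individual contributes a single binomial draw.
    """

    p: Tuple[float, ...]
    n: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.p) != len(self.n):
            raise ValueError("p and n must have equal length")
        if any(not 0 <= x <= 1 for x in self.p):
            raise ValueError("frequencies must be in [0, 1]")
        if any(x < 0 for x in self.n):
            raise ValueError("genotyped counts must be >= 0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FounderAlleleTable":
        return cls(tuple(df["p"].astype(float)), tuple(df["n_genotyped"].astype(int)))

    def __len__(self) -> int:
        return len(self.p)


@dataclass
class AlleleCountDistribution:
    """Simulated distribution of the number of observed founder alleles."""

    counts: np.ndarray
    percentile_interval: Tuple[float, float]
    mean: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "percentile_2.5": self.percentile_interval[0],
            "percentile_97.5": self.percentile_interval[1],
            "n_runs": len(self.counts),
        }


def simulate_observed_allele_count(
    table: FounderAlleleTable, n_runs: int = 10_000, seed: int = 0
) -> AlleleCountDistribution:
    """Simulate how many founder alleles appear in at least one individual.

    Per run, the ancient count for allele ``i`` is drawn as
    ``Binomial(n_i, p_i)`` (``n_i`` haploid draws — the pseudo-haploid
    convention); the statistic is the number of alleles with a non-zero
    draw.  Returns the empirical distribution with its [2.5, 97.5]
    percentile interval.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.asarray(table.p)
    n = np.asarray(table.n)
    draws = rng.binomial(n[None, :], p[None, :], size=(n_runs, len(table)))
    counts = (draws >= 1).sum(axis=1)
    lo, hi = np.percentile(counts, [2.5, 97.5])
    return AlleleCountDistribution(
        counts=counts,
        percentile_interval=(float(lo), float(hi)),
        mean=float(counts.mean()),
    )


def binomial_test_two_tailed(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test (method of small p-values)."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("require 0 < p0 < 1")
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher test on the 2x2 table ((a, b), (c, d))."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def per_generation_replacement_bound(total_fraction: float, generations: int) -> float:
    """Per-generation replacement rate implied by a cumulative fraction.

    Continuous gene flow replacing fraction ``m`` per generation for ``G``
    generations replaces ``X = 1 - (1 - m)^G`` in total; this returns the
    inverse, ``m = 1 - (1 - X)^{1/G}``.
    """
    if not 0 <= total_fraction < 1:
        raise ValueError("require 0 <= total_fraction < 1")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    return 1.0 - (1.0 - total_fraction) ** (1.0 / generations)


def lineage_frequency(carriers: int, total: int) -> float:
    """Carrier proportion ``k / n`` (report as a rounded percent)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= carriers <= total:
        raise ValueError("require 0 <= carriers <= total")
    return carriers / total


def format_percent(fraction: float) -> str:
    return f"{round(fraction * 100):d}%"


def filter_founder_alleles(
    df: pd.DataFrame,
    founder_freq_min: float = 0.005,
    outgroup_freq_max: float = 0.0001,
    regional_max_carriers: int = 1,
    min_genotyped: int = 3,
    detection_multiplier: Optional[str] = None,
) -> pd.DataFrame:
    """Predicate defining founder alleles over a user-supplied table.

    Expects columns ``founder_freq``, ``outgroup_freq``,
    ``regional_carriers`` and ``n_genotyped``; keeps minor alleles enriched
    in the founder population (frequency > ``founder_freq_min``), essentially
    absent in the outgroup (< ``outgroup_freq_max``), carried by at most
    ``regional_max_carriers`` regional reference individuals, and genotyped
    in at least ``min_genotyped`` ancient individuals.  If
    ``detection_multiplier`` names a column, it is retained for downstream
    per-allele detection-probability adjustment.
    """
    mask = (
        (df["founder_freq"] > founder_freq_min)
        & (df["outgroup_freq"] < outgroup_freq_max)
        & (df["regional_carriers"] <= regional_max_carriers)
        & (df["n_genotyped"] >= min_genotyped)
    )
    cols = ["founder_freq", "outgroup_freq", "regional_carriers", "n_genotyped"]
    if detection_multiplier:
        cols.append(detection_multiplier)
    return df.loc[mask, [c for c in df.columns if c in cols or c == "allele_id"]]
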
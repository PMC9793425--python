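"""Synthetic data with the statistical structure the analysis assumes.

Two generators are provided.  :func:`sample_counts` draws binned segment
counts directly as independent Poisson variables with the analytic means —
the same generative convention used by the parametric bootstrap.
:func:`simulate_segments_mc` is an independent Monte-Carlo oracle at the
segment level: per pair it draws a TMRCA from the coalescent distribution,
then scatters Poisson(2 u L) recombination breakpoints uniformly along each
chromosome and emits every inter-breakpoint interval as a segment.  The
TMRCA is held constant along the genome within a pair — the same
approximation the closed-form expectation makes, so the two routes must
agree (a full ancestral-recombination simulation would not match the
formula exactly).

:func:`generate_study` packages a matched modern-IBD + ancient-ROH study:
a modern cohort of 637 diploid genomes sampled today and an ancient cohort
of 16 individuals sampled 26 generations before present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .demography import (
    FOUNDER,
    IBD,
    ROH,
    Model,
    SamplingSpec,
    SinglePopModel,
    TwoPopModel,
    coalescent_pmf,
    model_from_dict,
    model_to_dict,
)
from .segments import (
    GenomeMap,
    LengthBins,
    SegmentCountTable,
    SegmentRecord,
    expected_bin_counts,
    pair_count,
)

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "sample_counts",
    "simulate_segments_mc",
    "simulate_binned_counts_mc",
    "generate_study",
]


def sample_counts(
    model: Model,
    sampling: SamplingSpec,
    genome: GenomeMap,
    bins: LengthBins,
    pairs: int,
    seed: int,
    n_individuals: Optional[int] = None,
) -> SegmentCountTable:
    """Poisson-distributed binned counts, ``K_b ~ Poisson(lambda_b)``."""
    rng = np.random.default_rng(seed)
    lam = expected_bin_counts(model, sampling, genome, bins, pairs)
    counts = rng.poisson(lam)
    return SegmentCountTable(
        counts=counts,
        pair_count=pairs,
        sampling=sampling,
        bins=bins,
        n_individuals=n_individuals,
    )


def _pair_interval_lengths(
    rng: np.random.Generator, a: np.ndarray, L: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Breakpoint-process intervals for many pairs on one chromosome.

    ``a`` is the per-Morgan breakpoint rate per pair (2 x TMRCA); ``L`` the
    chromosome length in Morgans.  Returns ``(owner, lengths)`` where each
    pair contributes ``n_breakpoints + 1`` intervals partitioning ``[0, L]``.
    """
    n = len(a)
    counts = rng.poisson(a * L)
    tot = int(counts.sum())
    owner_bp = np.repeat(np.arange(n), counts)
    pos = rng.random(tot) * L
    order = np.lexsort((pos, owner_bp))
    pos = pos[order]
    # lay out per pair: [sorted breakpoints..., L], then diff against the
    # previous position (0 at each pair's first slot)
    n_out = tot + n
    allpos = np.full(n_out, L, dtype=float)
    slot = np.arange(tot) + np.repeat(np.arange(n), counts)
    allpos[slot] = pos
    starts = np.concatenate(([0], np.cumsum(counts + 1)[:-1]))
    prev = np.empty(n_out)
    prev[1:] = allpos[:-1]
    prev[starts] = 0.0
    lengths = allpos - prev
    owner = np.repeat(np.arange(n), counts + 1)
    return owner, lengths


def _draw_tmrca(
    model: Model,
    sampling: SamplingSpec,
    rng: np.random.Generator,
    n_pairs: int,
    tmrca_fixed: Optional[float],
) -> np.ndarray:
    if tmrca_fixed is not None:
        return np.full(n_pairs, float(tmrca_fixed))
    pmf = coalescent_pmf(model, sampling)
    return pmf.sample(rng, n_pairs).astype(float)


def simulate_segments_mc(
    model: Model,
    sampling: SamplingSpec,
    genome: GenomeMap,
    n_pairs: int,
    seed: int,
    tmrca_fixed: Optional[float] = None,
    max_tmrca: Optional[float] = None,
) -> List[List[SegmentRecord]]:
    """Segment-level Monte-Carlo simulation; one record list per pair.

    ``max_tmrca`` suppresses segment emission for pairs with older
    coalescence; such pairs contribute essentially no segments above a few
    cM, so comparisons restricted to long segments are unaffected while the
    breakpoint process stays tractable.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    u = _draw_tmrca(model, sampling, rng, n_pairs, tmrca_fixed)
    active = np.ones(n_pairs, dtype=bool) if max_tmrca is None else u <= max_tmrca
    out: List[List[SegmentRecord]] = [[] for _ in range(n_pairs)]
    for p in np.flatnonzero(active):
        a = 2.0 * u[p]
        for c, L in enumerate(genome.lengths_morgans):
            k = int(rng.poisson(a * L))
            cuts = np.concatenate(([0.0], np.sort(rng.random(k) * L), [L]))
            for s, e in zip(cuts[:-1], cuts[1:]):
                out[p].append(
                    SegmentRecord(
                        sample=f"pair{p}",
                        chromosome=str(c + 1),
                        start_cm=s * 100.0,
                        end_cm=e * 100.0,
                        length_cm=(e - s) * 100.0,
                    )
                )
    return out


def simulate_binned_counts_mc(
    model: Model,
    sampling: SamplingSpec,
    genome: GenomeMap,
    bins: LengthBins,
    n_pairs: int,
    seed: int,
    tmrca_fixed: Optional[float] = None,
    max_tmrca: Optional[float] = None,
) -> np.ndarray:
    """Per-pair binned counts from the segment-level simulator.

    Returns an ``(n_pairs, n_bins)`` matrix, suitable for comparing bin
    means (and their standard errors) against the analytic expectation.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    u = _draw_tmrca(model, sampling, rng, n_pairs, tmrca_fixed)
    active = np.ones(n_pairs, dtype=bool) if max_tmrca is None else u <= max_tmrca
    a = 2.0 * u[active]
    idx_active = np.flatnonzero(active)
    edges = bins.edges_morgans
    mat = np.zeros((n_pairs, bins.n_bins), dtype=np.int64)
    for L in genome.lengths_morgans:
        owner, lengths = _pair_interval_lengths(rng, a, L)
        b = np.searchsorted(edges, lengths, side="right") - 1
        ok = (b >= 0) & (b < bins.n_bins) & (lengths < edges[-1])
        np.add.at(mat, (idx_active[owner[ok]], b[ok]), 1)
    return mat


@dataclass(frozen=True)
class StudyConfig:
    """Cohort sizes, sampling times, and generating model for a study.

    Defaults emulate the study conditions: a split/merge bottleneck
    (founder subgroup of 627 starting 46 generations ago, lasting 22,
    merge proportion 0.52), a modern cohort of 637 diploid genomes
    observed through IBD, and 16 ancient genomes sampled 26 generations
    before present observed through ROH.
    """

    model: Model = field(
        default_factory=lambda: TwoPopModel(
            N_a=5000.0, N_b=627.0, T_b=46.0, d=22.0, N_c=1e6, f=0.52
        )
    )
    modern_n: int = 637
    ancient_n: int = 16
    ancient_sample_time: float = 26.0
    consanguinity_fraction: float = 0.0
    ibd_bins: LengthBins = field(default_factory=LengthBins.default_ibd)
    roh_bins: LengthBins = field(default_factory=LengthBins.default_ancient_roh)
    genome: GenomeMap = field(default_factory=GenomeMap.default)

    @classmethod
    def single_pop_default(cls, **overrides) -> "StudyConfig":
        """Single-population bottleneck shaped like the modern-IBD fit."""
        model = overrides.pop(
            "model",
            SinglePopModel(N_a=5000.0, N_b=1563.0, T_b=41.0, d=20.0, N_c=1e6),
        )
        return cls(model=model, **overrides)

    def ibd_sampling(self) -> SamplingSpec:
        return SamplingSpec(sample_time=0.0, mode=IBD)

    def roh_sampling(self) -> SamplingSpec:
        return SamplingSpec(
            sample_time=self.ancient_sample_time,
            mode=ROH,
            consanguinity_fraction=self.consanguinity_fraction,
            subpop_assignment=FOUNDER if isinstance(self.model, TwoPopModel) else None,
        )


@dataclass
class SyntheticStudy:
    """A matched pair of modern-IBD and ancient-ROH count tables."""

    ibd: SegmentCountTable
    roh: SegmentCountTable
    model: Model
    config: StudyConfig
    seed: int

    def to_metadata(self) -> dict:
        return {
            "model": model_to_dict(self.model),
            "seed": self.seed,
            "modern_n": self.config.modern_n,
            "ancient_n": self.config.ancient_n,
            "ancient_sample_time": self.config.ancient_sample_time,
        }


def generate_study(config: Optional[StudyConfig] = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full synthetic study (modern IBD + ancient ROH counts)."""
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    seed_ibd = int(rng.integers(2**31 - 1))
    seed_roh = int(rng.integers(2**31 - 1))
    ibd = sample_counts(
        config.model,
        config.ibd_sampling(),
        config.genome,
        config.ibd_bins,
        pairs=pair_count(config.modern_n, IBD),
        seed=seed_ibd,
        n_individuals=config.modern_n,
    )
    roh = sample_counts(
        config.model,
        config.roh_sampling(),
        config.genome,
        config.roh_bins,
        pairs=pair_count(config.ancient_n, ROH),
        seed=seed_roh,
        n_individuals=config.ancient_n,
    )
    return SyntheticStudy(ibd=ibd, roh=roh, model=config.model, config=config, seed=seed)
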
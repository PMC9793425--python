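"""Expected IBD/ROH segment counts per length bin, and segment-table rules.

Conditional on a pair of haplotypes having separated ``t_sep`` generations
(``t_sep = u``, the TMRCA before sampling, so the two lineages accumulate
``a = 2 t_sep`` crossovers per Morgan), the number of shared segments of
genetic length ``l`` on a chromosome of map length ``L`` Morgans has density

    n(l) = [a^2 (L - l) + 2 a] exp(-a l),   0 < l < L,

plus an atom ``exp(-a L)`` at ``l = L`` (the whole chromosome shared).  The
density integrates in closed form via F(l) = exp(-a l) (a (l - L) - 1); the
expected total count over all lengths is ``1 + a L`` (breakpoints + 1).

All public interfaces take lengths in centimorgans; internal arithmetic is
in Morgans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .demography import (
    IBD,
    ROH,
    CoalescentPMF,
    Model,
    SamplingSpec,
    SinglePopModel,
    TwoPopModel,
    coalescent_pmf,
    two_pop_coalescent_pmf,
)

__all__ = [
    "GenomeMap",
    "LengthBins",
    "SegmentRecord",
    "SegmentCountTable",
    "expected_counts_given_tmrca",
    "expected_bin_counts",
    "pair_count",
    "merge_roh_gaps",
    "filter_high_roh_individuals",
    "bin_segments",
]

CM_PER_MORGAN = 100.0


@dataclass(frozen=True)
class GenomeMap:
    """Genetic lengths of the autosomes, in centimorgans."""

    lengths_cm: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.lengths_cm or any(L <= 0 for L in self.lengths_cm):
            raise ValueError("all chromosome lengths must be positive")

    @classmethod
    def default(cls) -> "GenomeMap":
        """The packaged 22-autosome sex-averaged map."""
        text = (
            resources.files("founderfit.data")
            .joinpath("genetic_map_autosomes.tsv")
            .read_text()
        )
        lengths = []
        for line in text.strip().splitlines()[1:]:
            _, L = line.split("\t")
            lengths.append(float(L))
        return cls(tuple(lengths))

    @property
    def lengths_morgans(self) -> np.ndarray:
        return np.asarray(self.lengths_cm) / CM_PER_MORGAN

    @property
    def total_cm(self) -> float:
        return float(sum(self.lengths_cm))


@dataclass(frozen=True)
class LengthBins:
    """Ordered half-open genetic-length bins ``[edge_i, edge_{i+1})`` in cM."""

    edges_cm: Tuple[float, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_cm)
        if len(edges) < 2:
            raise ValueError("need at least two edges")
        if edges[0] < 0:
            raise ValueError("minimum edge must be >= 0")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @classmethod
    def default_ibd(cls) -> "LengthBins":
        """11 one-cM bins on [4, 15) cM."""
        return cls(tuple(float(x) for x in range(4, 16)))

    @classmethod
    def default_ancient_roh(cls) -> "LengthBins":
        """One-cM bins on [4, 15) plus [15,20), [20,30), [30,40); 40-cM cap."""
        return cls(tuple(float(x) for x in range(4, 16)) + (20.0, 30.0, 40.0))

    @property
    def n_bins(self) -> int:
        return len(self.edges_cm) - 1

    @property
    def edges_morgans(self) -> np.ndarray:
        return np.asarray(self.edges_cm) / CM_PER_MORGAN


@dataclass
class SegmentRecord:
    """One detected IBD or ROH segment (cM coordinates).

    ``sample`` is the carrier individual (ROH) or the first member of the
    pair (IBD, with ``sample2`` set).
    """

    sample: str
    chromosome: str
    start_cm: float
    end_cm: float
    length_cm: float
    sample2: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.end_cm > self.start_cm:
            raise ValueError("end must exceed start")
        if abs((self.end_cm - self.start_cm) - self.length_cm) > 1e-6:
            raise ValueError("length inconsistent with start/end (tolerance 1e-6 cM)")


@dataclass
class SegmentCountTable:
    """Observed or simulated segment counts per genetic-length bin."""

    counts: np.ndarray
    pair_count: int
    sampling: SamplingSpec
    bins: LengthBins
    n_individuals: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.bins.n_bins:
            raise ValueError("counts length must equal number of bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.n_individuals is not None:
            expected = pair_count(self.n_individuals, self.sampling.mode)
            if expected != self.pair_count:
                raise ValueError(
                    f"pair_count {self.pair_count} inconsistent with "
                    f"n={self.n_individuals} in {self.sampling.mode} mode "
                    f"(expected {expected})"
                )


def pair_count(n: int, mode: str) -> int:
    """Number of haplotype pairs from ``n`` diploid individuals.

    IBD counts all between-individual (non-ROH) haplotype pairs,
    ``C(2n, 2) - n``; ROH counts the within-individual pair of each
    individual, ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == IBD:
        return math.comb(2 * n, 2) - n
    if mode == ROH:
        return n
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Closed-form expectations


def _expected_table(t_sep: np.ndarray, genome: GenomeMap, bins: LengthBins) -> np.ndarray:
    """Expected per-pair counts, shape ``(len(t_sep), n_bins)``."""
    a = 2.0 * np.asarray(t_sep, dtype=float)[:, None, None]  # (T,1,1)
    L = genome.lengths_morgans[None, :, None]  # (1,C,1)
    edges = bins.edges_morgans[None, None, :]  # (1,1,E)
    l = np.minimum(edges, L)
    F = np.exp(-a * l) * (a * (l - L) - 1.0)
    per_bin = F[..., 1:] - F[..., :-1]  # (T,C,B)
    # whole-chromosome atom: bin with lo <= L < hi
    lo, hi = edges[..., :-1], edges[..., 1:]
    atom_mask = (lo <= L) & (L < hi)
    atom = np.exp(-a * L) * atom_mask
    return (per_bin + atom).sum(axis=1)


def expected_counts_given_tmrca(
    t_sep: float, genome: GenomeMap, bins: LengthBins
) -> np.ndarray:
    """Expected per-pair segment counts per bin, conditional on the TMRCA.

    ``t_sep`` is the TMRCA in generations before sampling (>= 1); the pair's
    lineages carry ``a = 2 t_sep`` crossovers per Morgan.
    """
    if t_sep < 1:
        raise ValueError("t_sep must be >= 1 generation")
    return _expected_table(np.array([float(t_sep)]), genome, bins)[0]


# Cache of expectation tables, grown on demand: one likelihood search
# evaluates the same (genome, bins) at every candidate model.
_ETABLE_CACHE: Dict[Tuple[GenomeMap, LengthBins], np.ndarray] = {}


def _etable(genome: GenomeMap, bins: LengthBins, upto: int) -> np.ndarray:
    table = _ETABLE_CACHE.get((genome, bins))
    if table is None or len(table) < upto:
        n = max(upto, 256 if table is None else 2 * len(table))
        table = _expected_table(np.arange(1, n + 1, dtype=float), genome, bins)
        _ETABLE_CACHE[(genome, bins)] = table
    return table


def _u_horizon(model: Model, sampling: SamplingSpec, bins: LengthBins) -> int:
    """Truncation horizon for the TMRCA sum.

    Beyond ``u* = 60 / (2 l_min)`` the per-pair expectation in every bin is
    suppressed by at least ``exp(-60)``; the PMF is truncated there (but
    never before the ancestral epoch) and the remainder handled as the
    geometric tail.
    """
    l_min = float(bins.edges_morgans[0])
    if l_min <= 0:
        raise ValueError("expected_bin_counts requires a positive lowest bin edge")
    u_star = int(math.ceil(60.0 / (2.0 * l_min)))
    floor = int(math.ceil(model.T_b - sampling.sample_time)) + 10
    default = int(math.ceil(model.T_b + 5.0 * model.N_a - sampling.sample_time))
    return min(max(u_star, floor), max(default, floor))


def expected_bin_counts(
    model: Model,
    sampling: SamplingSpec,
    genome: GenomeMap,
    bins: LengthBins,
    pair_count: int,
    pmf: Optional[CoalescentPMF] = None,
) -> np.ndarray:
    """Expected segment counts per bin, marginalized over the TMRCA.

    ``lambda_b = P [ sum_u q(u) E_b(u) + tail ]`` where ``E_b(u)`` is the
    conditional expectation and the analytic geometric tail is summed in
    blocks until an increment falls below 1e-12 of the running total.
    """
    if pair_count < 1:
        raise ValueError("pair_count must be >= 1")
    if pmf is None:
        u_max = _u_horizon(model, sampling, bins)
        if isinstance(model, TwoPopModel):
            pmf = two_pop_coalescent_pmf(model, sampling, U_max=u_max)
        else:
            pmf = coalescent_pmf(model, sampling, U_max=u_max)
    U = pmf.u_max
    E = _etable(genome, bins, U)[:U]
    lam = np.zeros(bins.n_bins)
    running = 0.0
    block = 256
    t_post = model.T_b - sampling.sample_time  # no early stop before the ancestral epoch
    for s in range(0, U, block):
        e = min(s + block, U)
        contrib = pmf.q[s:e] @ E[s:e]
        lam += contrib
        c = float(contrib.sum())
        if s > t_post and running > 0 and c < 1e-12 * running:
            running += c
            break
        running += c
    # geometric tail beyond U
    r = pmf.tail_rate
    mass = pmf.tail_mass
    j = 0
    while mass > 0:
        w = mass * r * (1.0 - r) ** np.arange(block)
        Eb = _etable(genome, bins, U + (j + 1) * block)[U + j * block : U + (j + 1) * block]
        contrib = w @ Eb
        lam += contrib
        c = float(contrib.sum())
        mass *= (1.0 - r) ** block
        j += 1
        if c < 1e-12 * max(running, 1e-300) or mass < 1e-300:
            break
        running += c
    return pair_count * lam


# ---------------------------------------------------------------------------
# Segment-table post-processing


def merge_roh_gaps(segments: Sequence[SegmentRecord]) -> List[SegmentRecord]:
    """Merge short gaps between runs of homozygosity.

    Two adjacent ROH on the same sample and chromosome are merged (gap
    absorbed) when the gap is at most 0.5 cM, both segments are at least
    2 cM long, and at least one is at least 4 cM long.  Merging is applied
    iteratively left-to-right until stable, so a merged segment can seed a
    further merge.
    """
    if not segments:
        return []
    keys = {(s.sample, s.chromosome) for s in segments}
    if len(keys) > 1:
        raise ValueError("merge_roh_gaps expects one sample x chromosome group")
    recs = sorted(segments, key=lambda s: s.start_cm)
    for prev, nxt in zip(recs, recs[1:]):
        if nxt.start_cm < prev.end_cm:
            raise ValueError("overlapping input records")
    changed = True
    while changed:
        changed = False
        out: List[SegmentRecord] = [recs[0]]
        for rec in recs[1:]:
            prev = out[-1]
            gap = rec.start_cm - prev.end_cm
            if (
                gap <= 0.5
                and min(prev.length_cm, rec.length_cm) >= 2.0
                and max(prev.length_cm, rec.length_cm) >= 4.0
            ):
                out[-1] = SegmentRecord(
                    sample=prev.sample,
                    chromosome=prev.chromosome,
                    start_cm=prev.start_cm,
                    end_cm=rec.end_cm,
                    length_cm=rec.end_cm - prev.start_cm,
                    sample2=prev.sample2,
                )
                changed = True
            else:
                out.append(rec)
        recs = out
    return recs


def filter_high_roh_individuals(
    tables: Mapping[str, Sequence[SegmentRecord]],
    total_threshold: float = 50.0,
    min_len: float = 4.0,
) -> Tuple[Dict[str, List[SegmentRecord]], List[dict]]:
    """Drop individuals with excessive total ROH (likely related parents).

    An individual is excluded iff the summed length of its segments strictly
    longer than ``min_len`` cM strictly exceeds ``total_threshold`` cM.
    Returns the retained tables and an exclusion report.
    """
    retained: Dict[str, List[SegmentRecord]] = {}
    report: List[dict] = []
    for sample, segs in tables.items():
        total = sum(s.length_cm for s in segs if s.length_cm > min_len)
        if total > total_threshold:
            report.append({"sample": sample, "total_cm": total})
        else:
            retained[sample] = list(segs)
    return retained, report


def bin_segments(
    segments: Iterable[SegmentRecord], bins: LengthBins
) -> Tuple[np.ndarray, int]:
    """Count segments per half-open length bin; out-of-range segments dropped.

    Returns ``(counts, n_dropped)``.
    """
    edges = np.asarray(bins.edges_cm)
    lengths = np.asarray([s.length_cm for s in segments], dtype=float)
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    if len(lengths) == 0:
        return counts, 0
    idx = np.searchsorted(edges, lengths, side="right") - 1
    ok = (idx >= 0) & (idx < bins.n_bins) & (lengths < edges[-1])
    np.add.at(counts, idx[ok], 1)
    return counts, int((~ok).sum())
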
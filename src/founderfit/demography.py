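"""Piecewise demographic models and pairwise coalescence-time distributions.

The population-size history is a three-epoch piecewise model: a constant
ancestral size ``N_a`` until ``T_b`` generations before present, a bottleneck
of size ``N_b`` lasting ``d`` generations, and an exponential expansion from
the end of the bottleneck to the present-day size ``N_c``.  A two-population
variant splits the bottleneck epoch into two isolated subgroups (of sizes
``N_b`` and ``N_a - N_b``) that merge at the end of the bottleneck with
admixture proportion ``f``.

Time is discrete, in generations.  Generation ``u`` (counted from the
sampling time ``t_s``) spans the interval ``(u-1, u]`` and carries a
coalescence hazard ``h(u) = 1 / (2 N(t_s + u))`` where ``N`` is the diploid
effective size evaluated at the integer time ``t_s + u``.  Epoch boundaries
are older-closed: ``t = T_b`` belongs to the ancestral epoch and
``t = T_b - d`` to the bottleneck epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "IBD",
    "ROH",
    "SinglePopModel",
    "TwoPopModel",
    "SamplingSpec",
    "CoalescentPMF",
    "size_at",
    "coalescent_pmf",
    "two_pop_coalescent_pmf",
    "apply_consanguinity",
    "model_from_dict",
    "model_to_dict",
]

IBD = "ibd"
ROH = "roh"

#: subgroup labels for the split epoch of a two-population model
FOUNDER = "founder"  # the subgroup of size N_b (represented by the ancient sample)
OTHER = "other"  # the unsampled subgroup of size N_a - N_b


@dataclass(frozen=True)
class SinglePopModel:
    """Single-population bottleneck-then-expansion size history.

    Parameters
    ----------
    N_a : float
        Ancestral diploid effective size (``t >= T_b``).
    N_b : float
        Bottleneck diploid effective size (``T_b - d <= t < T_b``).
    T_b : float
        Onset of the bottleneck, generations before present.
    d : float
        Bottleneck duration in generations.
    N_c : float
        Present-day diploid effective size; the population grows
        exponentially from ``N_b`` at ``t = T_b - d`` to ``N_c`` at ``t = 0``.
    """

    N_a: float
    N_b: float
    T_b: float
    d: float
    N_c: float

    def __post_init__(self) -> None:
        if not self.N_a > 0:
            raise ValueError("N_a must be positive")
        if not (0 < self.N_b <= self.N_a):
            raise ValueError("require 0 < N_b <= N_a")
        if not (0 < self.d < self.T_b):
            raise ValueError("require 0 < d < T_b")
        if not self.N_c >= self.N_b:
            raise ValueError("require N_c >= N_b")

    @property
    def growth_start_size(self) -> float:
        return self.N_b


@dataclass(frozen=True)
class TwoPopModel:
    """Split/merge bottleneck model.

    At ``T_b`` generations before present the ancestral population (size
    ``N_a``) splits into a founder subgroup of size ``N_b`` and an unsampled
    subgroup of size ``N_a - N_b``.  The two merge at the end of the
    bottleneck with proportions ``f`` and ``1 - f`` and the merged pool grows
    exponentially from ``N_g`` to ``N_c``.  ``N_g`` defaults to ``N_b``.
    """

    N_a: float
    N_b: float
    T_b: float
    d: float
    N_c: float
    f: float
    N_g: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.N_a > 0:
            raise ValueError("N_a must be positive")
        if not (0 < self.N_b < self.N_a):
            raise ValueError("require 0 < N_b < N_a (other subgroup must be non-empty)")
        if not (0 < self.d < self.T_b):
            raise ValueError("require 0 < d < T_b")
        if not (0 < self.f < 1):
            raise ValueError("require 0 < f < 1")
        if self.N_g is None:
            object.__setattr__(self, "N_g", self.N_b)
        if not self.N_g > 0:
            raise ValueError("require N_g > 0")
        if not self.N_c >= self.N_g:
            raise ValueError("require N_c >= N_g")

    @property
    def growth_start_size(self) -> float:
        return float(self.N_g)


Model = Union[SinglePopModel, TwoPopModel]


@dataclass(frozen=True)
class SamplingSpec:
    """How a pair of haplotypes was sampled.

    ``mode`` is ``"ibd"`` for between-individual haplotype pairs or ``"roh"``
    for the two haplotypes within one individual.  ``sample_time`` is in
    generations before present (0 for modern cohorts).  In ROH mode the two
    lineages are forbidden from coalescing in the most recent
    ``no_recent_coalescence`` generations (no sib mating; default 2), and a
    consanguinity fraction ``kappa`` of individuals may carry a pedigree loop
    (first-cousin parents: coalescence with probability 1/16 exactly 3
    generations before sampling).
    """

    sample_time: float = 0.0
    mode: str = IBD
    no_recent_coalescence: Optional[int] = None
    consanguinity_fraction: float = 0.0
    pedigree_loop_time: int = 3
    pedigree_loop_prob: float = 1.0 / 16.0
    subpop_assignment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in (IBD, ROH):
            raise ValueError(f"mode must be '{IBD}' or '{ROH}', got {self.mode!r}")
        if self.sample_time < 0:
            raise ValueError("sample_time must be >= 0")
        if not 0 <= self.consanguinity_fraction <= 1:
            raise ValueError("consanguinity_fraction must be in [0, 1]")
        if not 0 <= self.pedigree_loop_prob <= 1:
            raise ValueError("pedigree_loop_prob must be in [0, 1]")
        if self.no_recent_coalescence is not None and self.no_recent_coalescence < 0:
            raise ValueError("no_recent_coalescence must be >= 0")
        if self.subpop_assignment not in (None, FOUNDER, OTHER):
            raise ValueError(f"subpop_assignment must be '{FOUNDER}' or '{OTHER}'")
        if self.consanguinity_fraction > 0 and self.mode != ROH:
            raise ValueError("consanguinity applies to ROH mode only")

    @property
    def nrc(self) -> int:
        """Effective number of recent generations with zero hazard."""
        if self.no_recent_coalescence is not None:
            return int(self.no_recent_coalescence)
        return 2 if self.mode == ROH else 0


@dataclass
class CoalescentPMF:
    """Discrete distribution of the pairwise TMRCA relative to sampling.

    ``q[u-1]`` is the probability that the pair coalesced exactly ``u``
    generations before sampling, for ``u = 1..U_max``.  ``tail_mass`` is the
    probability of coalescing later than ``U_max``; beyond the truncation the
    distribution is geometric with per-generation rate ``tail_rate``
    (``1 / (2 N_a)``, the hazard in the constant ancestral epoch).
    """

    q: np.ndarray
    tail_mass: float
    tail_rate: float
    sample_time: float = 0.0

    @property
    def u_max(self) -> int:
        return len(self.q)

    def total_mass(self) -> float:
        return float(self.q.sum() + self.tail_mass)

    def tail_pmf(self, n: int) -> np.ndarray:
        """Probability masses for ``u = U_max + 1 .. U_max + n``."""
        j = np.arange(1, n + 1)
        r = self.tail_rate
        return self.tail_mass * r * (1.0 - r) ** (j - 1)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw TMRCA values by inverse transform, tail included."""
        probs = np.append(self.q, self.tail_mass)
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        idx = rng.choice(len(probs), size=size, p=probs)
        u = idx + 1  # index U_max means "in the tail"
        in_tail = idx == self.u_max
        n_tail = int(in_tail.sum())
        if n_tail:
            u[in_tail] = self.u_max + rng.geometric(self.tail_rate, size=n_tail)
        return u.astype(np.int64)


def _merged_epoch_size(model: Model, t: np.ndarray) -> np.ndarray:
    """Size during the exponential epoch, N(t) = N_c (N_start/N_c)^{t/(T_b-d)}."""
    span = model.T_b - model.d
    n_start = model.growth_start_size
    return model.N_c * (n_start / model.N_c) ** (t / span)


def size_at(model: Model, t, subpop: Optional[str] = None):
    """Diploid effective size at time ``t`` (generations before present).

    For a :class:`TwoPopModel`, ``subpop`` selects the subgroup during the
    split epoch (``"founder"`` for the ``N_b`` group, ``"other"`` for the
    ``N_a - N_b`` group) and is required there.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = np.empty_like(t_arr)
    ancestral = t_arr >= model.T_b
    split = (t_arr >= model.T_b - model.d) & ~ancestral
    recent = ~ancestral & ~split
    out[ancestral] = model.N_a
    if isinstance(model, TwoPopModel):
        if split.any():
            if subpop == FOUNDER:
                out[split] = model.N_b
            elif subpop == OTHER:
                out[split] = model.N_a - model.N_b
            else:
                raise ValueError(
                    "subpop ('founder' or 'other') is required inside the "
                    "split epoch of a two-population model"
                )
    else:
        out[split] = model.N_b
    if recent.any():
        out[recent] = _merged_epoch_size(model, t_arr[recent])
    return float(out[0]) if scalar else out


def _default_u_max(model: Model, t_s: float) -> int:
    return int(math.ceil(model.T_b + 5.0 * model.N_a - t_s))


def _check_sizes(N: np.ndarray) -> None:
    if np.any(N < 1.0):
        raise ValueError(
            "effective size below 1 diploid individual (hazard > 0.5); "
            "model outside its regime of validity"
        )


def coalescent_pmf(
    model: SinglePopModel,
    sampling: SamplingSpec,
    U_max: Optional[int] = None,
) -> CoalescentPMF:
    """Pairwise TMRCA distribution under a single-population model.

    ``q(u) = h(u) prod_{v<u} (1 - h(v))`` with hazard ``h(u) = 1/(2 N(t_s+u))``
    zeroed for ``u <= no_recent_coalescence``; the mass beyond ``U_max``
    (default: 5 N_a generations past ``T_b``) is carried analytically as a
    geometric tail at rate ``1/(2 N_a)``.
    """
    if isinstance(model, TwoPopModel):
        return two_pop_coalescent_pmf(model, sampling, U_max)
    t_s = sampling.sample_time
    if U_max is None:
        U_max = _default_u_max(model, t_s)
    if not U_max + t_s > model.T_b:
        raise ValueError("U_max + sample_time must exceed T_b")
    u = np.arange(1, U_max + 1, dtype=float)
    N = size_at(model, t_s + u)
    _check_sizes(N)
    h = 1.0 / (2.0 * N)
    nrc = sampling.nrc
    if nrc > 0:
        h[: min(nrc, U_max)] = 0.0
    one_minus = 1.0 - h
    surv_prev = np.concatenate(([1.0], np.cumprod(one_minus)[:-1]))
    q = h * surv_prev
    tail = float(surv_prev[-1] * one_minus[-1])
    pmf = CoalescentPMF(q=q, tail_mass=tail, tail_rate=1.0 / (2.0 * model.N_a), sample_time=t_s)
    if sampling.consanguinity_fraction > 0:
        pmf = apply_consanguinity(pmf, sampling)
    return pmf


def two_pop_coalescent_pmf(
    model: TwoPopModel,
    sampling: SamplingSpec,
    U_max: Optional[int] = None,
) -> CoalescentPMF:
    """Pairwise TMRCA distribution under the split/merge model.

    During the split epoch two lineages can coalesce only if they occupy the
    same subgroup.  Going backward in time the computation tracks three
    states: both lineages in the founder subgroup (hazard ``1/(2 N_b)``),
    both in the other subgroup (hazard ``1/(2 (N_a - N_b))``), or split
    across the two (hazard 0).  Lineages sampled after the merge enter the
    split epoch in these states with probabilities ``(f^2, (1-f)^2,
    2 f (1-f))`` (independent assignment per lineage).  ROH lineages sampled
    within the split epoch occupy ``sampling.subpop_assignment`` throughout.
    """
    t_s = sampling.sample_time
    if U_max is None:
        U_max = _default_u_max(model, t_s)
    if not U_max + t_s > model.T_b:
        raise ValueError("U_max + sample_time must exceed T_b")
    u = np.arange(1, U_max + 1, dtype=float)
    t = t_s + u
    nrc = sampling.nrc
    hzero = u <= nrc

    merge_time = model.T_b - model.d
    m_idx = t < merge_time
    s_idx = (t >= merge_time) & (t < model.T_b)
    a_idx = t >= model.T_b

    q = np.zeros(U_max)
    together = 1.0

    if m_idx.any():
        Nm = _merged_epoch_size(model, t[m_idx])
        _check_sizes(Nm)
        h = 1.0 / (2.0 * Nm)
        h[hzero[m_idx]] = 0.0
        surv_prev = np.concatenate(([1.0], np.cumprod(1.0 - h)[:-1]))
        q[m_idx] = together * h * surv_prev
        together *= float(surv_prev[-1] * (1.0 - h[-1]))

    if s_idx.any():
        N_other = model.N_a - model.N_b
        _check_sizes(np.array([model.N_b, N_other]))
        if sampling.mode == ROH and t_s < model.T_b:
            if sampling.subpop_assignment is None:
                raise ValueError(
                    "ROH mode within the split epoch requires subpop_assignment"
                )
            entry = {FOUNDER: (1.0, 0.0, 0.0), OTHER: (0.0, 1.0, 0.0)}[
                sampling.subpop_assignment
            ]
        else:
            f = model.f
            entry = (f * f, (1.0 - f) ** 2, 2.0 * f * (1.0 - f))
        states = together * np.asarray(entry)
        k = int(s_idx.sum())
        H = np.tile(
            np.array([1.0 / (2.0 * model.N_b), 1.0 / (2.0 * N_other), 0.0]), (k, 1)
        )
        H[hzero[s_idx]] = 0.0
        surv_prev = np.vstack([np.ones(3), np.cumprod(1.0 - H, axis=0)[:-1]])
        q[s_idx] = (states * H * surv_prev).sum(axis=1)
        states = states * surv_prev[-1] * (1.0 - H[-1])
        together = float(states.sum())

    if a_idx.any():
        _check_sizes(np.array([model.N_a]))
        k = int(a_idx.sum())
        h = np.full(k, 1.0 / (2.0 * model.N_a))
        h[hzero[a_idx]] = 0.0
        surv_prev = np.concatenate(([1.0], np.cumprod(1.0 - h)[:-1]))
        q[a_idx] = together * h * surv_prev
        together *= float(surv_prev[-1] * (1.0 - h[-1]))

    pmf = CoalescentPMF(
        q=q, tail_mass=together, tail_rate=1.0 / (2.0 * model.N_a), sample_time=t_s
    )
    if sampling.consanguinity_fraction > 0:
        pmf = apply_consanguinity(pmf, sampling)
    return pmf


def apply_consanguinity(pmf: CoalescentPMF, sampling: SamplingSpec) -> CoalescentPMF:
    """Mix a pedigree-loop point mass into a TMRCA distribution.

    A fraction ``kappa`` of individuals are children of first cousins; such
    an individual's two haplotypes coalesce through the pedigree loop with
    probability ``pedigree_loop_prob`` (1/16) exactly ``pedigree_loop_time``
    (3) generations before sampling, and otherwise follow the population
    distribution.
    """
    if sampling.mode != ROH:
        raise ValueError("consanguinity applies to ROH mode only")
    kappa = sampling.consanguinity_fraction
    if kappa == 0:
        return pmf
    p_loop = sampling.pedigree_loop_prob
    t_loop = sampling.pedigree_loop_time
    if not 1 <= t_loop <= pmf.u_max:
        raise ValueError("pedigree_loop_time outside the PMF support")
    scale = 1.0 - kappa * p_loop
    q = pmf.q * scale
    q[t_loop - 1] += kappa * p_loop
    return CoalescentPMF(
        q=q,
        tail_mass=pmf.tail_mass * scale,
        tail_rate=pmf.tail_rate,
        sample_time=pmf.sample_time,
    )


# ---------------------------------------------------------------------------
# YAML-friendly (de)serialization


def model_to_dict(model: Model) -> dict:
    if isinstance(model, TwoPopModel):
        return {
            "model": "two_pop",
            "N_a": model.N_a,
            "N_b": model.N_b,
            "T_b": model.T_b,
            "d": model.d,
            "N_c": model.N_c,
            "f": model.f,
            "N_g": model.N_g,
        }
    return {
        "model": "single",
        "N_a": model.N_a,
        "N_b": model.N_b,
        "T_b": model.T_b,
        "d": model.d,
        "N_c": model.N_c,
    }


def model_from_dict(data: dict) -> Model:
    data = dict(data)
    kind = data.pop("model", "single")
    if kind == "single":
        return SinglePopModel(**data)
    if kind == "two_pop":
        return TwoPopModel(**data)
    raise ValueError(f"unknown model kind {kind!r}")


def sampling_to_dict(s: SamplingSpec) -> dict:
    return {
        "sample_time": s.sample_time,
        "mode": s.mode,
        "no_recent_coalescence": s.no_recent_coalescence,
        "consanguinity_fraction": s.consanguinity_fraction,
        "pedigree_loop_time": s.pedigree_loop_time,
        "pedigree_loop_prob": s.pedigree_loop_prob,
        "subpop_assignment": s.subpop_assignment,
    }


def sampling_from_dict(data: dict) -> SamplingSpec:
    return SamplingSpec(**data)
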
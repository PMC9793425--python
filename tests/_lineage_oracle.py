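"""Per-generation Monte-Carlo lineage-pair simulator (test oracle)."""

import numpy as np

import founderfit as ff


def mc_lineage_pmf(model, sampling, u_max, n_reps, seed):
    """Independent per-generation Monte-Carlo lineage-pair simulator.

    Tracks explicit subpopulation states and draws Bernoulli coalescence
    each generation; returns (counts per generation 1..u_max, n beyond).
    Oracle for the analytic survival-product PMFs.
    """
    rng = np.random.default_rng(seed)
    t_s = sampling.sample_time
    nrc = sampling.nrc
    two_pop = isinstance(model, ff.TwoPopModel)
    # lineage-pair state: 0 both-founder, 1 both-other, 2 split, 3 together
    if two_pop:
        merge_time = model.T_b - model.d
    coalesced_at = np.zeros(n_reps, dtype=np.int64)  # 0 = not yet
    state = np.full(n_reps, 3, dtype=np.int8)
    for u in range(1, u_max + 1):
        t = t_s + u
        active = coalesced_at == 0
        if not active.any():
            break
        if u <= nrc:
            continue
        if two_pop:
            in_split_epoch = merge_time <= t < model.T_b
            if in_split_epoch:
                newly = active & (state == 3)
                n_new = int(newly.sum())
                if n_new:
                    if sampling.mode == ff.demography.ROH and t_s < model.T_b:
                        target = {"founder": 0, "other": 1}[sampling.subpop_assignment]
                        state[newly] = target
                    else:
                        l1 = rng.random(n_new) < model.f
                        l2 = rng.random(n_new) < model.f
                        state[newly] = np.where(l1 & l2, 0, np.where(~l1 & ~l2, 1, 2))
            elif t >= model.T_b:
                state[active] = 3
        hazard = np.zeros(n_reps)
        if two_pop:
            N_t = {}
            for st in np.unique(state[active]):
                if st == 0:
                    N = model.N_b if (merge_time <= t < model.T_b) else None
                elif st == 1:
                    N = model.N_a - model.N_b if (merge_time <= t < model.T_b) else None
                elif st == 2:
                    N = None
                else:
                    N = ff.size_at(model, t) if not (merge_time <= t < model.T_b) else None
                mask = active & (state == st)
                hazard[mask] = 0.0 if N is None else 1.0 / (2.0 * N)
        else:
            N = ff.size_at(model, t)
            hazard[active] = 1.0 / (2.0 * N)
        hit = active & (rng.random(n_reps) < hazard)
        coalesced_at[hit] = u
    counts = np.bincount(coalesced_at[coalesced_at > 0], minlength=u_max + 1)[1:]
    beyond = int((coalesced_at == 0).sum())
    return counts, beyond
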
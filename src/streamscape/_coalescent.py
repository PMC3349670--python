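"""Batch single-population coalescent with stepwise microsatellite mutation.

All routines vectorize over independent replicate genealogies (replicates =
independent loci, or independent parameter draws in likelihood-free
inference), which is what makes rejection-style inference and
equilibrium-distribution simulation affordable.

Genealogies are built in two exchangeable halves:

1. interval durations while ``i`` lineages exist (``i = n, ..., 2``), drawn
   backward in time under the population-size trajectory;
2. topology and mutations laid down root-to-tip: starting from the root's
   two children, each interval mutates every active lineage, then a
   uniformly chosen lineage splits.  Uniform splitting reproduces the
   coalescent's uniform distribution over labelled histories.

Mutation is the stepwise model (SMM): +-1 repeat with equal probability, or
the two-phase generalization (TPM) where a mutation is multi-step with
probability ``p_multi`` and multi-step length ``1 + Geometric(q)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "constant_durations",
    "size_change_durations",
    "drop_mutations_smm",
    "drop_mutations_stepwise",
    "geometric_q_for_variance",
    "allele_summaries",
    "expected_het_smm",
]


def expected_het_smm(theta: float) -> float:
    """Equilibrium expected heterozygosity under the SMM, 1 - 1/sqrt(1+2*theta)."""
    return 1.0 - 1.0 / np.sqrt(1.0 + 2.0 * theta)


def geometric_q_for_variance(variance: float) -> float:
    """Geometric parameter q so that Var(multi-step length) = ``variance``.

    Multi-step mutations move ``1 + G`` repeats with ``G ~ Geometric(q)``
    (support 1, 2, ...), hence variance (1-q)/q**2.
    """
    if variance <= 0:
        return 1.0
    return (-1.0 + np.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)


# ------------------------------------------------------------- durations
def constant_durations(n_genes: int, size: int, rng) -> np.ndarray:
    """Interval durations in units of 2N generations, constant size.

    Column ``j`` is the interval while ``n_genes - j`` lineages exist.
    """
    i = np.arange(n_genes, 1, -1, dtype=float)
    rates = i * (i - 1) / 2.0
    return rng.exponential(1.0 / rates, size=(size, n_genes - 1))


def size_change_durations(n_genes, N0, N1, Ta, rng, size) -> np.ndarray:
    """Interval durations (generations) under exponential size change.

    Backward in time the diploid size follows
    ``N(t) = N0 * (N1/N0)**(t/Ta)`` for ``t <= Ta`` and ``N1`` beyond, so a
    pair of lineages coalesces at rate ``1 / (2 N(t))`` per generation.
    ``N0``, ``N1``, ``Ta`` may be scalars or arrays of length ``size``
    (independent trajectories per replicate). ``Ta = 0`` means the size is
    ``N1`` throughout.
    """
    N0 = np.broadcast_to(np.asarray(N0, dtype=float), (size,)).copy()
    N1 = np.broadcast_to(np.asarray(N1, dtype=float), (size,)).copy()
    Ta = np.broadcast_to(np.asarray(Ta, dtype=float), (size,)).copy()
    if (N0 <= 0).any() or (N1 <= 0).any() or (Ta < 0).any():
        raise ValueError("N0, N1 must be positive and Ta non-negative")
    # degenerate trajectory: constant at N1
    N0 = np.where(Ta == 0, N1, N0)
    Ta = np.where(Ta == 0, np.inf, Ta)  # beta -> 0, pure 'exponential' piece
    with np.errstate(over="ignore"):
        beta = np.where(np.isinf(Ta), 0.0, np.log(N0 / N1) / Ta)
    near_const = np.abs(np.log(N0 / N1)) < 1e-12
    beta = np.where(near_const, 0.0, beta)

    out = np.empty((size, n_genes - 1))
    t = np.zeros(size)
    for col, i in enumerate(range(n_genes, 1, -1)):
        c = i * (i - 1) / 2.0
        E = rng.exponential(1.0, size=size)
        # cumulative hazard from t to Ta within the exponential piece
        before = t < Ta
        with np.errstate(over="ignore", invalid="ignore"):
            ebt = np.exp(beta * t)
            ebTa = np.where(np.isinf(Ta), np.inf, np.exp(beta * Ta))
            lam_exp = np.where(
                beta != 0.0,
                c * (ebTa - ebt) / (2.0 * N0 * beta),
                c * (Ta - t) / (2.0 * N0),
            )
        lam_to_Ta = np.where(before, lam_exp, 0.0)
        within = before & (E <= lam_to_Ta)
        # solve inside the exponential piece
        with np.errstate(over="ignore", invalid="ignore"):
            t_exp = np.where(
                beta != 0.0,
                np.log(ebt + 2.0 * N0 * beta * E / c) / beta,
                t + 2.0 * N0 * E / c,
            )
        # overshoot into (or start within) the constant-ancestral piece
        with np.errstate(invalid="ignore"):
            E_rem = np.where(before, E - lam_to_Ta, E)
            start = np.where(before, Ta, t)
            t_const = start + 2.0 * N1 * E_rem / c
        t_new = np.where(within, t_exp, t_const)
        out[:, col] = t_new - t
        t = t_new
    return out


# ------------------------------------------------------------- mutations
def _topology_steps(durations):
    """Yield (i, column) pairs root-to-tip: i = 2 .. n active lineages."""
    n = durations.shape[1] + 1
    for i in range(2, n + 1):
        yield i, n - i


def drop_mutations_smm(durations, mu, rng, root=0) -> np.ndarray:
    """Tip alleles under the strict SMM (fast net-displacement path).

    ``durations``: (R, n-1) interval lengths; ``mu``: per-generation (or
    per-coalescent-unit) mutation rate per lineage, scalar or (R,).
    The net displacement of ``K`` single-step mutations is
    ``2*Binomial(K, 1/2) - K``, avoiding per-mutation draws.
    """
    R, nm1 = durations.shape
    n = nm1 + 1
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (R,))
    vals = np.zeros((R, n), dtype=np.int64)
    rows = np.arange(R)
    for i, col in _topology_steps(durations):
        lam = mu * durations[:, col]
        K = rng.poisson(lam[:, None], size=(R, i))
        vals[:, :i] += 2 * rng.binomial(K, 0.5) - K
        if i < n:
            pick = rng.integers(0, i, size=R)
            vals[:, i] = vals[rows, pick]
    return vals + int(root)


def drop_mutations_stepwise(durations, mu, rng, p_multi=0.0,
                            multi_step_variance=5.0, root=0) -> np.ndarray:
    """Tip alleles under the TPM, drawing every mutation individually.

    With ``p_multi = 0`` the per-mutation path still draws the (unused)
    multi-step lengths, so SMM run through this routine is bitwise
    reproducible as TPM with ``p_multi = 0`` under the same generator state.
    """
    R, nm1 = durations.shape
    n = nm1 + 1
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (R,))
    q = geometric_q_for_variance(multi_step_variance)
    vals = np.zeros((R, n), dtype=np.int64)
    rows = np.arange(R)
    for i, col in _topology_steps(durations):
        lam = mu * durations[:, col]
        K = rng.poisson(lam[:, None], size=(R, i))
        M = int(K.sum())
        if M:
            multi = rng.random(M) < p_multi
            geo = rng.geometric(q, size=M)
            sizes = np.where(multi, 1 + geo, 1)
            signs = 2 * rng.integers(0, 2, size=M) - 1
            cs = np.concatenate(([0], np.cumsum(signs * sizes)))
            ends = np.cumsum(K.ravel())
            vals[:, :i] += (cs[ends] - cs[ends - K.ravel()]).reshape(R, i)
        if i < n:
            pick = rng.integers(0, i, size=R)
            vals[:, i] = vals[rows, pick]
    return vals + int(root)


# ------------------------------------------------------------- summaries
def allele_summaries(alleles: np.ndarray) -> dict:
    """Per-replicate summaries of an (R, n_genes) allele-size array.

    Returns arrays ``k`` (distinct alleles), ``het`` (unbiased expected
    heterozygosity with the 2n/(2n-1) factor, gene-copy denominator),
    ``size_var`` (sample variance of repeat sizes, ddof=1), ``size_range``,
    ``m_ratio`` (k / (range + 1), alleles per occupied repeat span) and
    ``frac_rare`` (fraction of alleles with at most 2 copies — a
    frequency-spectrum signal that separates deep from shallow declines).
    """
    R, n = alleles.shape
    srt = np.sort(alleles, axis=1)
    new = np.empty((R, n), dtype=bool)
    new[:, 0] = True
    new[:, 1:] = srt[:, 1:] != srt[:, :-1]
    k = new.sum(axis=1)
    # run lengths = allele copy counts, flattened across rows
    idx = np.flatnonzero(new.ravel())
    counts = np.diff(np.append(idx, R * n))
    row_of_run = idx // n
    sum_sq = np.bincount(row_of_run, weights=counts.astype(float) ** 2,
                         minlength=R)
    sum_p2 = sum_sq / float(n) ** 2
    het = (n / (n - 1.0)) * (1.0 - sum_p2)
    size_range = srt[:, -1] - srt[:, 0]
    size_var = alleles.var(axis=1, ddof=1)
    m_ratio = k / (size_range + 1.0)
    rare_runs = np.bincount(row_of_run, weights=(counts <= 2).astype(float),
                            minlength=R)
    frac_rare = rare_runs / k
    return {"k": k, "het": het, "size_var": size_var,
            "size_range": size_range, "m_ratio": m_ratio,
            "frac_rare": frac_rare}
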
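"""Maximum-likelihood admixture estimation by EM on CNVR genotypes.

Model: individual i carries two allele copies per locus l. Each copy is
drawn by first choosing an ancestral component k with probability q_ik (the
individual's ancestry proportions) and then an allele a (a haploid copy
number in {0, 1, 2}) with probability p_lka, the component's allele
frequency. The log-likelihood is

    L(Q, P) = sum_{i,l,c} log( sum_k q_ik * p_{l,k,a_{ilc}} )

with missing copies contributing nothing. EM alternates copy-level
responsibilities r(k | i, l, c) with the closed-form updates

    q_ik  proportional to  sum_{l,c} r,       (per individual)
    p_lka proportional to  sum_{i,c: a_ilc=a} r   (per locus/component)

which never decrease L. This is the point-estimation counterpart of a
Bayesian admixture clustering run: the same likelihood, no priors and no
MCMC, with label switching resolved afterwards by
:func:`align_components`. Multiple seeded restarts guard against local
optima; the best-likelihood restart is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotype_coding import MISSING, GenotypeMatrix
from .io_formats import SampleManifest

N_ALLELES = 3  # haploid copy-number alphabet {0, 1, 2}


@dataclass
class AdmixtureFit:
    Q: pd.DataFrame               # individuals x K
    P: np.ndarray                 # loci x K x alleles
    loglik_trace: list[float]
    K: int
    seed: int | None
    converged: bool
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        q = self.Q.to_numpy()
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if not np.allclose(self.P.sum(axis=2), 1.0, atol=1e-8):
            raise ValueError("P allele slices must sum to 1")
        ll = np.asarray(self.loglik_trace)
        if ll.size > 1 and (np.diff(ll) < -1e-6).any():
            raise ValueError("log-likelihood trace must be non-decreasing")

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _prepare(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack the two allele copies; drop all-missing loci with a warning."""
    A = np.stack([genotypes.a1, genotypes.a2], axis=2)   # L x N x 2
    observed_locus = (A != MISSING).any(axis=(1, 2))
    if not observed_locus.all():
        dropped = [genotypes.loci[i] for i in np.nonzero(~observed_locus)[0]]
        warnings.warn(
            f"dropping {len(dropped)} all-missing loci: {dropped[:5]}...",
            stacklevel=3,
        )
    A = A[observed_locus]
    loci = [l for l, keep in zip(genotypes.loci, observed_locus) if keep]
    mask = A != MISSING                                   # L x N x 2
    return A, mask, loci


def _loglik_and_estep(
    A: np.ndarray, mask: np.ndarray, Q: np.ndarray, P: np.ndarray
) -> tuple[float, np.ndarray]:
    """Responsibilities R[l,k,i,c] and the current log-likelihood."""
    L, N, _ = A.shape
    K = Q.shape[1]
    safe_A = np.where(mask, A, 0)
    # gather P[l, k, a_{ilc}] -> (L, K, N, 2)
    PA = P[np.arange(L)[:, None, None, None],
           np.arange(K)[None, :, None, None],
           safe_A[:, None, :, :]]
    num = PA * Q.T[None, :, :, None]                      # L x K x N x 2
    denom = num.sum(axis=1, keepdims=True)                # L x 1 x N x 2
    obs = mask[:, None, :, :]
    ll = float(np.log(np.where(obs, denom, 1.0)).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(obs, num / np.where(denom > 0, denom, 1.0), 0.0)
    return ll, R


def _mstep(
    A: np.ndarray, mask: np.ndarray, R: np.ndarray,
    fixed_q: dict[int, np.ndarray] | None,
) -> tuple[np.ndarray, np.ndarray]:
    L, N, _ = A.shape
    K = R.shape[1]
    # Q update: responsibilities summed over loci and copies
    q_num = R.sum(axis=(0, 3)).T                          # N x K
    n_copies = mask.sum(axis=(0, 2)).astype(float)        # N
    Q = q_num / np.maximum(n_copies, 1.0)[:, None]
    Q /= Q.sum(axis=1, keepdims=True)
    if fixed_q:
        for i, q in fixed_q.items():
            Q[i] = q
    # P update: responsibilities scattered over observed alleles
    P = np.zeros((L, K, N_ALLELES))
    for a in range(N_ALLELES):
        sel = (A == a) & mask                             # L x N x 2
        P[:, :, a] = (R * sel[:, None, :, :]).sum(axis=(2, 3))
    totals = P.sum(axis=2, keepdims=True)
    P = np.where(totals > 0, P / np.where(totals > 0, totals, 1.0),
                 1.0 / N_ALLELES)
    return Q, np.clip(P, 1e-12, 1.0)


def fit_admixture(
    genotypes: GenotypeMatrix,
    K: int,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int | None = None,
    supervised: dict[str, int] | None = None,
) -> AdmixtureFit:
    """EM fit of ancestry proportions Q and component allele frequencies P.

    ``supervised`` optionally fixes named samples to pure ancestry from one
    component (Q row = unit vector); all other individuals are fit
    unsupervised, the default admixture model. The best of ``n_restarts``
    seeded restarts (Dirichlet(1,..,1) Q; P from perturbed observed allele
    frequencies) is returned; ``converged`` reports whether its final
    iteration improved the log-likelihood by less than ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > genotypes.n_samples:
        raise ValueError(
            f"K={K} exceeds the number of individuals ({genotypes.n_samples})"
        )
    A, mask, loci = _prepare(genotypes)
    L, N, _ = A.shape
    if L == 0:
        raise ValueError("no loci with observed genotypes")

    fixed_q: dict[int, np.ndarray] | None = None
    if supervised:
        fixed_q = {}
        index = {s: i for i, s in enumerate(genotypes.samples)}
        for sample, comp in supervised.items():
            if sample not in index:
                raise KeyError(f"supervised sample {sample!r} not in genotypes")
            if not 0 <= comp < K:
                raise ValueError(f"component {comp} outside [0, {K})")
            q = np.zeros(K)
            q[comp] = 1.0
            fixed_q[index[sample]] = q

    # observed allele frequencies per locus (for P initialization)
    base_freq = np.zeros((L, N_ALLELES))
    for a in range(N_ALLELES):
        base_freq[:, a] = ((A == a) & mask).sum(axis=(1, 2))
    base_freq /= np.maximum(base_freq.sum(axis=1, keepdims=True), 1.0)

    if K == 1:
        # closed form: Q is all ones; P is the observed allele frequencies
        Q = pd.DataFrame(np.ones((N, 1)), index=genotypes.samples,
                         columns=["K0"])
        P = np.clip(base_freq[:, None, :], 1e-12, 1.0)
        P /= P.sum(axis=2, keepdims=True)
        ll, _ = _loglik_and_estep(A, mask, np.ones((N, 1)), P)
        return AdmixtureFit(Q=Q, P=P, loglik_trace=[ll], K=1, seed=seed,
                            converged=True, loci=loci)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float], bool] | None = None
    for _ in range(max(1, n_restarts)):
        Q = rng.dirichlet(np.ones(K), size=N)
        if fixed_q:
            for i, q in fixed_q.items():
                Q[i] = q
        P = base_freq[:, None, :] * rng.uniform(0.5, 1.5, size=(L, K, N_ALLELES))
        P = np.clip(P, 1e-6, None)
        P /= P.sum(axis=2, keepdims=True)

        trace: list[float] = []
        converged = False
        for _it in range(max_iter):
            ll, R = _loglik_and_estep(A, mask, Q, P)
            if trace and ll - trace[-1] < tol:
                trace.append(max(ll, trace[-1]))
                converged = True
                break
            trace.append(ll)
            Q, P = _mstep(A, mask, R, fixed_q)
        else:
            ll, _ = _loglik_and_estep(A, mask, Q, P)
            trace.append(max(ll, trace[-1]))
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], Q, P, trace, converged)

    _, Q, P, trace, converged = best
    Q_df = pd.DataFrame(Q, index=genotypes.samples,
                        columns=[f"K{k}" for k in range(K)])
    return AdmixtureFit(Q=Q_df, P=P, loglik_trace=trace, K=K, seed=seed,
                        converged=converged, loci=loci)


def mean_ancestry_by_population(
    fit: AdmixtureFit, manifest: SampleManifest
) -> pd.DataFrame:
    """Arithmetic mean of Q rows per population; rows sum to 1."""
    pops = {}
    for sample in fit.Q.index:
        pops[sample] = manifest.population_of(sample)  # KeyError if unknown
    series = pd.Series(pops)
    return fit.Q.groupby(series).mean()


def align_components(
    fit: AdmixtureFit,
    manifest: SampleManifest,
    reference_populations: list[str],
) -> AdmixtureFit:
    """Permute components so reference population j dominates component j.

    Solves the optimal assignment maximizing the summed mean ancestry of
    each reference population on its assigned component; components beyond
    the references keep their relative order. Idempotent and deterministic.
    """
    K = fit.K
    if len(reference_populations) > K:
        raise ValueError(
            f"{len(reference_populations)} reference populations but K={K}"
        )
    means = mean_ancestry_by_population(fit, manifest)
    score = np.zeros((len(reference_populations), K))
    for r, pop in enumerate(reference_populations):
        if pop not in means.index:
            raise KeyError(f"population {pop!r} has no fitted samples")
        score[r] = means.loc[pop].to_numpy()
    rows, cols = linear_sum_assignment(-score)
    perm = [-1] * K
    for r, c in zip(rows, cols):
        perm[r] = int(c)
    leftover = [k for k in range(K) if k not in perm]
    for slot in range(K):
        if perm[slot] == -1:
            perm[slot] = leftover.pop(0)

    Q = fit.Q.to_numpy()[:, perm]
    P = fit.P[:, perm, :]
    return AdmixtureFit(
        Q=pd.DataFrame(Q, index=fit.Q.index,
                       columns=[f"K{k}" for k in range(K)]),
        P=P,
        loglik_trace=list(fit.loglik_trace),
        K=K,
        seed=fit.seed,
        converged=fit.converged,
        loci=list(fit.loci),
    )
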
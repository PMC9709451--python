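"""Consensus clustering of projected QTLs into meta-QTLs.

Model
-----
On each chromosome the projected QTL peaks x_1..x_n are treated as draws
from a K-component Gaussian mixture in which each observation carries
its own known standard deviation sigma_i, derived from its re-estimated
95% CI:

    x_i ~ sum_k pi_k * Normal(mu_k, sigma_i^2)

Only the cluster means mu_k and mixing proportions pi_k are free, so a
K-component model has nu = 2K - 1 free parameters.  The fit is by EM
with restarts; the E-step responsibilities are r_ik proportional to
pi_k * phi(x_i; mu_k, sigma_i), the M-step updates are the
precision-weighted means mu_k = sum_i r_ik x_i / sigma_i^2 /
sum_i r_ik / sigma_i^2 and pi_k = mean_i r_ik.

K is chosen per chromosome by a two-branch rule: with at most 10 QTLs
the model with the lowest AIC wins; with more, five information
criteria (AIC, AIC3, AICc, BIC, AWE) each vote for their minimising K
and the majority wins, ties going to the smaller K.

Each chosen cluster becomes an MQTL whose position is the cluster mean
and whose 95% CI follows from precision addition over its hard-assigned
members: CI = 3.92 * sqrt(1 / sum_i 1/sigma_i^2).  The MQTL CI is
therefore never wider than its narrowest member CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .ci import Z_95_WIDTH
from .consensus import ConsensusMap
from .projection import ProjectedQTL

#: Lower bound on per-QTL sigma (cM); avoids degenerate likelihood spikes.
SIGMA_FLOOR_CM = 0.1

DEFAULT_N_RESTARTS = 10
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_K_MAX = 10

#: QTL count at or below which the simpler single-criterion branch applies.
SMALL_N_BRANCH = 10

CRITERIA = ("aic", "aic3", "aicc", "bic", "awe")


@dataclass
class MixtureFit:
    """A converged EM fit of the known-variance Gaussian mixture."""

    chromosome: int
    K: int
    mu: np.ndarray
    pi: np.ndarray
    loglik: float
    loglik_classified: float
    n: int
    converged: bool
    n_iter: int
    seed: int
    responsibilities: np.ndarray = field(repr=False, default=None)
    empty_cluster_refit: bool = False

    @property
    def nu(self) -> int:
        """Free-parameter count: K means + K-1 independent proportions."""
        return 2 * self.K - 1


@dataclass(frozen=True)
class ModelScore:
    K: int
    aic: float
    aic3: float
    aicc: float
    bic: float
    awe: float


@dataclass
class SelectionRecord:
    """Chosen K plus the per-criterion votes that produced it."""

    K: int
    branch: str  # "aic_only" (n <= 10) or "majority_vote"
    votes: dict[str, int]


@dataclass
class MQTL:
    """A consensus cluster of co-locating QTLs."""

    name: str
    chromosome: int
    position_cm: float
    ci95_cm: float
    members: list[tuple[str, float]]  # (qtl_id, responsibility)
    traits: frozenset[str]
    n_qtls: int
    avg_pve: float  # percent
    flank_left: str | None = None
    flank_right: str | None = None

    @property
    def sigma_cm(self) -> float:
        return self.ci95_cm / Z_95_WIDTH


def _log_density_matrix(x: np.ndarray, sigma: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """log pi-free component densities, shape (n, K)."""
    z = (x[:, None] - mu[None, :]) / sigma[:, None]
    return -0.5 * z * z - np.log(sigma)[:, None] - 0.5 * math.log(2 * math.pi)


def _em_batch(
    x: np.ndarray,
    sigma: np.ndarray,
    mu0: np.ndarray,  # (R, K): one row of initial means per restart
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool, int]:
    """Run all restarts of EM simultaneously; return the best by loglik."""
    R, K = mu0.shape
    mu = mu0.astype(float).copy()
    pi = np.full((R, K), 1.0 / K)
    w = 1.0 / (sigma * sigma)  # per-observation precisions
    xs = x[None, :, None]
    ss = sigma[None, :, None]
    const = -np.log(sigma).sum() - 0.5 * x.size * math.log(2 * math.pi)
    prev_ll = np.full(R, -np.inf)
    done = np.zeros(R, dtype=bool)
    n_iter = np.zeros(R, dtype=int)
    for it in range(1, max_iter + 1):
        z = (xs - mu[:, None, :]) / ss
        log_num = -0.5 * z * z - np.log(ss) + np.log(pi)[:, None, :] \
            - 0.5 * math.log(2 * math.pi)
        m = log_num.max(axis=2, keepdims=True)
        log_norm = (m + np.log(np.exp(log_num - m).sum(axis=2, keepdims=True)))[..., 0]
        ll = log_norm.sum(axis=1)  # (R,)
        bad = ll < prev_ll - 1e-9 * np.maximum(1.0, np.abs(prev_ll))
        if np.any(bad & ~done):
            i = int(np.flatnonzero(bad & ~done)[0])
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it} "
                f"(restart {i}): {prev_ll[i]} -> {ll[i]}"
            )
        r = np.exp(log_num - log_norm[..., None])
        rw = r * w[None, :, None]
        denom = rw.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu_new = np.where(denom > 0, (rw * xs).sum(axis=1) / denom, mu)
        pi_new = np.clip(r.mean(axis=1), 1e-300, None)
        pi_new /= pi_new.sum(axis=1, keepdims=True)
        newly = (~done) & (prev_ll > -np.inf) & (
            np.abs(ll - prev_ll) <= tol * (np.abs(prev_ll) + 1e-12)
        )
        n_iter[newly] = it
        active = ~done
        mu[active] = mu_new[active]
        pi[active] = pi_new[active]
        prev_ll = np.where(active, ll, prev_ll)
        done = done | newly
        if done.all():
            break
    n_iter[~done] = max_iter
    # final E-step at the returned parameters of the best restart
    best = int(np.argmax(prev_ll))
    log_num = _log_density_matrix(x, sigma, mu[best]) + np.log(pi[best])[None, :]
    log_norm = logsumexp(log_num, axis=1)
    ll_best = float(log_norm.sum())
    r_best = np.exp(log_num - log_norm[:, None])
    return (mu[best], pi[best], ll_best, r_best, bool(done[best]), int(n_iter[best]))


def _quantile_init(x: np.ndarray, K: int) -> np.ndarray:
    qs = (np.arange(K) + 0.5) / K
    return np.quantile(x, qs)


def em_fit(
    positions: Sequence[float],
    sigmas: Sequence[float],
    K: int,
    seed: int,
    *,
    chromosome: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    sigma_floor: float = SIGMA_FLOOR_CM,
) -> MixtureFit:
    """Fit the K-component known-variance mixture by multi-start EM.

    One restart is quantile-initialised; the rest draw initial means
    from the data, seeded deterministically from ``seed``.  The best
    restart by log-likelihood wins, and the returned means are sorted
    ascending (proportions permuted accordingly).  A cluster left with
    no hard-assigned member triggers a refit at K-1, flagged on the
    result.
    """
    x = np.asarray(positions, dtype=float)
    s = np.maximum(np.asarray(sigmas, dtype=float), sigma_floor)
    if x.size != s.size:
        raise ValueError("positions and sigmas must have equal length")
    if not 1 <= K <= x.size:
        raise ValueError(f"K={K} must lie in [1, n={x.size}]")

    rng = np.random.default_rng(seed)
    inits = [_quantile_init(x, K)]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(np.sort(rng.choice(x, size=K, replace=K > x.size)))
    mu0 = np.stack(inits) + rng.normal(0.0, 1e-8, size=(len(inits), K))
    mu, pi, ll, r, converged, n_iter = _em_batch(x, s, mu0, tol, max_iter)
    order = np.argsort(mu)
    mu, pi, r = mu[order], pi[order], r[:, order]

    hard = np.argmax(r, axis=1)
    occupied = np.unique(hard)
    if occupied.size < K:
        refit = em_fit(
            x, s, K - 1, seed + 1, chromosome=chromosome, n_restarts=n_restarts,
            tol=tol, max_iter=max_iter, sigma_floor=sigma_floor,
        )
        refit.empty_cluster_refit = True
        return refit

    # classified (hard-assignment) complete-data log-likelihood, for AWE
    logphi = _log_density_matrix(x, s, mu)
    idx = np.arange(x.size)
    ll_c = float((logphi[idx, hard] + np.log(pi)[hard]).sum())

    return MixtureFit(
        chromosome=chromosome, K=K, mu=mu, pi=pi, loglik=ll,
        loglik_classified=ll_c, n=int(x.size), converged=converged,
        n_iter=n_iter, seed=seed, responsibilities=r,
    )


def score_models(fit: MixtureFit) -> ModelScore:
    """Information-criterion scores for one fitted K.

    AIC = -2lnL + 2nu; AIC3 = -2lnL + 3nu; AICc adds the small-sample
    correction 2nu(nu+1)/(n-nu-1) (infinite when n <= nu+1); BIC =
    -2lnL + nu ln n; AWE = -2lnL_c + 2nu(3/2 + ln n) uses the
    classified log-likelihood.
    """
    nu = fit.nu
    n = fit.n
    m2ll = -2.0 * fit.loglik
    aic = m2ll + 2.0 * nu
    aic3 = m2ll + 3.0 * nu
    aicc = aic + 2.0 * nu * (nu + 1) / (n - nu - 1) if n - nu - 1 > 0 else math.inf
    bic = m2ll + nu * math.log(n)
    awe = -2.0 * fit.loglik_classified + 2.0 * nu * (1.5 + math.log(n))
    return ModelScore(K=fit.K, aic=aic, aic3=aic3, aicc=aicc, bic=bic, awe=awe)


def select_model(scores: Sequence[ModelScore], n: int) -> SelectionRecord:
    """Choose K by the two-branch rule.

    Branch A (n <= 10): minimal AIC.  Branch B (n > 10): each of the
    five criteria votes for its minimising K; the K with most votes
    wins, ties resolved toward the smaller K.
    """
    if not scores:
        raise ValueError("empty score list")
    ordered = sorted(scores, key=lambda sc: sc.K)
    if n <= SMALL_N_BRANCH:
        k_best = min(ordered, key=lambda sc: (sc.aic, sc.K)).K
        return SelectionRecord(K=k_best, branch="aic_only",
                               votes={"aic": k_best})
    votes: dict[str, int] = {}
    for crit in CRITERIA:
        votes[crit] = min(ordered, key=lambda sc: (getattr(sc, crit), sc.K)).K
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    k_best = min(tally, key=lambda k: (-tally[k], k))
    return SelectionRecord(K=k_best, branch="majority_vote", votes=votes)


def _flanking_markers(
    consensus: ConsensusMap | None, chromosome: int, lo: float, hi: float
) -> tuple[str | None, str | None]:
    """Nearest consensus markers strictly outside [lo, hi]; chromosome
    terminal markers when the interval reaches past the ends."""
    if consensus is None:
        return None, None
    entries = consensus.chromosome_entries(chromosome)
    if not entries:
        return None, None
    left = None
    for e in entries:
        if e.pos_cm < lo:
            left = e.marker
        else:
            break
    right = next((e.marker for e in entries if e.pos_cm > hi), None)
    return left or entries[0].marker, right or entries[-1].marker


def build_mqtls(
    fit: MixtureFit,
    projected: Sequence[ProjectedQTL],
    consensus: ConsensusMap | None = None,
    *,
    sigma_floor: float = SIGMA_FLOOR_CM,
) -> list[MQTL]:
    """Turn a chosen fit into named MQTLs with precision-addition CIs.

    Members are hard-assigned by maximum responsibility; each member's
    responsibility for its cluster is retained as its percent
    membership.  Names run MQTL{chr}.{k} by ascending position.
    """
    if len(projected) != fit.n:
        raise ValueError("fit and projected QTL list disagree in length")
    r = fit.responsibilities
    hard = np.argmax(r, axis=1)
    sigmas = np.maximum(np.array([p.sigma_cm for p in projected]), sigma_floor)
    mqtls: list[MQTL] = []
    rank = 0
    for k in range(fit.K):
        idx = np.flatnonzero(hard == k)
        if idx.size == 0:
            continue
        rank += 1
        members = [(projected[i].qtl_id, float(r[i, k])) for i in idx]
        precision = float(np.sum(1.0 / sigmas[idx] ** 2))
        ci = Z_95_WIDTH * math.sqrt(1.0 / precision)
        pos = float(fit.mu[k])
        traits = frozenset(projected[i].trait for i in idx)
        avg_pve = float(np.mean([projected[i].pve for i in idx])) * 100.0
        fl, fr = _flanking_markers(consensus, fit.chromosome, pos - ci / 2, pos + ci / 2)
        mqtls.append(MQTL(
            name=f"MQTL{fit.chromosome}.{rank}",
            chromosome=fit.chromosome,
            position_cm=pos,
            ci95_cm=ci,
            members=members,
            traits=traits,
            n_qtls=int(idx.size),
            avg_pve=avg_pve,
            flank_left=fl,
            flank_right=fr,
        ))
    return mqtls


@dataclass
class ChromosomeResult:
    chromosome: int
    mqtls: list[MQTL]
    fits: list[MixtureFit]
    scores: list[ModelScore]
    selection: SelectionRecord


def run_chromosome(
    projected: Sequence[ProjectedQTL],
    *,
    seed: int,
    consensus: ConsensusMap | None = None,
    k_max: int = DEFAULT_K_MAX,
    n_restarts: int = DEFAULT_N_RESTARTS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    sigma_floor: float = SIGMA_FLOOR_CM,
) -> ChromosomeResult:
    """Fit K = 1..K_max on one chromosome, select K, and build MQTLs.

    K_max is capped at min(n, k_max).  Restart seeds for each K are
    derived deterministically from ``seed`` and the chromosome.
    """
    if not projected:
        raise ValueError("no projected QTLs")
    chrom = projected[0].chromosome
    if any(p.chromosome != chrom for p in projected):
        raise ValueError("projected QTLs span multiple chromosomes")
    x = [p.peak_cons_cm for p in projected]
    s = [p.sigma_cm for p in projected]
    n = len(x)
    fits: list[MixtureFit] = []
    scores: list[ModelScore] = []
    ss = np.random.SeedSequence(entropy=(seed, chrom))
    k_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(min(n, k_max))]
    for K in range(1, min(n, k_max) + 1):
        fit = em_fit(
            x, s, K, k_seeds[K - 1], chromosome=chrom, n_restarts=n_restarts,
            tol=tol, max_iter=max_iter, sigma_floor=sigma_floor,
        )
        if fit.K != K:  # empty-cluster refit collapsed onto a smaller K
            continue
        fits.append(fit)
        scores.append(score_models(fit))
    selection = select_model(scores, n)
    chosen = next(f for f in fits if f.K == selection.K)
    mqtls = build_mqtls(chosen, projected, consensus, sigma_floor=sigma_floor)
    return ChromosomeResult(
        chromosome=chrom, mqtls=mqtls, fits=fits, scores=scores, selection=selection
    )


def run_all_chromosomes(
    projected: Sequence[ProjectedQTL],
    *,
    seed: int,
    consensus: ConsensusMap | None = None,
    **kwargs,
) -> dict[int, ChromosomeResult]:
    """Cluster every chromosome present in the projected set."""
    chroms = sorted({p.chromosome for p in projected})
    out: dict[int, ChromosomeResult] = {}
    for chrom in chroms:
        subset = [p for p in projected if p.chromosome == chrom]
        out[chrom] = run_chromosome(subset, seed=seed, consensus=consensus, **kwargs)
    return out
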
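"""Model-based clustering of dominant markers with Evanno delta-K selection.

A lightweight Bayesian admixture model tailored to 0/1 band data: each
individual ``i`` carries membership proportions ``q_i ~ Dirichlet(1,...,1)``
over ``K`` clusters; each band observation draws a latent cluster of origin
``z_ij ~ Categorical(q_i)`` and then a score ``x_ij ~ Bernoulli(theta[z,j])``
with per-cluster band frequencies ``theta ~ Beta(1,1)``.  Bands are modelled
directly as Bernoulli characters — there is no attempt to back-calculate a
recessive null allele — which matches how dominant matrices are scored and
keeps every update conjugate.

Inference is collapsed-free Gibbs sampling (z, q, theta in turn).  The
per-sweep data log-likelihood, with z integrated out,

    L = sum_ij log sum_k q_ik * theta_kj^x_ij * (1 - theta_kj)^(1-x_ij)

is averaged over post-burn-in sweeps; repeating the fit over a grid of K
with several independent runs per K feeds the Evanno ad hoc statistic

    deltaK(K) = mean_runs |L(K+1) - 2 L(K) + L(K-1)| / SD_runs(L(K))

whose interior argmax estimates the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import BandMatrix

__all__ = [
    "AdmixtureModel",
    "AdmixtureFit",
    "DeltaKTable",
    "fit_admixture",
    "run_grid",
    "evanno_delta_k",
]

DEFAULT_ITERATIONS = 2000
DEFAULT_BURNIN = 500


@dataclass(frozen=True)
class AdmixtureFit:
    """Posterior summaries of one admixture run at fixed K."""

    K: int
    q: pd.DataFrame  # individuals x K posterior-mean memberships
    theta: np.ndarray  # K x n_bands posterior-mean band frequencies
    mean_loglik: float
    loglik_trace: np.ndarray  # post-burn-in per-sweep log-likelihoods
    seed: int
    burnin: int
    iterations: int

    def modal_assignment(self) -> pd.Series:
        """Hard cluster per individual (argmax of posterior-mean membership)."""
        return self.q.idxmax(axis=1)

    def summary(self) -> str:
        counts = self.modal_assignment().value_counts().sort_index()
        return (
            f"Admixture fit K={self.K}: mean log-likelihood "
            f"{self.mean_loglik:.2f} over {len(self.loglik_trace)} kept sweeps "
            f"({self.iterations} total, {self.burnin} burn-in, seed {self.seed})\n"
            f"modal cluster sizes: {counts.to_dict()}"
        )


class AdmixtureModel:
    """Admixture mixture model for one band matrix at fixed K.

    ``AdmixtureModel(m, K).fit(...)`` returns an :class:`AdmixtureFit`; the
    module-level :func:`fit_admixture` is a one-call convenience wrapper.
    """

    def __init__(self, m: BandMatrix, K: int) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > m.n_individuals:
            raise ValueError(
                f"K={K} exceeds the number of individuals ({m.n_individuals})"
            )
        self.m = m
        self.K = K
        self._x = m.scores.astype(np.float64)

    def fit(
        self,
        iterations: int = DEFAULT_ITERATIONS,
        burnin: int = DEFAULT_BURNIN,
        seed: int | None = None,
    ) -> AdmixtureFit:
        if not iterations > burnin >= 0:
            raise ValueError("need iterations > burnin >= 0")
        seed_int = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(seed_int)
        # float32 internals: theta lives well inside (0,1) and the sweep is
        # memory-bound, so single precision halves traffic at no statistical
        # cost; log-likelihoods are accumulated in float64.
        dtype = np.float32
        x = self._x.astype(dtype)
        n, j = x.shape
        k = self.K
        q = np.full((n, k), 1.0 / k, dtype=dtype)
        theta = rng.beta(1.0, 1.0, size=(k, j)).astype(dtype)
        row_idx = np.repeat(np.arange(n), j)
        col_idx = np.tile(np.arange(j), n)
        x_flat = self._x.ravel()

        kept = iterations - burnin
        trace = np.empty(kept)
        q_sum = np.zeros((n, k))
        theta_sum = np.zeros((k, j))
        p = np.empty((k, n, j), dtype=dtype)  # cluster-major: contiguous slabs
        for sweep in range(iterations):
            # per-(k,i,j) joint weight q_ik * theta^x (1-theta)^(1-x); for x
            # in {0,1} the Bernoulli factor is (1-theta) + x*(2*theta - 1)
            for kk in range(k):
                pk = p[kk]
                np.multiply(x, 2.0 * theta[kk] - 1.0, out=pk)
                pk += 1.0 - theta[kk]
                pk *= q[:, kk, None]
            tot = p.sum(axis=0)
            if sweep >= burnin:
                trace[sweep - burnin] = np.log(tot).sum(dtype=np.float64)
            # z | q, theta, x: inverse-cdf draw on the running sum over k
            for kk in range(1, k):
                p[kk] += p[kk - 1]
            u = rng.random((n, j)).astype(dtype) * tot
            z = (p < u[None, :, :]).sum(axis=0)
            np.minimum(z, k - 1, out=z)  # float32 rounding guard at the top bin
            # q | z  (Dirichlet with alpha = 1 + per-individual cluster counts)
            counts = np.bincount(row_idx * k + z.ravel(), minlength=n * k).reshape(n, k)
            gam = rng.gamma(1.0 + counts)
            q = (gam / gam.sum(axis=1, keepdims=True)).astype(dtype)
            # theta | z, x  (Beta with successes/failures per cluster-band)
            flat = z.ravel() * j + col_idx
            ones = np.bincount(flat, weights=x_flat, minlength=k * j).reshape(k, j)
            tots = np.bincount(flat, minlength=k * j).reshape(k, j)
            theta = rng.beta(1.0 + ones, 1.0 + tots - ones).astype(dtype)
            if sweep >= burnin:
                q_sum += q
                theta_sum += theta
        q_mean = q_sum / kept
        q_mean /= q_mean.sum(axis=1, keepdims=True)
        return AdmixtureFit(
            K=k,
            q=pd.DataFrame(
                q_mean,
                index=list(self.m.individual_ids),
                columns=[f"cluster{c + 1}" for c in range(k)],
            ),
            theta=theta_sum / kept,
            mean_loglik=float(trace.mean()),
            loglik_trace=trace,
            seed=seed_int,
            burnin=burnin,
            iterations=iterations,
        )


def fit_admixture(
    m: BandMatrix,
    K: int,
    iterations: int = DEFAULT_ITERATIONS,
    burnin: int = DEFAULT_BURNIN,
    seed: int | None = None,
) -> AdmixtureFit:
    """Fit the admixture model once at fixed ``K`` (see :class:`AdmixtureModel`)."""
    return AdmixtureModel(m, K).fit(iterations=iterations, burnin=burnin, seed=seed)


def run_grid(
    m: BandMatrix,
    k_min: int = 2,
    k_max: int = 8,
    runs_per_k: int = 10,
    iterations: int = DEFAULT_ITERATIONS,
    burnin: int = DEFAULT_BURNIN,
    seed: int | None = None,
) -> list[AdmixtureFit]:
    """Independent runs over a grid of K, with seeds spawned from one master seed."""
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    if runs_per_k < 1:
        raise ValueError("runs_per_k must be >= 1")
    children = np.random.SeedSequence(seed).spawn((k_max - k_min + 1) * runs_per_k)
    fits: list[AdmixtureFit] = []
    it = iter(children)
    for k in range(k_min, k_max + 1):
        model = AdmixtureModel(m, k)
        for _ in range(runs_per_k):
            child = next(it)
            child_seed = int(child.generate_state(1)[0] % 2**31)
            fits.append(model.fit(iterations=iterations, burnin=burnin, seed=child_seed))
    return fits


@dataclass(frozen=True)
class DeltaKTable:
    """Evanno table: per-K likelihood summaries and the deltaK statistic.

    ``best_k`` is the interior argmax of deltaK (ties toward smaller K);
    ``None`` when no K shows curvature (all second differences ~ 0) or the
    run SD vanishes somewhere (flagged in ``degenerate``).
    """

    table: pd.DataFrame  # index K; columns mean_L, sd_L, Lp, Lpp_abs, delta_k
    best_k: int | None
    degenerate: bool = False

    def summary(self) -> str:
        head = (
            f"Evanno deltaK selection: best K = {self.best_k}"
            if self.best_k is not None
            else "Evanno deltaK selection: no signal"
        )
        return head + "\n" + self.table.round(4).to_string()


def evanno_delta_k(fits: Sequence[AdmixtureFit]) -> DeltaKTable:
    """Evanno second-difference statistic over a grid of admixture fits.

    Requires at least three consecutive K values with at least two runs
    each; run r's second difference pairs the r-th run at each K.
    """
    by_k: dict[int, list[float]] = {}
    for f in fits:
        by_k.setdefault(f.K, []).append(f.mean_loglik)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    runs = {k: len(v) for k, v in by_k.items()}
    if min(runs.values()) < 2:
        raise ValueError("need >= 2 runs per K")
    n_runs = min(runs.values())
    liks = np.array([by_k[k][:n_runs] for k in ks])  # n_k x n_runs
    mean_l = liks.mean(axis=1)
    sd_l = liks.std(axis=1, ddof=1)
    lp = np.full(len(ks), np.nan)
    lp[1:] = mean_l[1:] - mean_l[:-1]
    lpp_abs = np.full(len(ks), np.nan)
    delta = np.full(len(ks), np.nan)
    degenerate = False
    for i in range(1, len(ks) - 1):
        second = np.abs(liks[i + 1] - 2.0 * liks[i] + liks[i - 1])
        lpp_abs[i] = second.mean()
        if sd_l[i] <= 0:
            degenerate = True
        else:
            delta[i] = lpp_abs[i] / sd_l[i]
    table = pd.DataFrame(
        {
            "mean_L": mean_l,
            "sd_L": sd_l,
            "Lp": lp,
            "Lpp_abs": lpp_abs,
            "delta_k": delta,
        },
        index=pd.Index(ks, name="K"),
    )
    interior = table["delta_k"].iloc[1:-1]
    best_k: int | None = None
    if interior.notna().any() and np.nanmax(interior.to_numpy()) > 0:
        best_k = int(interior.idxmax())  # idxmax returns first (smallest K) on ties
    return DeltaKTable(table=table, best_k=best_k, degenerate=degenerate)
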
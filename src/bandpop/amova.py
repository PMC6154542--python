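"""Analysis of molecular variance (AMOVA) for dominant binary profiles.

Genetic differentiation among populations is quantified by partitioning the
pairwise squared Euclidean distances between band profiles — for 0/1 scores
simply the number of mismatched bands — into among- and within-population
variance components (the one-level Excoffier decomposition):

    SS_total  = (1/N)   sum_{i<j} d2_ij
    SS_within = sum_g (1/n_g) sum_{i<j in g} d2_ij
    SS_among  = SS_total - SS_within

    sigma2_w = SS_within / (N - G)
    sigma2_a = (SS_among/(G-1) - sigma2_w) / n0,
        n0 = (N - sum n_g^2 / N) / (G - 1)

    Phi_ST = sigma2_a / (sigma2_a + sigma2_w)

``Phi_ST`` (reported as FST throughout) is the among-population fraction of
molecular variance.  Significance comes from permuting individuals among
populations; the add-one estimator ``p = (1 + #{perm >= obs}) / (1 + P)``
never reports an exact zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import BandMatrix, subset
from .rarefaction import DEFAULT_LADDER, SamplingLadder

__all__ = [
    "AmovaResult",
    "pairwise_sq_euclidean",
    "amova",
    "phi_st_permutation",
    "fst_sweep",
]


@dataclass(frozen=True)
class AmovaResult:
    """AMOVA variance components, Phi_ST and (optionally) a permutation p."""

    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float | None = None
    n_permutations: int | None = None

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    def to_frame(self) -> pd.DataFrame:
        total_var = max(self.sigma2_among, 0.0) + self.sigma2_within
        pct = (
            (100 * max(self.sigma2_among, 0.0) / total_var, 100 * self.sigma2_within / total_var)
            if total_var > 0
            else (float("nan"), float("nan"))
        )
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within],
                "SS": [self.ss_among, self.ss_within],
                "variance": [self.sigma2_among, self.sigma2_within],
                "pct_total": pct,
                "Phi_ST": [self.phi_st, float("nan")],
                "p": [self.p_value, None],
            },
            index=pd.Index(["among populations", "within populations"], name="source"),
        )

    def summary(self) -> str:
        lines = ["Analysis of molecular variance", self.to_frame().to_string()]
        if self.p_value is not None:
            lines.append(
                f"Phi_ST = {self.phi_st:.4f}, p = {self.p_value:.4g} "
                f"({self.n_permutations} permutations)"
            )
        return "\n".join(lines)


def pairwise_sq_euclidean(m: BandMatrix) -> np.ndarray:
    """Squared Euclidean distances between band profiles (= mismatch counts)."""
    if m.n_individuals < 2:
        raise ValueError("need at least two individuals")
    return squareform(pdist(m.scores.astype(float), metric="sqeuclidean"))


def amova(
    m: BandMatrix,
    grouping: Sequence[str] | None = None,
    *,
    _d2: np.ndarray | None = None,
) -> AmovaResult:
    """One-level AMOVA of ``m`` grouped by population labels.

    ``grouping`` defaults to the matrix's population labels; a caller may
    pass any label vector of the same length (e.g. a focal-vs-rest
    contrast, or a species-level stratum collapsed onto populations).
    """
    labels = np.asarray(
        m.population_labels if grouping is None else list(grouping), dtype=object
    )
    if len(labels) != m.n_individuals:
        raise ValueError("grouping length must equal the number of individuals")
    d2 = pairwise_sq_euclidean(m) if _d2 is None else _d2
    return _amova_from_d2(d2, labels)


def _amova_from_d2(d2: np.ndarray, labels: np.ndarray) -> AmovaResult:
    n = d2.shape[0]
    groups, inverse = np.unique(labels, return_inverse=True)
    g = len(groups)
    if g < 2:
        raise ValueError("AMOVA requires at least two populations")
    sizes = np.bincount(inverse)
    if (sizes < 2).any():
        small = groups[sizes < 2]
        raise ValueError(
            f"every population needs >= 2 individuals (offending: {list(small)})"
        )
    triu = np.triu_indices(n, k=1)
    ss_total = d2[triu].sum() / n
    ss_within = 0.0
    for gi in range(g):
        idx = np.flatnonzero(inverse == gi)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / sizes[gi]
    ss_among = ss_total - ss_within
    df_among = g - 1
    df_within = n - g
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma2_w = ms_within
    sigma2_a = (ss_among / df_among - ms_within) / n0
    # Negative among-group component kept as the estimate; clamped to zero
    # only inside the Phi ratio (the usual convention).
    a = max(sigma2_a, 0.0)
    denom = a + sigma2_w
    phi = a / denom if denom > 0 else 0.0
    return AmovaResult(
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        df_among=df_among,
        df_within=df_within,
        sigma2_among=float(sigma2_a),
        sigma2_within=float(sigma2_w),
        phi_st=float(phi),
    )


def phi_st_permutation(
    m: BandMatrix,
    grouping: Sequence[str] | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA with a permutation p-value for Phi_ST.

    Individuals are shuffled among populations (group sizes preserved);
    the p-value is ``(1 + #{Phi_perm >= Phi_obs}) / (1 + n_permutations)``.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    labels = np.asarray(
        m.population_labels if grouping is None else list(grouping), dtype=object
    )
    d2 = pairwise_sq_euclidean(m)
    observed = _amova_from_d2(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = _amova_from_d2(d2, rng.permutation(labels))
        if perm.phi_st >= observed.phi_st - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return AmovaResult(
        ss_among=observed.ss_among,
        ss_within=observed.ss_within,
        df_among=observed.df_among,
        df_within=observed.df_within,
        sigma2_among=observed.sigma2_among,
        sigma2_within=observed.sigma2_within,
        phi_st=observed.phi_st,
        p_value=p,
        n_permutations=n_permutations,
    )


def fst_sweep(
    m: BandMatrix,
    ladder: SamplingLadder | Sequence[int] = DEFAULT_LADDER,
    replicates: int = 20,
    seed: int | None = None,
    mode: str = "focal_vs_rest",
) -> pd.DataFrame:
    """Mean FST (Phi_ST) per sampling size, per population.

    For each ladder size ``n``, ``replicates`` draws take ``n`` individuals
    per population without replacement and compute Phi_ST on the reduced
    matrix.  ``mode="focal_vs_rest"`` contrasts each focal population
    against the pooled remainder (one column per population, as diversity
    studies tabulate a per-accession FST); ``mode="global"`` reports the
    single among-all-populations Phi_ST.  Size-1 rows are reported as 0.00
    by convention (a single individual per group carries no within-group
    variance to partition).
    """
    if mode not in ("focal_vs_rest", "global"):
        raise ValueError("mode must be 'focal_vs_rest' or 'global'")
    if not isinstance(ladder, SamplingLadder):
        ladder = SamplingLadder(tuple(ladder))
    pops = m.populations
    if len(pops) < 2:
        raise ValueError("FST sweep requires at least two populations")
    sizes_by_pop = {p: np.array(m.population_individuals(p)) for p in pops}
    n_min = min(len(v) for v in sizes_by_pop.values())
    if ladder.sizes[-1] > n_min:
        raise ValueError(
            f"ladder size {ladder.sizes[-1]} exceeds smallest population size {n_min}"
        )
    rng = np.random.default_rng(seed)
    columns = list(pops) if mode == "focal_vs_rest" else ["global"]
    rows: list[list[float]] = []
    for size in ladder.sizes:
        if size == 1:
            rows.append([0.0] * len(columns))
            continue
        acc = np.zeros(len(columns))
        for _ in range(replicates):
            chosen: list[str] = []
            for p in pops:
                chosen.extend(rng.choice(sizes_by_pop[p], size=size, replace=False))
            sub = subset(m, chosen)
            d2 = pairwise_sq_euclidean(sub)
            labels = np.asarray(sub.population_labels, dtype=object)
            if mode == "global":
                acc[0] += _amova_from_d2(d2, labels).phi_st
            else:
                for ci, focal in enumerate(pops):
                    contrast = np.where(labels == focal, focal, "rest")
                    acc[ci] += _amova_from_d2(d2, contrast).phi_st
        rows.append(list(acc / replicates))
    frame = pd.DataFrame(rows, index=pd.Index(ladder.sizes, name="size"), columns=columns)
    return frame
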
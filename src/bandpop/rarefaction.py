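"""Random-subsampling retention curves and their exact rarefaction oracle.

The central question the package answers: how many individuals must be
sampled from one population so the subsample retains most of the
population's marker diversity?  The procedure draws, at each size of a
sampling ladder, replicate subsamples *without replacement* from one
population and tracks

* ``Na``  — bands observed in the subsample,
* ``RP``  — Reserve Percentage, ``100 * Na(subsample) / Na(full sample)``
  rounded to a whole percent (the fraction of the population sample's
  alleles retained),
* ``He`` and ``PIC`` on the subsample's pooled allele frequencies.

Because each band with presence count ``c`` among the population's ``N``
individuals survives a random ``n``-subsample with probability
``1 - C(N-c, n) / C(N, n)`` (hypergeometric non-retention), the expected
band count has the closed form

    E[Na(n)] = sum_b [ 1 - C(N - c_b, n) / C(N, n) ]

which serves as an exact analytic check on the Monte-Carlo curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import diversity
from .matrix import BandMatrix, band_presence_counts, subset

__all__ = [
    "DEFAULT_LADDER",
    "SamplingLadder",
    "RarefactionResult",
    "reserve_percentage",
    "expected_richness",
    "subsample_curve",
    "plateau_size",
]

#: Sampling sizes of the study design: dense below ten individuals where the
#: retention curve rises steeply, then coarse up to the full population.
DEFAULT_LADDER: tuple[int, ...] = (1, 2, 3, 5, 8, 10, 20, 30, 40, 50, 60)


@dataclass(frozen=True)
class SamplingLadder:
    """Strictly increasing subsample sizes."""

    sizes: tuple[int, ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if not sizes:
            raise ValueError("ladder must contain at least one size")
        if sizes[0] < 1 or any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("ladder sizes must be positive and strictly increasing")
        object.__setattr__(self, "sizes", sizes)

    def capped(self, n_max: int) -> "SamplingLadder":
        """Drop sizes exceeding ``n_max`` (ensuring at least one remains)."""
        kept = tuple(s for s in self.sizes if s <= n_max)
        if not kept:
            raise ValueError(f"no ladder size fits a population of {n_max}")
        return SamplingLadder(kept)


@dataclass(frozen=True)
class RarefactionResult:
    """Per-size Monte-Carlo summaries plus the exact expectation curve.

    ``per_size`` maps statistic name (``na``, ``rp``, ``he``, ``pic``) to a
    ``(mean, sd)`` pair per ladder size; ``expected_na`` is the analytic
    hypergeometric expectation and ``reference_na`` the full-sample Na the
    Reserve Percentage is taken against.
    """

    population: str
    sizes: tuple[int, ...]
    replicates: int
    mean: pd.DataFrame  # index sizes, columns na/rp/he/pic
    sd: pd.DataFrame
    expected_na: tuple[float, ...]
    reference_na: int
    seed: int | None = None
    replicate_values: pd.DataFrame | None = None  # audit dump (size, replicate) rows

    def to_frame(self) -> pd.DataFrame:
        """Wide table: mean and SD of every statistic plus the exact E[Na]."""
        frame = pd.DataFrame(index=pd.Index(self.sizes, name="size"))
        for col in self.mean.columns:
            frame[f"{col}_mean"] = self.mean[col]
            frame[f"{col}_sd"] = self.sd[col]
        frame["expected_na"] = self.expected_na
        return frame

    def summary(self) -> str:
        lines = [
            f"Rarefaction of population {self.population!r} "
            f"({self.replicates} replicates per size, reference Na = {self.reference_na})",
            self.to_frame().round(4).to_string(),
        ]
        return "\n".join(lines)

    def plot(self, path=None):
        """Retention curve (mean RP vs size) with the exact E[Na] overlay."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.errorbar(
            self.sizes, self.mean["na"], yerr=self.sd["na"], fmt="o-", label="mean Na"
        )
        ax.plot(self.sizes, self.expected_na, "--", label="exact E[Na]")
        ax.axhline(self.reference_na, color="grey", lw=0.8)
        ax.set_xlabel("sampling size")
        ax.set_ylabel("bands retained")
        ax.set_title(f"Allele retention, {self.population}")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig


def reserve_percentage(sub_na: int, full_na: int) -> int:
    """Percent of the full sample's bands retained, rounded half away from zero."""
    if full_na <= 0:
        raise ValueError("full_na must be positive")
    if not 0 <= sub_na <= full_na:
        raise ValueError(f"sub_na must be in [0, {full_na}], got {sub_na}")
    return int(math.floor(100.0 * sub_na / full_na + 0.5))


def expected_richness(m: BandMatrix, population: str, n: int) -> float:
    """Exact expected band count of a random ``n``-subsample of one population."""
    pop = m.population_matrix(population)
    big_n = pop.n_individuals
    if not 0 < n <= big_n:
        raise ValueError(f"n must be in [1, {big_n}], got {n}")
    counts = band_presence_counts(pop)
    # P(band missed) = C(N-c, n)/C(N, n) = hypergeometric P(X=0) drawing n
    # from c carriers + (N-c) non-carriers.
    miss = hypergeom.pmf(0, big_n, counts, n)
    return float(np.sum(1.0 - miss))


def subsample_curve(
    m: BandMatrix,
    population: str,
    ladder: SamplingLadder | Sequence[int] = DEFAULT_LADDER,
    replicates: int = 200,
    seed: int | None = None,
    keep_replicates: bool = False,
) -> RarefactionResult:
    """Monte-Carlo retention curve for one population.

    At each ladder size, ``replicates`` subsamples are drawn uniformly
    without replacement from the population's individuals; Na, RP (against
    the population's full-sample Na), He and PIC are evaluated on each, and
    means and SDs are reported.  ``replicates=1`` gives the single-draw mode
    in which each cell is one random draw, as a field study would report.
    ``keep_replicates`` additionally stores every per-replicate value for
    audit.
    """
    if not isinstance(ladder, SamplingLadder):
        ladder = SamplingLadder(tuple(ladder))
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    pop = m.population_matrix(population)
    big_n = pop.n_individuals
    if ladder.sizes[-1] > big_n:
        raise ValueError(
            f"ladder size {ladder.sizes[-1]} exceeds population {population!r} "
            f"size {big_n}"
        )
    full_na = int((band_presence_counts(pop) > 0).sum())
    rng = np.random.default_rng(seed)
    ids = np.array(pop.individual_ids)
    stats = ("na", "rp", "he", "pic")
    means = {s: [] for s in stats}
    sds = {s: [] for s in stats}
    audit_rows: list[dict[str, float]] = []
    for size in ladder.sizes:
        vals = {s: np.empty(replicates) for s in stats}
        for r in range(replicates):
            chosen = rng.choice(ids, size=size, replace=False)
            sub = subset(pop, chosen)
            f = diversity.allele_frequencies(sub)
            vals["na"][r] = f.na
            vals["rp"][r] = reserve_percentage(f.na, full_na)
            vals["he"][r] = diversity.expected_heterozygosity(f)
            vals["pic"][r] = diversity.pic(f)
            if keep_replicates:
                audit_rows.append(
                    {"size": size, "replicate": r, **{s: vals[s][r] for s in stats}}
                )
        for s in stats:
            means[s].append(vals[s].mean())
            sds[s].append(vals[s].std(ddof=1) if replicates > 1 else 0.0)
    index = pd.Index(ladder.sizes, name="size")
    return RarefactionResult(
        population=population,
        sizes=ladder.sizes,
        replicates=replicates,
        mean=pd.DataFrame(means, index=index),
        sd=pd.DataFrame(sds, index=index),
        expected_na=tuple(
            expected_richness(m, population, n) for n in ladder.sizes
        ),
        reference_na=full_na,
        seed=seed,
        replicate_values=pd.DataFrame(audit_rows) if keep_replicates else None,
    )


def plateau_size(r: RarefactionResult, threshold: float) -> int:
    """Smallest ladder size whose mean Reserve Percentage meets ``threshold``."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    for size, rp in zip(r.sizes, r.mean["rp"]):
        if rp >= threshold:
            return int(size)
    raise ValueError(f"no sampling size reaches RP >= {threshold}")
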
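"""Diversity statistics for dominant-marker band matrices.

Bands are treated as alleles: each reproducible fragment is one allele, and
``Na`` is simply the number of distinct bands observed in a sample.  Allele
frequencies are *occurrence-proportional* — all observed bands are pooled as
alleles of a single phantom multi-allelic locus, with

    p_j = count_j / sum_k count_k

so that a single individual exhibiting ``Na`` bands has uniform frequencies
``1/Na`` and expected heterozygosity ``1 - 1/Na``.  On top of those
frequencies the module computes

* ``He``  — expected heterozygosity (Nei gene diversity), ``1 - sum p^2``,
  without a small-sample correction (the correction diverges at n = 1,
  where the uniform anchor must hold exactly);
* ``PIC`` — polymorphism information content in the Botstein form,
  ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``;
* ``PPB`` — percentage of observed bands that are polymorphic (present in
  some but not all individuals);
* ``I``   — Shannon information index, the mean per-band binary entropy of
  band carrier frequencies ``q_b = count_b / n``;
* ``Rp``  — per-primer resolving power ``sum_b (1 - 2|0.5 - q_b|)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import BandMatrix, band_presence_counts, subset

__all__ = [
    "AlleleFrequencies",
    "DiversitySummary",
    "PrimerSummary",
    "allele_frequencies",
    "expected_heterozygosity",
    "pic",
    "ppb",
    "shannon_index",
    "resolving_power",
    "summarize",
    "primer_summary_table",
    "accession_primer_table",
]


@dataclass(frozen=True)
class AlleleFrequencies:
    """Occurrence-proportional pooled allele frequencies.

    ``band_ids`` is restricted to bands with nonzero presence count and
    ``p`` sums to one with every entry strictly positive.
    """

    band_ids: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or len(p) != len(self.band_ids):
            raise ValueError("p must be one frequency per band id")
        if not len(p):
            raise ValueError("no alleles observed")
        if (p <= 0).any():
            raise ValueError("all frequencies must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {p.sum()}, expected 1")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "band_ids", tuple(self.band_ids))

    @property
    def na(self) -> int:
        """Observed number of alleles (bands with count > 0)."""
        return len(self.band_ids)


@dataclass(frozen=True)
class PrimerSummary:
    na: int
    ppb: float
    he: float
    pic: float
    rp: float


@dataclass(frozen=True)
class DiversitySummary:
    """Pooled diversity statistics of a band matrix (optionally per primer)."""

    na: int
    ppb: float
    he: float
    pic: float
    shannon: float
    per_primer: Mapping[str, PrimerSummary] | None = None


def allele_frequencies(
    m: BandMatrix, bands: Iterable[str] | str = "all"
) -> AlleleFrequencies:
    """Pooled band-as-allele frequencies of ``m`` (or a band subset of it)."""
    if not isinstance(bands, str):
        m = subset(m, m.individual_ids, bands)
    counts = band_presence_counts(m)
    keep = counts > 0
    if not keep.any():
        raise ValueError("no alleles observed (all-zero matrix)")
    kept = counts[keep].astype(float)
    return AlleleFrequencies(
        tuple(b for b, k in zip(m.band_ids, keep) if k), kept / kept.sum()
    )


def expected_heterozygosity(f: AlleleFrequencies) -> float:
    """Nei gene diversity ``He = 1 - sum p_j^2`` of pooled allele frequencies."""
    return float(1.0 - np.sum(f.p**2))


def pic(f: AlleleFrequencies) -> float:
    """Botstein polymorphism information content.

    ``PIC = 1 - S2 - (S2^2 - S4)`` with ``S2 = sum p^2`` and ``S4 = sum p^4``,
    an algebraic rewrite of ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``.
    """
    s2 = float(np.sum(f.p**2))
    s4 = float(np.sum(f.p**4))
    return 1.0 - s2 - (s2 * s2 - s4)


def ppb(m: BandMatrix) -> float:
    """Percentage of observed bands that are polymorphic.

    A band counts as polymorphic when present in some but not all of the
    matrix's individuals; the denominator is the number of observed
    (count > 0) bands.
    """
    if m.n_individuals < 2:
        raise ValueError("PPB requires at least two individuals")
    counts = band_presence_counts(m)
    observed = counts > 0
    if not observed.any():
        raise ValueError("no bands observed")
    poly = observed & (counts < m.n_individuals)
    return 100.0 * poly.sum() / observed.sum()


def shannon_index(m: BandMatrix) -> float:
    """Mean per-band binary entropy of band carrier frequencies.

    Each band contributes ``-(q ln q + (1-q) ln(1-q))`` with ``q`` the
    fraction of individuals carrying it; fixed or absent bands contribute 0.
    The average runs over all bands of the matrix.
    """
    if m.n_individuals < 1:
        raise ValueError("Shannon index requires at least one individual")
    if m.n_bands == 0:
        raise ValueError("no bands")
    q = band_presence_counts(m) / m.n_individuals
    return float(np.mean(_binary_entropy(q)))


def resolving_power(m: BandMatrix, primer: str) -> float:
    """Resolving power ``Rp = sum_b I_b`` of one primer's bands.

    ``I_b = 1 - 2|0.5 - q_b|`` rewards bands near 50% carrier frequency,
    which are the most informative for telling genotypes apart.
    """
    bands = m.primer_bands(primer)
    sub = subset(m, m.individual_ids, bands)
    q = band_presence_counts(sub) / sub.n_individuals
    return float(np.sum(1.0 - 2.0 * np.abs(0.5 - q)))


def summarize(m: BandMatrix, per_primer: bool = True) -> DiversitySummary:
    """Pooled Na/PPB/He/PIC/Shannon summary, optionally broken out by primer."""
    f = allele_frequencies(m)
    primer_map: dict[str, PrimerSummary] | None = None
    if per_primer:
        primer_map = {}
        for primer in m.primers:
            sub = subset(m, m.individual_ids, m.primer_bands(primer))
            fp = allele_frequencies(sub)
            primer_map[primer] = PrimerSummary(
                na=fp.na,
                ppb=ppb(sub),
                he=expected_heterozygosity(fp),
                pic=pic(fp),
                rp=resolving_power(m, primer),
            )
    return DiversitySummary(
        na=f.na,
        ppb=ppb(m),
        he=expected_heterozygosity(f),
        pic=pic(f),
        shannon=shannon_index(m),
        per_primer=primer_map,
    )


def primer_summary_table(m: BandMatrix) -> pd.DataFrame:
    """Per-primer PPB/Na/He/PIC table over all individuals, plus an average row."""
    s = summarize(m, per_primer=True)
    assert s.per_primer is not None
    rows = {
        primer: {
            "PPB": ps.ppb,
            "Na": ps.na,
            "He": round(ps.he, 4),
            "PIC": round(ps.pic, 4),
        }
        for primer, ps in s.per_primer.items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.loc["Average"] = [
        frame["PPB"].mean(),
        round(frame["Na"].mean(), 1),
        round(frame["He"].mean(), 4),
        round(frame["PIC"].mean(), 4),
    ]
    frame.index.name = "Primer"
    return frame


def accession_primer_table(m: BandMatrix) -> pd.DataFrame:
    """Rp/He/PIC of each primer within each population (accession)."""
    records: list[dict[str, object]] = []
    for primer in m.primers:
        row: dict[str, object] = {"Primer": primer}
        for pop in m.populations:
            sub = m.population_matrix(pop)
            fp = allele_frequencies(sub, sub.primer_bands(primer))
            row[f"{pop} Rp"] = round(resolving_power(sub, primer), 2)
            row[f"{pop} He"] = round(expected_heterozygosity(fp), 4)
            row[f"{pop} PIC"] = round(pic(fp), 4)
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("Primer")


def _binary_entropy(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q)
    inner = (q > 0) & (q < 1)
    qi = q[inner]
    out[inner] = -(qi * np.log(qi) + (1 - qi) * np.log(1 - qi))
    return out
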
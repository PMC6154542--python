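"""Band-score matrices for dominant molecular markers.

A dominant marker (SCoT, RAPD, ISSR, AFLP scored dominantly) yields, for
every individual, a binary profile over amplified fragments: each band is
present (1) or absent (0), and heterozygotes are indistinguishable from
dominant homozygotes.  The :class:`BandMatrix` is the single container all
downstream statistics operate on: an individuals x bands 0/1 matrix with
per-individual population labels and per-band primer annotations.

The on-disk layout is delimited text with two (optionally three) header
rows::

    individual_id,population,Scot28_200bp,Scot28_350bp,...
    primer,,Scot28,Scot28,...
    size_bp,,200,350,...            # optional
    ind_001,LJ. 1,1,0,...

Only curated, reproducible bands are expected; a missing or non-binary cell
is a hard error, never imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BandMatrix",
    "BandMatrixError",
    "ParseError",
    "read_band_matrix",
    "write_band_matrix",
    "subset",
    "band_presence_counts",
]

_DELIMS = {"comma": ",", "tab": "\t"}


class BandMatrixError(ValueError):
    """Invalid band-matrix content (duplicates, shape mismatch, bad values)."""


class ParseError(BandMatrixError):
    """Malformed band-matrix file."""


@dataclass(frozen=True)
class BandMatrix:
    """Individuals x bands 0/1 score matrix with annotations.

    Parameters
    ----------
    scores
        Integer array of shape ``(n_individuals, n_bands)`` with entries in
        ``{0, 1}``.
    individual_ids
        Unique identifier per row.
    population_labels
        Population (accession) label per individual.
    band_ids
        Unique identifier per column.
    band_primer
        Primer name per band.
    band_size_bp
        Optional fragment length (bp) per band; every entry must be > 0.
    """

    scores: np.ndarray
    individual_ids: tuple[str, ...]
    population_labels: tuple[str, ...]
    band_ids: tuple[str, ...]
    band_primer: tuple[str, ...]
    band_size_bp: tuple[int, ...] | None = None

    def __init__(
        self,
        scores,
        individual_ids: Sequence[str],
        population_labels: Sequence[str],
        band_ids: Sequence[str],
        band_primer: Sequence[str],
        band_size_bp: Sequence[int] | None = None,
    ) -> None:
        scores = np.asarray(scores)
        if scores.ndim != 2:
            raise BandMatrixError("scores must be a 2-D array")
        if scores.size and not np.isin(scores, (0, 1)).all():
            raise BandMatrixError("scores must contain only 0 and 1")
        scores = scores.astype(np.int8, copy=True)
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "individual_ids", tuple(str(i) for i in individual_ids))
        object.__setattr__(self, "population_labels", tuple(str(p) for p in population_labels))
        object.__setattr__(self, "band_ids", tuple(str(b) for b in band_ids))
        object.__setattr__(self, "band_primer", tuple(str(p) for p in band_primer))
        object.__setattr__(
            self,
            "band_size_bp",
            None if band_size_bp is None else tuple(int(s) for s in band_size_bp),
        )
        self._validate()

    def _validate(self) -> None:
        n, j = self.scores.shape
        if len(self.individual_ids) != n:
            raise BandMatrixError(
                f"{len(self.individual_ids)} individual ids for {n} score rows"
            )
        if len(self.population_labels) != n:
            raise BandMatrixError(
                f"{len(self.population_labels)} population labels for {n} individuals"
            )
        if len(self.band_ids) != j:
            raise BandMatrixError(f"{len(self.band_ids)} band ids for {j} score columns")
        if len(self.band_primer) != j:
            raise BandMatrixError(f"{len(self.band_primer)} primer labels for {j} bands")
        if len(set(self.individual_ids)) != n:
            raise BandMatrixError("duplicate individual ids")
        if len(set(self.band_ids)) != j:
            raise BandMatrixError("duplicate band ids")
        if self.band_size_bp is not None:
            if len(self.band_size_bp) != j:
                raise BandMatrixError(f"{len(self.band_size_bp)} band sizes for {j} bands")
            if any(s <= 0 for s in self.band_size_bp):
                raise BandMatrixError("band sizes must be positive")

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    @property
    def n_bands(self) -> int:
        return self.scores.shape[1]

    @property
    def populations(self) -> tuple[str, ...]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p, None)
        return tuple(seen)

    @property
    def primers(self) -> tuple[str, ...]:
        """Distinct primer names in band order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.band_primer:
            seen.setdefault(p, None)
        return tuple(seen)

    def population_individuals(self, label: str) -> tuple[str, ...]:
        ids = tuple(
            i for i, p in zip(self.individual_ids, self.population_labels) if p == label
        )
        if not ids:
            raise KeyError(f"unknown population {label!r}")
        return ids

    def primer_bands(self, primer: str) -> tuple[str, ...]:
        bands = tuple(b for b, p in zip(self.band_ids, self.band_primer) if p == primer)
        if not bands:
            raise KeyError(f"unknown primer {primer!r}")
        return bands

    def population_matrix(self, label: str) -> "BandMatrix":
        """Restrict to one population's individuals (all bands kept)."""
        return subset(self, self.population_individuals(label))

    # -- spec operations as methods -----------------------------------------

    def subset(self, individuals: Iterable[str], bands: Iterable[str] | str = "all"):
        return subset(self, individuals, bands)

    def band_presence_counts(self) -> np.ndarray:
        return band_presence_counts(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.population_labels == other.population_labels
            and self.band_ids == other.band_ids
            and self.band_primer == other.band_primer
            and self.band_size_bp == other.band_size_bp
            and np.array_equal(self.scores, other.scores)
        )

    def __hash__(self) -> int:  # frozen dataclass contract
        return hash((self.individual_ids, self.band_ids))

    def __repr__(self) -> str:
        return (
            f"<BandMatrix {self.n_individuals} individuals x {self.n_bands} bands, "
            f"{len(self.populations)} populations, {len(self.primers)} primers>"
        )


def read_band_matrix(path, dialect: str = "comma") -> BandMatrix:
    """Read a band matrix from delimited text.

    ``dialect`` is ``"comma"`` (CSV) or ``"tab"`` (TSV).  The file must have
    band ids in header row 1, primers in header row 2, an optional band-size
    row 3 (first cell ``size_bp``), and one data row per individual with the
    individual id and population label in the first two columns.
    """
    delim = _delimiter(dialect)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if len(rows) < 2:
        raise ParseError(f"{path}: expected at least two header rows")
    header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: header must have id and population columns")
    band_ids = header[2:]
    primer_row = rows[1]
    if len(primer_row) != len(header):
        raise ParseError(f"{path}: primer row length differs from header")
    band_primer = primer_row[2:]
    data_start = 2
    band_size: list[int] | None = None
    if len(rows) > 2 and rows[2] and rows[2][0] == "size_bp":
        if len(rows[2]) != len(header):
            raise ParseError(f"{path}: size row length differs from header")
        try:
            band_size = [int(s) for s in rows[2][2:]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer band size: {exc}") from None
        data_start = 3
    individual_ids: list[str] = []
    population_labels: list[str] = []
    score_rows: list[list[int]] = []
    for row in rows[data_start:]:
        if not row:
            continue
        if len(row) != len(header):
            raise ParseError(
                f"{path}: ragged row for individual {row[0]!r}: "
                f"{len(row)} fields, expected {len(header)}"
            )
        individual_ids.append(row[0])
        population_labels.append(row[1])
        scores_row = []
        for band, cell in zip(band_ids, row[2:]):
            if cell not in ("0", "1"):
                raise ParseError(
                    f"{path}: non-binary score {cell!r} at {row[0]},{band}"
                )
            scores_row.append(int(cell))
        score_rows.append(scores_row)
    scores = np.array(score_rows, dtype=np.int8).reshape(len(individual_ids), len(band_ids))
    return BandMatrix(
        scores, individual_ids, population_labels, band_ids, band_primer, band_size
    )


def write_band_matrix(m: BandMatrix, path, dialect: str = "comma") -> None:
    """Write ``m`` so that :func:`read_band_matrix` reproduces it exactly."""
    delim = _delimiter(dialect)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["individual_id", "population", *m.band_ids])
        writer.writerow(["primer", "", *m.band_primer])
        if m.band_size_bp is not None:
            writer.writerow(["size_bp", "", *m.band_size_bp])
        for i, (ind, pop) in enumerate(zip(m.individual_ids, m.population_labels)):
            writer.writerow([ind, pop, *m.scores[i].tolist()])


def subset(
    m: BandMatrix,
    individuals: Iterable[str],
    bands: Iterable[str] | str = "all",
) -> BandMatrix:
    """Slice a band matrix by individual and band ids, preserving request order."""
    individuals = list(individuals)
    ind_index = {v: i for i, v in enumerate(m.individual_ids)}
    try:
        rows = [ind_index[i] for i in individuals]
    except KeyError as exc:
        raise KeyError(f"unknown individual id {exc.args[0]!r}") from None
    if isinstance(bands, str):
        if bands != "all":
            raise ValueError("bands must be an iterable of band ids or 'all'")
        cols = list(range(m.n_bands))
        band_list = list(m.band_ids)
    else:
        band_list = list(bands)
        band_index = {v: i for i, v in enumerate(m.band_ids)}
        try:
            cols = [band_index[b] for b in band_list]
        except KeyError as exc:
            raise KeyError(f"unknown band id {exc.args[0]!r}") from None
    return BandMatrix(
        m.scores[np.ix_(rows, cols)],
        [m.individual_ids[i] for i in rows],
        [m.population_labels[i] for i in rows],
        band_list,
        [m.band_primer[c] for c in cols],
        None if m.band_size_bp is None else [m.band_size_bp[c] for c in cols],
    )


def band_presence_counts(m: BandMatrix) -> np.ndarray:
    """Number of individuals carrying each band (column sums of ``scores``)."""
    return m.scores.sum(axis=0, dtype=np.int64)


def _delimiter(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise ValueError(f"dialect must be one of {sorted(_DELIMS)}, got {dialect!r}") from None
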
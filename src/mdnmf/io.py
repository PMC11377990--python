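"""Reading, deduplicating and indexing microbe-disease association data.

The central container is :class:`AssociationData`: a binary matrix ``A`` of
shape ``(m, d)`` whose rows are microbes and columns are diseases, with
``A[i, j] = 1`` iff an experimentally supported association between microbe
``i`` and disease ``j`` is on record.  Identifiers are kept in first-
appearance order and matched case-sensitively after stripping surrounding
whitespace, so distinct taxa are never silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FormatError

__all__ = [
    "AssociationData",
    "load_edge_list",
    "load_dense_matrix",
    "density",
    "write_scores",
    "read_scores",
]

_HEADER_WORDS = {"microbe", "microbes", "disease", "diseases", "name", "id", "taxon"}


@dataclass
class AssociationData:
    """Named binary microbe x disease association matrix.

    Parameters
    ----------
    microbes : list of str
        Unique microbe identifiers, one per matrix row.
    diseases : list of str
        Unique disease identifiers, one per matrix column.
    A : ndarray of shape (m, d)
        Binary association matrix (float64 with entries in {0.0, 1.0}).
    """

    microbes: list[str]
    diseases: list[str]
    A: np.ndarray
    microbe_index: dict[str, int] = field(init=False, repr=False)
    disease_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise FormatError("association matrix must be 2-dimensional")
        m, d = self.A.shape
        if len(self.microbes) != m or len(self.diseases) != d:
            raise FormatError(
                f"matrix shape {self.A.shape} does not match "
                f"{len(self.microbes)} microbes x {len(self.diseases)} diseases"
            )
        if len(set(self.microbes)) != m:
            raise FormatError("duplicate microbe identifiers")
        if len(set(self.diseases)) != d:
            raise FormatError("duplicate disease identifiers")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise FormatError("association matrix entries must be 0 or 1")
        self.microbe_index = {name: i for i, name in enumerate(self.microbes)}
        self.disease_index = {name: j for j, name in enumerate(self.diseases)}

    @property
    def n_microbes(self) -> int:
        return self.A.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.A.shape[1]

    @property
    def n_associations(self) -> int:
        """Number of recorded (microbe, disease) associations (ones in A)."""
        return int(self.A.sum())

    def known_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) with A[i, j] == 1, in row-major order."""
        rows, cols = np.nonzero(self.A)
        return list(zip(rows.tolist(), cols.tolist()))

    def masked(self, pairs) -> "AssociationData":
        """Copy with the given (i, j) entries set to 0 (held-out associations)."""
        A = self.A.copy()
        for i, j in pairs:
            A[i, j] = 0.0
        return AssociationData(list(self.microbes), list(self.diseases), A)


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _is_header(fields: list[str]) -> bool:
    lowered = [f.strip().lower() for f in fields[:2]]
    return any(w in _HEADER_WORDS or "microbe" in w or "disease" in w for w in lowered)


def load_edge_list(path) -> AssociationData:
    """Load a two-column (microbe, disease) edge list (TSV or CSV).

    Duplicate pairs collapse to a single association; identifiers are ordered
    by first appearance.  A header row is skipped when its first two fields
    look like column names ("microbe", "disease", "name", ...).

    Raises
    ------
    FormatError
        On an empty file or a row with fewer than two fields (the message
        names the offending line number).
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [(no, ln) for no, ln in enumerate(lines, start=1) if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty edge list")
    delim = _sniff_delimiter(lines[0][1])

    microbes: list[str] = []
    diseases: list[str] = []
    pairs: set[tuple[str, str]] = set()
    ordered_pairs: list[tuple[str, str]] = []
    first = True
    for no, ln in lines:
        fields = ln.split(delim)
        if len(fields) < 2:
            raise FormatError(f"{path}: line {no}: expected >=2 fields, got {len(fields)}")
        if first:
            first = False
            if _is_header(fields):
                continue
        microbe = fields[0].strip()
        disease = fields[1].strip()
        if not microbe or not disease:
            raise FormatError(f"{path}: line {no}: empty identifier")
        if (microbe, disease) not in pairs:
            pairs.add((microbe, disease))
            ordered_pairs.append((microbe, disease))
        if microbe not in microbes:
            microbes.append(microbe)
        if disease not in diseases:
            diseases.append(disease)

    if not ordered_pairs:
        raise FormatError(f"{path}: no data rows")
    A = np.zeros((len(microbes), len(diseases)))
    mi = {name: i for i, name in enumerate(microbes)}
    di = {name: j for j, name in enumerate(diseases)}
    for microbe, disease in ordered_pairs:
        A[mi[microbe], di[disease]] = 1.0
    return AssociationData(microbes, diseases, A)


def load_dense_matrix(path) -> AssociationData:
    """Load a dense binary matrix: disease names in the header row, microbe
    names in the first column, tab-separated."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: dense matrix needs a header and >=1 data row")
    diseases = [f.strip() for f in lines[0].split("\t")[1:]]
    microbes: list[str] = []
    rows = []
    for no, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(diseases) + 1:
            raise FormatError(f"{path}: line {no}: expected {len(diseases) + 1} fields")
        microbes.append(fields[0].strip())
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {no}: non-numeric entry") from exc
    return AssociationData(microbes, diseases, np.array(rows))


def density(data: AssociationData) -> float:
    """Percentage of observed associations among all microbe-disease pairs.

    Returns ``100 * (#ones) / (m * d)``.
    """
    return 100.0 * data.n_associations / (data.n_microbes * data.n_diseases)


def write_scores(scores: np.ndarray, data: AssociationData, path) -> None:
    """Write a three-column (microbe, disease, score) TSV, microbe-major order,
    full float precision."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != data.A.shape:
        raise FormatError(
            f"score matrix shape {scores.shape} does not match data {data.A.shape}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        for i, microbe in enumerate(data.microbes):
            for j, disease in enumerate(data.diseases):
                fh.write(f"{microbe}\t{disease}\t{scores[i, j]:.17g}\n")


def read_scores(path, data: AssociationData) -> np.ndarray:
    """Read a score TSV written by :func:`write_scores` back into a matrix."""
    scores = np.full(data.A.shape, np.nan)
    with open(path, encoding="utf-8") as fh:
        for no, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: line {no}: expected 3 fields")
            i = data.microbe_index[fields[0]]
            j = data.disease_index[fields[1]]
            scores[i, j] = float(fields[2])
    if np.isnan(scores).any():
        raise FormatError(f"{path}: incomplete score matrix")
    return scores
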
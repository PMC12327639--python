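"""Protein-graph construction and I/O.

A protein is represented as a residue contact graph: nodes are amino-acid
residues, and two residues are connected when their Cα atoms lie within a
distance threshold (default 10 Å). Each node carries a feature vector
(typically a protein-language-model embedding such as an ESM-2 row, 1280-d,
or a 20-d one-hot fallback). Function labels are multi-hot vectors over a
GO-term vocabulary for one category (MF, BP or CC).

This module parses structures / coordinate tables, builds contact graphs,
and reads/writes the plain-text interchange formats used by the CLI:

* coordinates: 3-column whitespace-delimited table (x y z per residue, Å),
  or PDB / mmCIF (first model; one point per residue with a Cα atom);
* contact graphs: 2-column 0-based edge list, one undirected edge per line,
  ``i j`` with ``i < j``;
* feature matrices: delimited text or ``.npy``;
* labels: TSV rows ``protein_id<TAB>GO:NNNNNNN[;GO:...]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("contactgo")

#: Contact threshold between Cα atoms, in Å.
DEFAULT_CONTACT_THRESHOLD = 10.0

#: Canonical 20-letter amino-acid alphabet used for one-hot encoding.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

GO_CATEGORIES = ("MF", "BP", "CC")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class EmptyStructureError(DataError):
    """A structure file yielded no Cα coordinates."""


class ShapeMismatchError(DataError):
    """Row/column counts of two inputs disagree."""


class ConfigurationError(ValueError):
    """An invalid configuration value or combination."""


# ---------------------------------------------------------------------------
# Protein graph container
# ---------------------------------------------------------------------------


@dataclass
class ProteinGraph:
    """One protein as a residue contact graph.

    Parameters
    ----------
    protein_id:
        Identifier of the protein.
    adjacency:
        Symmetric binary ``(Np, Np)`` matrix with zero diagonal. The
        self-interaction is handled by the closed aggregation neighbourhood
        of the network, not stored as an edge.
    features:
        Real ``(Np, Dp)`` residue feature matrix; row ``i`` belongs to
        residue ``i``.
    coords:
        Optional ``(Np, 3)`` Cα coordinates in Å, in chain order.
    node_classes:
        Optional per-residue class labels (e.g. amino-acid types), used by
        class-conditioned synthetic label rules.
    """

    protein_id: str
    adjacency: np.ndarray
    features: np.ndarray
    coords: np.ndarray | None = None
    node_classes: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ShapeMismatchError(f"adjacency must be square, got {A.shape}")
        if not np.array_equal(A, A.T):
            raise DataError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise DataError("adjacency diagonal must be zero")
        if not np.isin(A, (0, 1)).all():
            raise DataError("adjacency must be binary")
        self.adjacency = A.astype(np.int8)
        X = np.asarray(self.features, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != A.shape[0]:
            raise ShapeMismatchError(
                f"feature matrix has {X.shape[0] if X.ndim == 2 else 'bad'} rows "
                f"for {A.shape[0]} residues"
            )
        self.features = X
        if self.coords is not None:
            C = np.asarray(self.coords, dtype=np.float64)
            if C.shape != (A.shape[0], 3):
                raise ShapeMismatchError(
                    f"coords shape {C.shape} does not match {A.shape[0]} residues"
                )
            self.coords = C

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Undirected edge set ``{(i, j) : i < j}``."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return {(int(i), int(j)) for i, j in zip(ii, jj)}

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GOLabelVector:
    """Multi-hot GO-term annotation of one protein in one category."""

    protein_id: str
    category: str
    labels: np.ndarray
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in GO_CATEGORIES:
            raise ConfigurationError(
                f"category must be one of {GO_CATEGORIES}, got {self.category!r}"
            )
        y = np.asarray(self.labels, dtype=np.int8)
        if y.shape != (len(self.vocabulary),):
            raise ShapeMismatchError(
                f"label vector length {y.shape} != vocabulary size {len(self.vocabulary)}"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise DataError("vocabulary contains duplicate terms")
        self.labels = y
        self.vocabulary = tuple(self.vocabulary)


# ---------------------------------------------------------------------------
# Structure / coordinate parsing
# ---------------------------------------------------------------------------

_STRUCTURE_SUFFIXES = {".pdb", ".ent", ".cif", ".mmcif"}


def parse_ca_coordinates(structure_file: str | Path, chain: str | None = None) -> np.ndarray:
    """Extract one Cα coordinate per residue, in chain order.

    Accepts PDB / mmCIF (parsed with gemmi, first model only) or a plain
    3-column whitespace-delimited coordinate table. Residues lacking a Cα
    atom are skipped with a warning; for altLoc duplicates the first
    occurrence is kept.
    """
    path = Path(structure_file)
    if not path.is_file():
        raise DataError(f"structure file not found: {path}")
    if path.suffix.lower() in _STRUCTURE_SUFFIXES:
        return _parse_structure_gemmi(path, chain)
    return _parse_coordinate_table(path)


def _parse_coordinate_table(path: Path) -> np.ndarray:
    try:
        table = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise DataError(f"cannot parse coordinate table {path}: {exc}") from exc
    if table.size == 0:
        raise EmptyStructureError(f"no coordinates in {path}")
    if table.shape[1] != 3:
        raise DataError(f"coordinate table {path} has {table.shape[1]} columns, expected 3")
    return table


def _parse_structure_gemmi(path: Path, chain: str | None) -> np.ndarray:
    import gemmi

    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"cannot read structure {path}: {exc}") from exc
    if len(structure) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = structure[0]
    points: list[tuple[float, float, float]] = []
    n_skipped = 0
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for residue in ch:
            ca = None
            for atom in residue:
                if atom.name == "CA":
                    ca = atom  # first altLoc occurrence wins
                    break
            if ca is None:
                n_skipped += 1
                continue
            points.append((ca.pos.x, ca.pos.y, ca.pos.z))
    if n_skipped:
        logger.warning("%s: skipped %d residue(s) without a CA atom", path.name, n_skipped)
    if not points:
        raise EmptyStructureError(f"no CA atoms found in {path} (chain={chain!r})")
    return np.asarray(points, dtype=np.float64)


def build_contact_graph(
    coords: np.ndarray,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    inclusive: bool = True,
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Threshold pairwise Cα distances into a binary contact graph.

    Entry ``(i, j)``, ``i != j``, is 1 iff the Euclidean distance is within
    ``threshold`` Å. With ``inclusive`` (default) the comparison is
    ``<= threshold``; boundary ties are measure-zero for real coordinates,
    so either convention matches practice, and ``inclusive=False`` gives the
    strict ``<`` reading.

    Returns the symmetric zero-diagonal adjacency matrix and the undirected
    edge set ``{(i, j): i < j}``.
    """
    C = np.asarray(coords, dtype=np.float64)
    if C.ndim != 2 or C.shape[1] != 3:
        raise DataError(f"coords must be (N, 3), got {C.shape}")
    if C.shape[0] < 1:
        raise DataError("need at least one point")
    if threshold <= 0:
        raise ConfigurationError(f"threshold must be positive, got {threshold}")
    if not np.isfinite(C).all():
        raise DataError("non-finite coordinate encountered")
    n = C.shape[0]
    if n == 1:
        return np.zeros((1, 1), dtype=np.int8), set()
    dists = squareform(pdist(C))
    close = dists <= threshold if inclusive else dists < threshold
    np.fill_diagonal(close, False)
    adjacency = close.astype(np.int8)
    ii, jj = np.nonzero(np.triu(adjacency, k=1))
    return adjacency, {(int(i), int(j)) for i, j in zip(ii, jj)}


# ---------------------------------------------------------------------------
# Node features
# ---------------------------------------------------------------------------


def load_feature_matrix(feature_file: str | Path, expected_rows: int) -> np.ndarray:
    """Load a dense residue feature matrix (text table or ``.npy``).

    Real ESM-2 embeddings have Dp = 1280 columns; any width is accepted —
    the row count must match the structure's residue count.
    """
    path = Path(feature_file)
    if not path.is_file():
        raise DataError(f"feature file not found: {path}")
    if path.suffix.lower() == ".npy":
        X = np.load(path, allow_pickle=False)
    else:
        try:
            X = np.loadtxt(path, dtype=np.float64, ndmin=2)
        except ValueError as exc:
            raise DataError(f"cannot parse feature matrix {path}: {exc}") from exc
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise DataError(f"feature matrix {path} is not 2-D (shape {X.shape})")
    if X.shape[0] != expected_rows:
        raise ShapeMismatchError(
            f"feature matrix {path} has {X.shape[0]} rows but the structure "
            f"has {expected_rows} residues"
        )
    return X


def one_hot_features(sequence: str) -> np.ndarray:
    """One-hot encode an amino-acid sequence (Np × 20).

    The traditional fallback embedder: position-independent, one row per
    residue, columns ordered as ``ACDEFGHIKLMNPQRSTVWY``. Letters outside
    the 20-letter alphabet map to the all-zero row with a warning.
    """
    if not sequence:
        raise DataError("empty sequence")
    index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    X = np.zeros((len(sequence), len(AMINO_ACIDS)), dtype=np.float64)
    unknown = 0
    for i, aa in enumerate(sequence.upper()):
        k = index.get(aa)
        if k is None:
            unknown += 1
        else:
            X[i, k] = 1.0
    if unknown:
        logger.warning("%d unknown residue letter(s) mapped to zero rows", unknown)
    return X


# ---------------------------------------------------------------------------
# GO label tables
# ---------------------------------------------------------------------------


def read_go_labels(
    tsv: str | Path,
    category: str,
    min_term_count: int = 1,
) -> dict[str, GOLabelVector]:
    """Read a protein→GO-terms TSV into multi-hot label vectors.

    Rows are ``protein_id<TAB>GO:NNNNNNN[;GO:...]``. Terms annotated in
    fewer than ``min_term_count`` proteins are dropped (rare-term filter);
    the surviving vocabulary is sorted lexicographically so label vectors
    are reproducible across runs.
    """
    path = Path(tsv)
    if not path.is_file():
        raise DataError(f"label table not found: {path}")
    if min_term_count < 1:
        raise ConfigurationError("min_term_count must be >= 1")
    per_protein: dict[str, set[str]] = {}
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0]:
                raise DataError(f"{path}:{lineno}: malformed row {line!r}")
            # an empty second field is a protein with no annotated terms
            terms = [t for t in parts[1].split(";") if t]
            per_protein.setdefault(parts[0], set()).update(terms)
    counts: dict[str, int] = {}
    for terms in per_protein.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    vocabulary = tuple(sorted(t for t, c in counts.items() if c >= min_term_count))
    term_index = {t: k for k, t in enumerate(vocabulary)}
    out: dict[str, GOLabelVector] = {}
    for pid, terms in per_protein.items():
        y = np.zeros(len(vocabulary), dtype=np.int8)
        for t in terms:
            k = term_index.get(t)
            if k is not None:
                y[k] = 1
        out[pid] = GOLabelVector(pid, category, y, vocabulary)
    return out


def write_go_labels(path: str | Path, labels: Mapping[str, GOLabelVector] | Iterable[GOLabelVector]) -> None:
    """Write label vectors back to the TSV interchange format."""
    items = labels.values() if isinstance(labels, Mapping) else labels
    with Path(path).open("w") as handle:
        for lab in items:
            terms = [lab.vocabulary[k] for k in np.nonzero(lab.labels)[0]]
            handle.write(f"{lab.protein_id}\t{';'.join(terms)}\n")


# ---------------------------------------------------------------------------
# Interchange formats: edge lists, coordinates, feature tables
# ---------------------------------------------------------------------------


def write_edge_list(path: str | Path, edges: Iterable[tuple[int, int]]) -> None:
    """Write an undirected edge list, one ``i j`` (0-based, i < j) per line."""
    with Path(path).open("w") as handle:
        for i, j in sorted(tuple(sorted(e)) for e in edges):
            handle.write(f"{i} {j}\n")


def read_edge_list(path: str | Path, n_nodes: int) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Read an edge list into an adjacency matrix + edge set."""
    adjacency = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    edges: set[tuple[int, int]] = set()
    with Path(path).open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: malformed edge row {line!r}")
            i, j = int(parts[0]), int(parts[1])
            if not (0 <= i < n_nodes and 0 <= j < n_nodes) or i == j:
                raise DataError(f"{path}:{lineno}: invalid edge ({i}, {j}) for {n_nodes} nodes")
            i, j = min(i, j), max(i, j)
            adjacency[i, j] = adjacency[j, i] = 1
            edges.add((i, j))
    return adjacency, edges


def write_coordinates(path: str | Path, coords: np.ndarray) -> None:
    np.savetxt(path, np.asarray(coords, dtype=np.float64), fmt="%.6f")


def write_feature_matrix(path: str | Path, features: np.ndarray) -> None:
    np.savetxt(path, np.asarray(features, dtype=np.float64), fmt="%.8g")


def graph_from_files(
    protein_id: str,
    edge_file: str | Path,
    feature_file: str | Path,
    coord_file: str | Path | None = None,
) -> ProteinGraph:
    """Assemble a :class:`ProteinGraph` from interchange files.

    The residue count is taken from the feature matrix; the edge list must
    be consistent with it.
    """
    if Path(feature_file).suffix.lower() == ".npy":
        X = np.load(feature_file, allow_pickle=False)
    else:
        X = np.loadtxt(feature_file, dtype=np.float64, ndmin=2)
    n = X.shape[0]
    adjacency, _ = read_edge_list(edge_file, n)
    coords = None
    if coord_file is not None:
        coords = _parse_coordinate_table(Path(coord_file))
    return ProteinGraph(protein_id, adjacency, X, coords=coords)


def graph_from_structure(
    protein_id: str,
    structure_file: str | Path,
    features: np.ndarray | str | Path,
    chain: str | None = None,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> ProteinGraph:
    """Parse a structure, build its contact graph and attach features."""
    coords = parse_ca_coordinates(structure_file, chain=chain)
    adjacency, _ = build_contact_graph(coords, threshold=threshold)
    if isinstance(features, (str, Path)):
        features = load_feature_matrix(features, expected_rows=coords.shape[0])
    return ProteinGraph(protein_id, adjacency, np.asarray(features), coords=coords)
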
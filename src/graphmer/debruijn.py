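"""Weighted De Bruijn graph construction and flattening to k-mer features.

Each sample's reads are converted to a directed graph whose nodes are the
k-mers occurring in the reads and whose edges connect k-mers overlapping
by k-1 bases; an edge's weight is the number of times it is observed
across all reads of the sample.  Because every length-(k+1) window of a
read induces exactly one edge, the graph flattened over the full node set
is equivalent to a (k+1)-mer count vector of length 4^k x 4: for every
possible node, four consecutive slots count how often each base (A,C,G,T)
follows that node.

Conventions fixed here (they define column semantics for interchange):

* k-mer ids are the base-4 positional encoding A=0, C=1, G=2, T=3, i.e.
  lexicographic rank, so id("A"*k) = 0 and id("T"*k) = 4^k - 1;
* the feature vector is node-major: entry ``source_id * 4 + next_base``;
* counting is forward-strand only — no reverse-complement collapsing —
  keeping the feature space the full 4^k x 4 grid;
* windows never span read boundaries, and any window containing an ``N``
  is skipped (the skip count is reported, not silently lost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fastq_io import CleanSample

__all__ = [
    "BASES",
    "KmerIndex",
    "EdgeList",
    "FeatureMatrix",
    "EdgeTableError",
    "kmer_to_id",
    "id_to_kmer",
    "build_edges",
    "edges_to_vector",
    "featurize_cohort",
    "export_edge_table",
    "import_edge_table",
    "feature_names",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# byte-level lookup: A/C/G/T -> 0..3, N (and anything else) -> -1
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _CODE_TABLE[ord(_b)] = _c

MIN_K, MAX_K = 2, 12


class EdgeTableError(ValueError):
    """Malformed or invariant-violating edge table row."""


@dataclass(frozen=True)
class KmerIndex:
    """Lexicographic base-4 indexing of all 4^k k-mers (A<C<G<T)."""

    k: int

    def __post_init__(self) -> None:
        if not MIN_K <= self.k <= MAX_K:
            raise ValueError(f"k must be in [{MIN_K}, {MAX_K}], got {self.k}")

    @property
    def size(self) -> int:
        return 4**self.k

    def to_id(self, kmer: str) -> int:
        return kmer_to_id(kmer)

    def to_kmer(self, kmer_id: int) -> str:
        return id_to_kmer(kmer_id, self.k)


def kmer_to_id(kmer: str) -> int:
    """Base-4 positional encoding of a k-mer (A=0,C=1,G=2,T=3).

    Equals the k-mer's rank in the lexicographic enumeration of all
    length-k strings over {A,C,G,T}.
    """
    value = 0
    for ch in kmer:
        code = _BASE_CODE.get(ch)
        if code is None:
            raise ValueError(f"invalid base {ch!r} in k-mer {kmer!r}")
        value = value * 4 + code
    return value


def id_to_kmer(kmer_id: int, k: int) -> str:
    """Inverse of :func:`kmer_to_id` for length ``k``."""
    if not 0 <= kmer_id < 4**k:
        raise ValueError(f"k-mer id {kmer_id} out of range for k={k}")
    chars = []
    for _ in range(k):
        chars.append(BASES[kmer_id % 4])
        kmer_id //= 4
    return "".join(reversed(chars))


@dataclass
class EdgeList:
    """Weighted De Bruijn edges of one sample.

    ``edges`` maps (source k-mer id, destination k-mer id) to a positive
    weight: the number of (k+1)-mer windows inducing that edge.
    ``skipped_windows`` counts windows dropped for containing N.
    """

    graph_id: str
    k: int
    edges: dict[tuple[int, int], int] = field(default_factory=dict)
    skipped_windows: int = 0

    def total_weight(self) -> int:
        return sum(self.edges.values())


def _encode_read(read: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(read.encode("ascii"), dtype=np.uint8)]


def _window_values(sample: CleanSample, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(k+1)-mer integer values over all clean windows of all reads.

    Returns (unique values, counts, number of skipped N-windows).
    Windows are confined to single reads.
    """
    w = k + 1
    powers = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    chunks: list[np.ndarray] = []
    skipped = 0
    for read in sample.reads:
        if len(read) < w:
            continue
        codes = _encode_read(read)
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        clean = (windows >= 0).all(axis=1)
        skipped += int(len(windows) - clean.sum())
        if clean.any():
            chunks.append(windows[clean].astype(np.int64) @ powers)
    if not chunks:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), skipped
    values, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return values, counts, skipped


def build_edges(sample: CleanSample, k: int) -> EdgeList:
    """Build the sample's weighted De Bruijn graph at k-mer length ``k``.

    Every window ``read[i : i+k+1]`` made only of A/C/G/T adds weight 1 to
    the edge from ``read[i : i+k]`` to ``read[i+1 : i+k+1]`` — the two
    k-mers overlap by k-1 bases by construction.  Reads shorter than k+1
    contribute nothing; N-containing windows are skipped and counted.
    """
    if not MIN_K <= k <= MAX_K:
        raise ValueError(f"k must be in [{MIN_K}, {MAX_K}], got {k}")
    values, counts, skipped = _window_values(sample, k)
    size_k = 4**k
    # a (k+1)-mer value v splits as: source = v // 4, destination = v % 4^k
    edges = {
        (int(v) // 4, int(v) % size_k): int(c) for v, c in zip(values, counts)
    }
    if skipped:
        logger.info(
            "sample %s: skipped %d N-containing windows at k=%d",
            sample.sample_id, skipped, k,
        )
    return EdgeList(graph_id=sample.sample_id, k=k, edges=edges,
                    skipped_windows=skipped)


def _check_overlap(src: int, dst: int, k: int) -> bool:
    # suffix(k-1) of source == prefix(k-1) of destination
    return src % 4 ** (k - 1) == dst // 4


def edges_to_vector(edge_list: EdgeList, k: int | None = None) -> np.ndarray:
    """Flatten an EdgeList into the 4^(k+1) node-major count vector.

    Entry ``source_id * 4 + last_base(destination)`` holds the edge's
    weight; for each node its four consecutive slots count the next base
    in order A,C,G,T.
    """
    if k is None:
        k = edge_list.k
    elif k != edge_list.k:
        raise ValueError(f"edge list built at k={edge_list.k}, requested k={k}")
    vec = np.zeros(4 ** (k + 1), dtype=np.int64)
    for (src, dst), weight in edge_list.edges.items():
        if not _check_overlap(src, dst, k):
            raise EdgeTableError(
                f"edge {id_to_kmer(src, k)}->{id_to_kmer(dst, k)} violates "
                f"the k-1 overlap invariant"
            )
        vec[src * 4 + dst % 4] = weight
    return vec


def feature_names(k: int) -> list[str]:
    """Column names ``<kmer>_<nextbase>`` in node-major vector order."""
    return [
        f"{id_to_kmer(node, k)}_{base}"
        for node in range(4**k)
        for base in BASES
    ]


@dataclass
class FeatureMatrix:
    """Samples x 4^(k+1) flattened transition counts with optional labels.

    ``data`` is a DataFrame indexed by sample_id with one column per
    (k-mer, next-base) pair; ``labels`` aligns with ``data.index``.
    """

    k: int
    data: pd.DataFrame
    labels: Optional[pd.Series] = None

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def normalized(self) -> "FeatureMatrix":
        """Per-sample total-sum normalization (off by default upstream)."""
        totals = self.data.sum(axis=1).replace(0, 1)
        return FeatureMatrix(self.k, self.data.div(totals, axis=0), self.labels)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        if self.labels is not None:
            out["label"] = self.labels
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        df.index = df.index.astype(str)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").astype(int)
        n = df.shape[1]
        k = int(round(np.log(n) / np.log(4))) - 1
        if 4 ** (k + 1) != n:
            raise ValueError(f"{path}: {n} feature columns is not 4^(k+1)")
        return cls(k=k, data=df, labels=labels)


def featurize_cohort(samples: Sequence[CleanSample], k: int) -> FeatureMatrix:
    """Featurize a cohort: one row of 4^(k+1) transition counts per sample.

    Row order follows input order; labels are attached where known.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    rows = np.zeros((len(samples), 4 ** (k + 1)), dtype=np.int64)
    for i, sample in enumerate(samples):
        rows[i] = edges_to_vector(build_edges(sample, k))
    data = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                        columns=feature_names(k))
    labels = None
    if any(s.label is not None for s in samples):
        labels = pd.Series(
            [s.label for s in samples], index=data.index, name="label"
        )
    return FeatureMatrix(k=k, data=data, labels=labels)


EDGE_TABLE_COLUMNS = ("graph_id", "source_id", "destination_id", "weight")


def export_edge_table(
    edge_lists: Iterable[EdgeList], path: str | Path
) -> None:
    """Write the combined per-k edge file as 4-column TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(EDGE_TABLE_COLUMNS) + "\n")
        for el in edge_lists:
            for (src, dst), weight in sorted(el.edges.items()):
                fh.write(f"{el.graph_id}\t{src}\t{dst}\t{weight}\n")


def import_edge_table(path: str | Path, k: int) -> list[EdgeList]:
    """Read a 4-column edge TSV back into per-sample EdgeLists.

    Validates weights (>= 1), id ranges, the k-1 overlap invariant and
    (source, destination) uniqueness per graph; errors name the line.
    """
    path = Path(path)
    size_k = 4**k
    result: dict[str, EdgeList] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EDGE_TABLE_COLUMNS:
            raise EdgeTableError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise EdgeTableError(f"{path}: line {lineno}: expected 4 columns")
            graph_id, src_s, dst_s, w_s = parts
            try:
                src, dst, weight = int(src_s), int(dst_s), int(w_s)
            except ValueError as exc:
                raise EdgeTableError(f"{path}: line {lineno}: {exc}") from exc
            if weight < 1:
                raise EdgeTableError(
                    f"{path}: line {lineno}: weight must be >= 1, got {weight}"
                )
            if not (0 <= src < size_k and 0 <= dst < size_k):
                raise EdgeTableError(
                    f"{path}: line {lineno}: k-mer id out of range for k={k}"
                )
            if not _check_overlap(src, dst, k):
                raise EdgeTableError(
                    f"{path}: line {lineno}: edge "
                    f"{id_to_kmer(src, k)}->{id_to_kmer(dst, k)} violates the "
                    f"k-1 overlap invariant"
                )
            el = result.setdefault(graph_id, EdgeList(graph_id=graph_id, k=k))
            if (src, dst) in el.edges:
                raise EdgeTableError(
                    f"{path}: line {lineno}: duplicate edge for graph {graph_id}"
                )
            el.edges[(src, dst)] = weight
    return list(result.values())
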
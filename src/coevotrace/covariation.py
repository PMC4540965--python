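"""Column-pair covariation statistics on multiple sequence alignments.

Implements the plain-count covariation measures (Shannon entropy, mutual
information, MI normalized by joint entropy, the average-product-corrected
MIp, a permutation-null-corrected MI, and the chi-square statistic), the
invariant-column filter applied before any covariation analysis, and readers
for externally computed score tables (PSICOV / direct-information style
output), which are consumed from files and never re-derived.

Conventions: logarithms are base 2 (bits), so two identical evenly split
binary columns have MI = 1 bit; gaps are handled by pairwise-complete
deletion; frequencies are raw counts without pseudocounts; no sequence
weighting is applied.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"

__all__ = [
    "GAP",
    "Alignment",
    "PairScoreTable",
    "EmptyColumnError",
    "InsufficientDataError",
    "DegenerateAlignmentError",
    "read_fasta",
    "write_fasta",
    "column_entropy",
    "mutual_information",
    "joint_entropy",
    "mi_over_joint_entropy",
    "mip",
    "mi_adj",
    "chi_square_pair",
    "filter_invariant_columns",
    "score_all_pairs",
    "read_external_scores",
]


class EmptyColumnError(ValueError):
    """A column contains no non-gap symbols."""


class InsufficientDataError(ValueError):
    """Fewer than two rows where both columns are non-gap."""


class DegenerateAlignmentError(ValueError):
    """The alignment carries no usable covariation signal (e.g. mean MI 0)."""


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment.

    Attributes
    ----------
    ids
        Sequence identifiers, unique, in input order.
    matrix
        ``(n_sequences, n_columns)`` array of single-character symbols
        (dtype ``<U1``); gaps are ``'-'``.
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            dupes = {x for x in self.ids if self.ids.count(x) > 1}
            raise ValueError(f"duplicate sequence identifiers: {sorted(dupes)}")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def alphabet(self) -> set[str]:
        return set(np.unique(self.matrix)) - {GAP}

    def column(self, i: int) -> np.ndarray:
        """1-based column accessor."""
        if not 1 <= i <= self.n_columns:
            raise IndexError(f"column {i} out of range 1..{self.n_columns}")
        return self.matrix[:, i - 1]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for name, seq in records:
            ids.append(name)
            seqs.append(list(seq))
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        return cls(ids, np.array(seqs, dtype="<U1"))


def read_fasta(path: str | Path) -> Alignment:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Alignment.from_records(records)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=name, description="")
        for name, row in zip(aln.ids, aln.matrix)
    ]
    SeqIO.write(records, str(path), "fasta")


def _counts(column: np.ndarray) -> dict[str, int]:
    vals, counts = np.unique(column[column != GAP], return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def column_entropy(column: np.ndarray) -> float:
    """Shannon entropy (bits) of the non-gap symbol frequencies of a column."""
    counts = _counts(np.asarray(column, dtype="<U1"))
    n = sum(counts.values())
    if n == 0:
        raise EmptyColumnError("column contains only gaps")
    p = np.array(list(counts.values()), dtype=float) / n
    return float(-(p * np.log2(p)).sum())


def _complete_rows(colA: np.ndarray, colB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    colA = np.asarray(colA, dtype="<U1")
    colB = np.asarray(colB, dtype="<U1")
    if colA.shape != colB.shape:
        raise ValueError("columns have different lengths")
    keep = (colA != GAP) & (colB != GAP)
    if keep.sum() < 2:
        raise InsufficientDataError(
            f"only {int(keep.sum())} rows where both columns are non-gap"
        )
    return colA[keep], colB[keep]


def _joint_table(colA: np.ndarray, colB: np.ndarray) -> np.ndarray:
    a, b = _complete_rows(colA, colB)
    asyms, ai = np.unique(a, return_inverse=True)
    bsyms, bi = np.unique(b, return_inverse=True)
    table = np.zeros((len(asyms), len(bsyms)))
    np.add.at(table, (ai, bi), 1.0)
    return table


def mutual_information(colA: np.ndarray, colB: np.ndarray) -> float:
    """Mutual information (bits) between two columns over pairwise-complete
    rows; bounded by ``0 <= MI <= min(H_A, H_B)``."""
    table = _joint_table(colA, colB)
    n = table.sum()
    pxy = table / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pxy > 0, pxy * np.log2(pxy / (px * py)), 0.0)
    return float(max(terms.sum(), 0.0))


def joint_entropy(colA: np.ndarray, colB: np.ndarray) -> float:
    """Shannon entropy (bits) of the joint symbol-pair distribution."""
    table = _joint_table(colA, colB)
    p = table.ravel() / table.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mi_over_joint_entropy(colA: np.ndarray, colB: np.ndarray) -> float:
    """MI normalized by the joint entropy H(X,Y); in [0, 1].

    Corrects for site entropy so that highly variable pairs are not favored
    merely for being variable.  Undefined when both columns are constant
    (H(X,Y) = 0); such pairs are excluded upstream by the invariant-site
    filter.
    """
    h = joint_entropy(colA, colB)
    if h <= 0:
        raise DegenerateAlignmentError("H(X,Y) = 0: both columns constant")
    return mutual_information(colA, colB) / h


def mip(mi_matrix: np.ndarray) -> np.ndarray:
    """Average product correction (APC) applied to an all-pairs MI matrix.

    ``MIp(a,b) = MI(a,b) - MI(a,.) * MI(b,.) / <MI>`` where ``MI(a,.)`` is
    column a's mean MI with all other columns and ``<MI>`` the mean over all
    distinct pairs.  The correction removes shared background signal
    (phylogeny plus entropy) from every pair.

    Parameters
    ----------
    mi_matrix
        Symmetric ``(L, L)`` matrix of pairwise MI values with zero diagonal.

    Returns
    -------
    ``(L, L)`` matrix of corrected scores (diagonal zero).
    """
    m = np.asarray(mi_matrix, dtype=float)
    L = m.shape[0]
    if L < 3:
        raise ValueError("APC requires at least 3 columns")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("MI matrix must be symmetric")
    col_mean = m.sum(axis=1) / (L - 1)
    overall = m.sum() / (L * (L - 1))
    if overall == 0:
        raise DegenerateAlignmentError("mean MI is 0: APC undefined")
    apc = np.outer(col_mean, col_mean) / overall
    out = m - apc
    np.fill_diagonal(out, 0.0)
    return out


def mi_adj(
    colA: np.ndarray,
    colB: np.ndarray,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """MI corrected by a permutation null: MI minus the mean MI of
    ``n_shuffles`` row-permuted replicates of ``colB``.

    This is a null-model correction in the spirit of published
    background-adjusted MI scores; the exact published formula is not
    reproduced here (see the methods note).  Deterministic given the seed.
    """
    if n_shuffles < 0:
        raise ValueError(f"n_shuffles must be >= 0, got {n_shuffles}")
    observed = mutual_information(colA, colB)
    if n_shuffles == 0:
        return observed
    rng = np.random.default_rng(seed)
    colB = np.asarray(colB, dtype="<U1")
    null = [
        mutual_information(colA, rng.permutation(colB)) for _ in range(n_shuffles)
    ]
    return observed - float(np.mean(null))


def chi_square_pair(colA: np.ndarray, colB: np.ndarray) -> float:
    """Pearson chi-square statistic comparing observed symbol-pair counts to
    the product-of-marginals expectation; no continuity correction; cells
    with zero expectation are skipped."""
    table = _joint_table(colA, colB)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = expected > 0
    return float(((table[mask] - expected[mask]) ** 2 / expected[mask]).sum())


def filter_invariant_columns(aln: Alignment) -> tuple[Alignment, list[int]]:
    """Remove columns with <= 1 distinct non-gap symbol.

    Returns the filtered alignment and the kept columns' original 1-based
    indices (for downstream reporting).  Warns (not errors) when every
    column is invariant.
    """
    keep: list[int] = []
    for i in range(1, aln.n_columns + 1):
        col = aln.column(i)
        if len({s for s in col.tolist() if s != GAP}) > 1:
            keep.append(i)
    if not keep:
        warnings.warn("all columns are invariant; result is empty", UserWarning)
    sub = aln.matrix[:, [i - 1 for i in keep]]
    return Alignment(list(aln.ids), sub.reshape(aln.n_sequences, len(keep))), keep


@dataclass
class PairScoreTable:
    """Per-column-pair scores for every metric; the pipeline's central
    exchange format.

    ``df`` is indexed by the unordered 1-based column pair ``(i, j)`` with
    ``i < j``; each column holds one metric.  Externally loaded metrics may
    contain missing values.
    """

    df: pd.DataFrame
    n_columns: int

    @classmethod
    def empty(cls, n_columns: int) -> "PairScoreTable":
        index = pd.MultiIndex.from_tuples([], names=["i", "j"])
        return cls(pd.DataFrame(index=index), n_columns)

    def add_metric(self, name: str, values: Mapping[tuple[int, int], float]) -> None:
        for (i, j) in values:
            self._check_pair(i, j)
        if not values:
            self.df[name] = np.nan
            return
        s = pd.Series(dict(values), name=name)
        s.index = pd.MultiIndex.from_tuples(s.index, names=["i", "j"])
        self.df = self.df.join(s, how="outer")
        self.df.index.names = ["i", "j"]

    def metric(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise KeyError(f"unknown metric {name!r}; have {list(self.df.columns)}")
        return self.df[name]

    def _check_pair(self, i: int, j: int) -> None:
        if not (1 <= i < j <= self.n_columns):
            raise ValueError(
                f"invalid pair ({i}, {j}) for alignment with {self.n_columns} columns"
            )

    def to_tsv(self, path: str | Path) -> None:
        long = self.df.stack().rename("value").reset_index()
        long.columns = ["i", "j", "metric", "value"]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n_columns: int) -> "PairScoreTable":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot_table(index=["i", "j"], columns="metric", values="value")
        wide.columns.name = None
        return cls(wide, n_columns)


def score_all_pairs(
    aln: Alignment,
    metrics: Sequence[str] = ("H", "MI", "MI_over_HXY", "MIp", "chi2"),
    mi_adj_shuffles: int = 20,
    seed: int = 0,
) -> PairScoreTable:
    """Compute the requested covariation metrics for every column pair.

    Recognized metrics: ``MI``, ``MI_over_HXY``, ``MIp``, ``MI_adj``,
    ``chi2`` (``H`` adds per-column entropies H_i / H_j as pair columns).
    Columns should already have passed :func:`filter_invariant_columns`.
    """
    L = aln.n_columns
    table = PairScoreTable.empty(L)
    pairs = list(itertools.combinations(range(1, L + 1), 2))
    cols = {i: aln.column(i) for i in range(1, L + 1)}

    mi_vals: dict[tuple[int, int], float] = {}
    if {"MI", "MIp", "MI_over_HXY"} & set(metrics):
        for i, j in pairs:
            mi_vals[(i, j)] = mutual_information(cols[i], cols[j])
    if "H" in metrics:
        ent = {i: column_entropy(cols[i]) for i in cols}
        table.add_metric("H_i", {(i, j): ent[i] for i, j in pairs})
        table.add_metric("H_j", {(i, j): ent[j] for i, j in pairs})
    if "MI" in metrics:
        table.add_metric("MI", mi_vals)
    if "MI_over_HXY" in metrics:
        table.add_metric(
            "MI_over_HXY",
            {(i, j): mi_vals[(i, j)] / joint_entropy(cols[i], cols[j]) for i, j in pairs},
        )
    if "MIp" in metrics:
        m = np.zeros((L, L))
        for (i, j), v in mi_vals.items():
            m[i - 1, j - 1] = m[j - 1, i - 1] = v
        corrected = mip(m)
        table.add_metric("MIp", {(i, j): corrected[i - 1, j - 1] for i, j in pairs})
    if "MI_adj" in metrics:
        rng = np.random.default_rng(seed)
        table.add_metric(
            "MI_adj",
            {
                (i, j): mi_adj(cols[i], cols[j], mi_adj_shuffles, rng)
                for i, j in pairs
            },
        )
    if "chi2" in metrics:
        table.add_metric("chi2", {(i, j): chi_square_pair(cols[i], cols[j]) for i, j in pairs})
    return table


def read_external_scores(
    path: str | Path, metric_name: str, n_columns: int
) -> dict[tuple[int, int], float]:
    """Parse an external covariation score file (PSICOV / EVFold style).

    Rows are whitespace- or comma-delimited with 1-based residue indices in
    the first two fields and the score in the last field; intermediate
    fields (e.g. PSICOV's distance-bin columns) are ignored.  Self-pairs are
    rejected; on duplicate pairs the last entry wins with a logged warning.
    """
    scores: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields, got {len(fields)}")
            try:
                i, j = int(fields[0]), int(fields[1])
                value = float(fields[-1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            if i == j:
                raise ValueError(f"{path}:{lineno}: self-pair ({i}, {j}) is invalid")
            if not (1 <= i <= n_columns and 1 <= j <= n_columns):
                raise ValueError(
                    f"{path}:{lineno}: pair ({i}, {j}) outside alignment bounds 1..{n_columns}"
                )
            key = (min(i, j), max(i, j))
            if key in scores:
                logger.warning("%s:%d: duplicate pair %s; last value wins", path, lineno, key)
            scores[key] = value
    return scores
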
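"""Coevolution-based interaction scores: in-silico two-hybrid (i2h) and
mirror-tree (MT).

Both operate on a :class:`~tcspred.io_data.PairedAlignment`, i.e. the two
proteins' MSAs restricted to common species and matched row-by-row.

The i2h score looks for correlated (compensatory) mutations between the
two proteins: for every alignment column a vector of residue-pair
similarities across all unordered sequence pairs is built (McLachlan
table by default), columns are correlated pairwise between the two
proteins, and the score is the fraction of inter-protein column pairs
whose Pearson correlation reaches a threshold (default 0.8).  Interacting
partners accumulate such high-correlation column pairs because a
substitution in one binding surface selects for a compensating
substitution in the other.

The mirror-tree score exploits the tendency of interacting proteins'
phylogenies to mirror each other: each protein's inter-species distance
matrix (fractional sequence identity distance) is a cheap proxy for its
tree, and the score is the Pearson correlation of the two matrices'
upper triangles.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from tcspred.errors import DataError, MissingFeature
from tcspred.io_data import PairedAlignment

GAP = "-"
#: minimum number of sequence pairs shared by two similarity vectors for
#: their correlation to be meaningful; below this r is defined as 0.
MIN_SHARED = 10


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise sequence distances in [0, 1]."""

    species_list: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species_list)
        if v.shape != (n, n):
            raise DataError("distance matrix shape out of step with species")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise DataError("distance matrix must be symmetric with zero diagonal")
        if v.min() < 0 or v.max() > 1:
            raise DataError("distances must lie in [0, 1]")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.species_list), k=1)
        return self.values[iu]


@lru_cache(maxsize=8)
def load_similarity_table(name: str = "MCLACHLAN") -> dict[tuple[str, str], float]:
    """Load a symmetric amino-acid similarity table by name.

    Any table shipped with Biopython may be named; a path to a square
    labelled TSV over the 20 amino acids is also accepted.
    """
    if "/" in name or name.endswith(".tsv"):
        return _read_similarity_tsv(name)
    mat = substitution_matrices.load(name)
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def _read_similarity_tsv(path: str) -> dict[tuple[str, str], float]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    cols = lines[0].split("\t")[1:]
    table: dict[tuple[str, str], float] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        row = parts[0]
        for col, val in zip(cols, parts[1:]):
            table[(row, col)] = float(val)
    for (a, b), v in list(table.items()):
        if abs(table.get((b, a), v) - v) > 1e-9:
            raise DataError(f"similarity table not symmetric at ({a},{b})")
    return table


# ---------------------------------------------------------------------------
# i2h
# ---------------------------------------------------------------------------

def column_similarity_vector(
    rows: list[str],
    column: int,
    table: dict[tuple[str, str], float] | None = None,
) -> np.ndarray:
    """Similarity of the residues of every unordered sequence pair at one
    alignment column; entries involving a gap are NaN (missing)."""
    if table is None:
        table = load_similarity_table()
    residues = [r[column] for r in rows]
    n = len(residues)
    out = np.full(n * (n - 1) // 2, np.nan)
    idx = 0
    for k in range(n):
        for l in range(k + 1, n):
            a, b = residues[k], residues[l]
            if a != GAP and b != GAP:
                out[idx] = table.get((a, b), table.get((b, a), 0.0))
            idx += 1
    return out


def position_pair_correlation(vec_i: np.ndarray, vec_j: np.ndarray) -> float:
    """Pearson correlation over entries present in both vectors.

    Defined as 0 when fewer than :data:`MIN_SHARED` entries are shared or
    either vector is constant over the shared entries, so downstream
    feature vectors stay numeric.
    """
    if len(vec_i) != len(vec_j):
        raise DataError("similarity vectors must share the sequence-pair index")
    mask = ~(np.isnan(vec_i) | np.isnan(vec_j))
    if mask.sum() < MIN_SHARED:
        return 0.0
    x, y = vec_i[mask], vec_j[mask]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return 0.0 if np.isnan(r) else r


def variable_columns(rows: list[str], max_gap_frac: float = 0.5) -> list[int]:
    """Columns with >= 2 distinct non-gap residues and <= ``max_gap_frac``
    gaps; constant or gappy columns carry no covariation signal."""
    n = len(rows)
    length = len(rows[0])
    out = []
    for j in range(length):
        col = [r[j] for r in rows]
        gaps = col.count(GAP)
        if gaps / n > max_gap_frac:
            continue
        if len({c for c in col if c != GAP}) >= 2:
            out.append(j)
    return out


def i2h_score(
    pa: PairedAlignment,
    threshold: float = 0.8,
    table: dict[tuple[str, str], float] | None = None,
) -> float:
    """In-silico two-hybrid score: fraction of inter-protein variable
    column pairs with correlation >= ``threshold``.

    Raises :class:`MissingFeature` when either protein has no variable
    column, i.e. no covariation signal can exist.
    """
    if table is None:
        table = load_similarity_table()
    cols_a = variable_columns(pa.rows_a)
    cols_b = variable_columns(pa.rows_b)
    if not cols_a or not cols_b:
        raise MissingFeature("no variable columns on one side of the pair")
    vecs_a = np.array([column_similarity_vector(pa.rows_a, j, table) for j in cols_a])
    vecs_b = np.array([column_similarity_vector(pa.rows_b, j, table) for j in cols_b])
    if not (np.isnan(vecs_a).any() or np.isnan(vecs_b).any()):
        # gap-free: all correlations at once via standardised dot products
        m = vecs_a.shape[1]
        if m < MIN_SHARED:
            return 0.0
        sa = vecs_a.std(axis=1)
        sb = vecs_b.std(axis=1)
        za = np.where(sa[:, None] > 0,
                      (vecs_a - vecs_a.mean(axis=1, keepdims=True))
                      / np.where(sa[:, None] > 0, sa[:, None], 1.0), 0.0)
        zb = np.where(sb[:, None] > 0,
                      (vecs_b - vecs_b.mean(axis=1, keepdims=True))
                      / np.where(sb[:, None] > 0, sb[:, None], 1.0), 0.0)
        corr = za @ zb.T / m  # zero-variance rows contribute r = 0
        return float((corr >= threshold).sum() / corr.size)
    high = total = 0
    for va in vecs_a:
        for vb in vecs_b:
            total += 1
            if position_pair_correlation(va, vb) >= threshold:
                high += 1
    return high / total


# ---------------------------------------------------------------------------
# mirror-tree
# ---------------------------------------------------------------------------

def identity_distance_matrix(species_list: list[str],
                             rows: list[str]) -> DistanceMatrix:
    """Fractional-identity distances: ``d = 1 - identical / compared``
    over columns where neither row is gapped."""
    if len(rows) < 3:
        raise DataError("need >= 3 species for a distance matrix")
    arr = np.array([list(r) for r in rows])
    n = len(rows)
    d = np.zeros((n, n))
    for k in range(n):
        for l in range(k + 1, n):
            ok = (arr[k] != GAP) & (arr[l] != GAP)
            total = int(ok.sum())
            if total == 0:
                raise DataError(
                    f"rows {species_list[k]} and {species_list[l]} share no "
                    "comparable columns")
            same = int((arr[k][ok] == arr[l][ok]).sum())
            d[k, l] = d[l, k] = 1.0 - same / total
    return DistanceMatrix(list(species_list), d)


def mirror_tree_score(pa: PairedAlignment) -> float:
    """Correlation of the two proteins' distance matrices over the common
    species.  Raises :class:`MissingFeature` when either matrix is
    constant (no tree signal to compare)."""
    da = identity_distance_matrix(pa.species_list, pa.rows_a).upper_triangle()
    db = identity_distance_matrix(pa.species_list, pa.rows_b).upper_triangle()
    if da.std() == 0.0 or db.std() == 0.0:
        raise MissingFeature("constant distance matrix on one side")
    return float(np.corrcoef(da, db)[0, 1])
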
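"""Pairwise haplotype F_ST between localities with permutation significance.

F_ST is computed from mean pairwise distances among individuals::

    F_ST = (d_b - (d_w(A) + d_w(B)) / 2) / d_b

where ``d_w`` is the mean distance over all unordered within-unit pairs
and ``d_b`` the mean over all cross-unit pairs.  The default distance is
haplotype identity (0 if two individuals carry the same haplotype, 1
otherwise), i.e. the frequency-based "conventional" F_ST; a
sequence-mismatch (Hamming) distance variant is available behind the
``distance`` flag.  When ``d_b = 0`` (no between-unit diversity at all)
the statistic is defined as 0.  Negative estimates are reported as
computed — significance is judged by permutation only.

The permutation test pools the individuals of the two units and
repeatedly re-partitions them at random into groups of the original
sizes; the p-value uses the add-one estimator

    p = (1 + #{permuted F_ST >= observed}) / (1 + n_permutations)

which never returns an exact zero.  Default ``n_permutations`` is 10 000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable

DEFAULT_PERMUTATIONS = 10_000

DISTANCES = ("identity", "hamming")


class FstError(ValueError):
    """Raised for invalid F_ST inputs (unit too small, bad parameters)."""


@dataclass(frozen=True)
class FstResult:
    """Pairwise F_ST with its permutation p-value."""

    unit_a: str
    unit_b: str
    fst: float
    p_value: float
    n_permutations: int
    seed: int
    n_a: int
    n_b: int


@dataclass(frozen=True)
class FstMatrix:
    """Symmetric F_ST and p-value matrices over a set of units."""

    units: tuple
    fst: pd.DataFrame
    p: pd.DataFrame
    n_permutations: int
    seed: int
    missing_pairs: tuple = ()

    def result(self, unit_a: str, unit_b: str) -> tuple:
        """(fst, p) for a unit pair; raises KeyError if absent."""
        try:
            f = float(self.fst.loc[unit_a, unit_b])
            p = float(self.p.loc[unit_a, unit_b])
        except KeyError as exc:
            raise KeyError(f"unit pair ({unit_a}, {unit_b}) not in matrix") from exc
        if np.isnan(f):
            raise KeyError(
                f"unit pair ({unit_a}, {unit_b}) has no F_ST (insufficient samples)"
            )
        return f, p


def _pair_sums(c: np.ndarray, d: np.ndarray | None) -> np.ndarray:
    """Sum of distances over ordered within-group pairs, for count rows ``c``.

    ``c`` has shape (m, k); with identity distance (d is None) this is
    n^2 - sum c_i^2, otherwise c D c^T (diagonal of D is zero).
    """
    n = c.sum(axis=1)
    if d is None:
        return n.astype(float) ** 2 - (c.astype(float) ** 2).sum(axis=1)
    return np.einsum("mi,ij,mj->m", c.astype(float), d, c.astype(float))


def _cross_sums(ca: np.ndarray, cb: np.ndarray, d: np.ndarray | None) -> np.ndarray:
    na = ca.sum(axis=1).astype(float)
    nb = cb.sum(axis=1).astype(float)
    if d is None:
        return na * nb - (ca.astype(float) * cb.astype(float)).sum(axis=1)
    return np.einsum("mi,ij,mj->m", ca.astype(float), d, cb.astype(float))


def fst_from_counts(
    counts_a: np.ndarray, counts_b: np.ndarray, distance_matrix: np.ndarray | None = None
) -> float:
    """F_ST from per-haplotype count vectors of the two units."""
    ca = np.atleast_2d(np.asarray(counts_a, dtype=np.int64))
    cb = np.atleast_2d(np.asarray(counts_b, dtype=np.int64))
    return float(_fst_rows(ca, cb, distance_matrix)[0])


def _fst_rows(ca: np.ndarray, cb: np.ndarray, d: np.ndarray | None) -> np.ndarray:
    na = ca.sum(axis=1).astype(float)
    nb = cb.sum(axis=1).astype(float)
    if np.any(na < 2) or np.any(nb < 2):
        raise FstError("each unit needs >= 2 individuals")
    dwa = _pair_sums(ca, d) / (na * (na - 1.0))
    dwb = _pair_sums(cb, d) / (nb * (nb - 1.0))
    db = _cross_sums(ca, cb, d) / (na * nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = (db - 0.5 * (dwa + dwb)) / db
    return np.where(db > 0, fst, 0.0)


def permutation_test_counts(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    distance_matrix: np.ndarray | None = None,
) -> tuple:
    """(observed F_ST, permutation p-value) from count vectors.

    Reproducible given ``seed``; the partition sizes are those of the two
    input units.  The test is symmetric in its arguments.
    """
    if n_permutations < 1:
        raise FstError("n_permutations must be >= 1")
    ca = np.asarray(counts_a, dtype=np.int64)
    cb = np.asarray(counts_b, dtype=np.int64)
    observed = fst_from_counts(ca, cb, distance_matrix)

    # canonical orientation so that swapping unit labels cannot change p
    if cb.sum() < ca.sum() or (cb.sum() == ca.sum() and tuple(cb) < tuple(ca)):
        ca, cb = cb, ca
    k = ca.size
    na = int(ca.sum())
    n = na + int(cb.sum())
    pooled = np.repeat(np.arange(k), ca + cb)

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    labels = pooled[order]
    hap_index = np.arange(k)
    perm_a = (labels[:, :na, None] == hap_index).sum(axis=1)
    perm_b = (labels[:, na:, None] == hap_index).sum(axis=1)
    perm_fst = _fst_rows(perm_a, perm_b, distance_matrix)
    n_ge = int(np.sum(perm_fst >= observed - 1e-12))
    p = (1 + n_ge) / (1 + n_permutations)
    return observed, p


def _pair_counts(table: HaplotypeTable, unit_a: str, unit_b: str) -> tuple:
    cf = table.counts_frame("locality")
    for u in (unit_a, unit_b):
        if u not in cf.columns:
            raise FstError(f"unit {u!r} not present in table")
    ca = cf[unit_a].to_numpy()
    cb = cf[unit_b].to_numpy()
    keep = (ca + cb) > 0
    return ca[keep], cb[keep], np.array(table.haplotypes, dtype=object)[keep]


def _distance_matrix(haps, variable_sites) -> np.ndarray:
    seqs = [
        "".join(h.sequence[c - 1] for c in variable_sites) for h in haps
    ]
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    if mat.size == 0:
        return np.zeros((len(haps), len(haps)))
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)


def pairwise_fst(
    table: HaplotypeTable, unit_a: str, unit_b: str, distance: str = "identity"
) -> float:
    """Haplotype F_ST between two localities (no significance test)."""
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    ca, cb, haps = _pair_counts(table, unit_a, unit_b)
    d = _distance_matrix(haps, table.variable_sites) if distance == "hamming" else None
    return fst_from_counts(ca, cb, d)


def fst_permutation_test(
    table: HaplotypeTable,
    unit_a: str,
    unit_b: str,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    distance: str = "identity",
) -> FstResult:
    """Permutation-tested haplotype F_ST between two localities."""
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    ca, cb, haps = _pair_counts(table, unit_a, unit_b)
    d = _distance_matrix(haps, table.variable_sites) if distance == "hamming" else None
    fst, p = permutation_test_counts(ca, cb, n_permutations, seed, d)
    return FstResult(
        unit_a=unit_a,
        unit_b=unit_b,
        fst=fst,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        n_a=int(ca.sum()),
        n_b=int(cb.sum()),
    )


def fst_matrix(
    table: HaplotypeTable,
    units: list | None = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    distance: str = "identity",
) -> FstMatrix:
    """All-pairs permutation-tested F_ST.

    Per-pair sub-seeds are derived deterministically from the master seed
    and the (sorted) unit pair, so individual pairs can be reproduced in
    isolation.  Pairs where a unit has fewer than two individuals are
    recorded as missing (NaN) rather than failing the whole matrix.
    """
    if units is None:
        units = table.units("locality")
    units = sorted(units)
    fst = pd.DataFrame(np.zeros((len(units), len(units))), index=units, columns=units)
    p = pd.DataFrame(np.ones((len(units), len(units))), index=units, columns=units)
    missing = []
    for i, ua in enumerate(units):
        for j in range(i + 1, len(units)):
            ub = units[j]
            sub_seed = np.random.SeedSequence([seed, i, j])
            try:
                ca, cb, haps = _pair_counts(table, ua, ub)
                d = (
                    _distance_matrix(haps, table.variable_sites)
                    if distance == "hamming"
                    else None
                )
                f, pv = permutation_test_counts(
                    ca, cb, n_permutations, sub_seed, d
                )
            except FstError:
                missing.append((ua, ub))
                f, pv = np.nan, np.nan
            fst.loc[ua, ub] = fst.loc[ub, ua] = f
            p.loc[ua, ub] = p.loc[ub, ua] = pv
    return FstMatrix(
        units=tuple(units),
        fst=fst,
        p=p,
        n_permutations=n_permutations,
        seed=seed,
        missing_pairs=tuple(missing),
    )
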
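"""Pedigree handling: validation, relatedness, and gene dropping.

A pedigree is the backbone of every animal-model analysis: it encodes the
expected additive-genetic covariance between individuals (the numerator
relationship matrix ``A``) and, read generatively, it is a simulation
scheme for breeding values ("gene dropping").

Individuals are stored topologically sorted (parents before offspring),
which makes the tabular method for ``A``, Henderson's rules for ``A^-1``
and gene dropping single forward passes.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "inbreeding",
    "relationship_matrix",
    "a_inverse",
    "gene_drop",
]

#: sentinel index for an unknown parent
UNKNOWN = -1

#: values in a CSV that denote a missing parent / cohort / sex
_NA_STRINGS = {"", "NA", "NaN", "nan", "None", "*"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids:
        Individual identifiers, parents always before offspring.
    dam, sire:
        Integer positions of each individual's parents in ``ids``;
        ``-1`` where the parent is unknown.
    cohort:
        Return-year of each individual (``nan`` if unknown).
    sex:
        ``"F"``, ``"M"`` or ``"U"``.
    """

    ids: np.ndarray
    dam: np.ndarray
    sire: np.ndarray
    cohort: np.ndarray
    sex: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> np.ndarray:
        """Boolean mask of individuals with both parents unknown."""
        return (self.dam == UNKNOWN) & (self.sire == UNKNOWN)

    def positions(self, ids) -> np.ndarray:
        """Map identifiers to row positions, raising on unknown ids."""
        try:
            return np.array([self._index[i] for i in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"individual {exc.args[0]!r} not in pedigree") from exc

    def to_frame(self) -> pd.DataFrame:
        dam_id = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], "")
        sire_id = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], "")
        cohort = pd.array(
            [int(c) if np.isfinite(c) else pd.NA for c in self.cohort],
            dtype="Int64",
        )
        return pd.DataFrame(
            {"id": self.ids, "dam": dam_id, "sire": sire_id,
             "cohort": cohort, "sex": self.sex}
        )


def _clean(value) -> str:
    s = "" if value is None else str(value).strip()
    return "" if s in _NA_STRINGS or s.lower() == "nan" else s


def _toposort(ids, dam_of, sire_of):
    """Stable Kahn topological sort; ties broken by input position."""
    import heapq

    pos = {i: k for k, i in enumerate(ids)}
    children: dict[str, list[str]] = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for i in ids:
        for p in (dam_of[i], sire_of[i]):
            if p:
                children[p].append(i)
                indeg[i] += 1
    heap = [pos[i] for i in ids if indeg[i] == 0]
    heapq.heapify(heap)
    order: list[str] = []
    while heap:
        i = ids[heapq.heappop(heap)]
        order.append(i)
        for ch in children[i]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(heap, pos[ch])
    if len(order) != len(ids):
        stuck = sorted(i for i in ids if indeg[i] > 0)[:5]
        raise PedigreeError(f"cycle detected in pedigree involving {stuck}")
    return order


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Build a validated, topologically sorted :class:`Pedigree`.

    Individuals that appear only as parents are promoted to founder
    records (unknown cohort; sex inferred from the parental role).
    """
    required = {"id", "dam", "sire"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree table missing columns {sorted(missing)}")

    ids: list[str] = []
    dam_of: dict[str, str] = {}
    sire_of: dict[str, str] = {}
    cohort_of: dict[str, float] = {}
    sex_of: dict[str, str] = {}
    seen = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        i = _clean(row.id)
        if not i:
            raise PedigreeError(f"row {row_no}: empty id")
        if i in seen:
            raise PedigreeError(f"row {row_no}: duplicate id {i!r}")
        seen.add(i)
        d, s = _clean(row.dam), _clean(row.sire)
        if i in (d, s):
            raise PedigreeError(f"row {row_no}: {i!r} listed as its own parent")
        coh = _clean(getattr(row, "cohort", ""))
        if coh:
            try:
                cohort_of[i] = float(int(float(coh)))
            except ValueError:
                raise PedigreeError(
                    f"row {row_no}: unparseable cohort {coh!r}"
                ) from None
        else:
            cohort_of[i] = np.nan
        sx = _clean(getattr(row, "sex", "")).upper()[:1]
        sex_of[i] = sx if sx in ("F", "M") else "U"
        ids.append(i)
        dam_of[i], sire_of[i] = d, s

    # promote parent-only individuals to founders
    for i in list(ids):
        for p, role_sex in ((dam_of[i], "F"), (sire_of[i], "M")):
            if p and p not in seen:
                seen.add(p)
                ids.append(p)
                dam_of[p] = sire_of[p] = ""
                cohort_of[p] = np.nan
                sex_of[p] = role_sex

    order = _toposort(ids, dam_of, sire_of)
    pos = {i: k for k, i in enumerate(order)}
    n = len(order)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    cohort = np.full(n, np.nan)
    sex = np.empty(n, dtype=object)
    for i in order:
        k = pos[i]
        if dam_of[i]:
            dam[k] = pos[dam_of[i]]
        if sire_of[i]:
            sire[k] = pos[sire_of[i]]
        cohort[k] = cohort_of[i]
        sex[k] = sex_of[i]
    return Pedigree(np.array(order, dtype=object), dam, sire, cohort, sex)


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (columns ``id,dam,sire,cohort,sex``).

    Unknown parents may be encoded as empty fields or ``NA``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return pedigree_from_frame(df)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# relatedness


def relationship_matrix(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Dense numerator relationship matrix by the tabular method.

    Returns ``(A, F)`` where ``A[i, j]`` is twice the kinship between
    individuals ``i`` and ``j`` and ``F`` the inbreeding coefficients
    (``diag(A) = 1 + F``).  Quadratic in pedigree size; intended for
    pedigrees up to a few thousand individuals.
    """
    n = ped.n
    if n > 20000:
        raise MemoryError("dense A beyond 20k individuals; use a_inverse")
    A = np.zeros((n, n))
    F = np.zeros(n)
    for i in range(n):
        d, s = ped.dam[i], ped.sire[i]
        row = np.zeros(i)
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        A[i, :i] = row
        A[:i, i] = row
        if d != UNKNOWN and s != UNKNOWN:
            F[i] = 0.5 * A[d, s]
        A[i, i] = 1.0 + F[i]
    return A, F


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients ``F_i = kinship(dam_i, sire_i)``.

    Computed by recursive kinship with memoisation, so large pedigrees
    with shallow depth (e.g. founder-heavy simulations) stay cheap.
    """
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * ped.n + 1000))
    dam, sire = ped.dam, ped.sire
    memo: dict[tuple[int, int], float] = {}

    def kin(a: int, b: int) -> float:
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if a > b:
            a, b = b, a
        key = (a, b)
        v = memo.get(key)
        if v is not None:
            return v
        if a == b:
            v = 0.5 * (1.0 + kin(dam[a], sire[a]))
        else:
            # b is the younger individual (topological order)
            v = 0.5 * (kin(a, dam[b]) + kin(a, sire[b]))
        memo[key] = v
        return v

    return np.array([kin(dam[i], sire[i]) for i in range(ped.n)])


def mendelian_variance(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Mendelian-sampling variance ``d_i`` (in units of V_A).

    ``0.5 - 0.25 (F_dam + F_sire)`` with two known parents,
    ``0.75 - 0.25 F_known`` with one, ``1`` with none.
    """
    if F is None:
        F = inbreeding(ped)
    d = np.ones(ped.n)
    has_d = ped.dam != UNKNOWN
    has_s = ped.sire != UNKNOWN
    Fd = np.where(has_d, F[np.maximum(ped.dam, 0)], 0.0)
    Fs = np.where(has_s, F[np.maximum(ped.sire, 0)], 0.0)
    both = has_d & has_s
    one = has_d ^ has_s
    d[both] = 0.5 - 0.25 * (Fd[both] + Fs[both])
    d[one] = 0.75 - 0.25 * (Fd + Fs)[one]
    return d


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csc_matrix:
    """Sparse inverse of ``A`` by Henderson's rules with inbreeding.

    Each individual contributes outer-product terms weighted by the
    inverse of its Mendelian-sampling variance ``d_i``.
    """
    if F is None:
        F = inbreeding(ped)
    d = mendelian_variance(ped, F)
    assert np.all(d > 0), "non-positive Mendelian variance"
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        w = 1.0 / d[i]
        parents = [p for p in (ped.dam[i], ped.sire[i]) if p != UNKNOWN]
        rows.append(i)
        cols.append(i)
        vals.append(w)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * w, -0.5 * w]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * w)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return Ainv.tocsc()


# ---------------------------------------------------------------------------
# gene dropping


def gene_drop(
    ped: Pedigree,
    v_a: float,
    rng: np.random.Generator | int | None = None,
    n_reps: int = 1,
) -> np.ndarray:
    """Simulate breeding values down the pedigree.

    Founders are drawn ``N(0, v_a)``; every other individual receives the
    mean of its known parents' values plus a Mendelian deviation
    ``N(0, d_i v_a)``.  Replicates share the pedigree but are independent
    draws, so their empirical covariance converges to ``v_a * A``.

    Returns an array of shape ``(n_reps, n)``.
    """
    if v_a < 0:
        raise ValueError("v_a must be non-negative")
    rng = np.random.default_rng(rng)
    n = ped.n
    out = np.zeros((n_reps, n))
    if v_a == 0:
        return out
    d = mendelian_variance(ped)
    noise = rng.standard_normal((n_reps, n)) * np.sqrt(v_a * d)
    for i in range(n):
        val = noise[:, i]
        if ped.dam[i] != UNKNOWN:
            val = val + 0.5 * out[:, ped.dam[i]]
        if ped.sire[i] != UNKNOWN:
            val = val + 0.5 * out[:, ped.sire[i]]
        out[:, i] = val
    return out


def gene_drop_bivariate(
    ped: Pedigree,
    G: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Drop correlated breeding values for two traits (2x2 ``G``) down
    the pedigree; returns shape ``(n, 2)``.  Used by the population
    simulator to build in a genetic trait-fitness covariance."""
    G = np.asarray(G, dtype=float)
    if G.shape != (2, 2) or not np.allclose(G, G.T):
        raise ValueError("G must be a symmetric 2x2 matrix")
    w, V = np.linalg.eigh(G)
    if np.any(w < -1e-12):
        raise ValueError("G must be positive semi-definite")
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    rng = np.random.default_rng(rng)
    d = mendelian_variance(ped)
    n = ped.n
    out = np.zeros((n, 2))
    noise = rng.standard_normal((n, 2)) @ L.T
    for i in range(n):
        val = noise[i] * np.sqrt(d[i])
        if ped.dam[i] != UNKNOWN:
            val = val + 0.5 * out[ped.dam[i]]
        if ped.sire[i] != UNKNOWN:
            val = val + 0.5 * out[ped.sire[i]]
        out[i] = val
    return out
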
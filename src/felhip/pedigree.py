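"""Pedigree handling and additive-relationship machinery.

A pedigree is the sole source of genetic-relationship information in these
analyses: the additive relationship matrix ``A`` built from it defines the
covariance of breeding values in the animal model, and the recursive
generation-counting of screened ancestors ("mean ancestor score") is the
covariate used to measure response to selection in a health programme.

Conventions
-----------
* Unknown parents are encoded as ``""`` or ``"0"`` in files and as ``None``
  in memory; they are treated as unrelated, non-inbred founders.
* Pedigrees are stored topologically sorted (parents before offspring);
  reading reorders rows as needed and keeps the original order as metadata.
* An individual may act as sire or dam, never both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = None

_SEXES = ("female", "male", "unknown")


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree entry: an individual and its (possibly unknown) parents."""

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("pedigree record with empty id")
        if self.id in (self.sire_id, self.dam_id):
            raise ValueError(f"individual {self.id!r} listed as its own parent")
        if self.sex not in _SEXES:
            raise ValueError(f"invalid sex {self.sex!r} for {self.id!r}")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


class Pedigree:
    """Topologically ordered pedigree with id-based and positional access.

    Parameters
    ----------
    records
        Pedigree records in any order; they are topologically sorted so that
        every known parent precedes its offspring.  A cycle or an unresolved
        parent id raises :class:`PedigreeError` (unless ``add_missing_founders``
        inserts unknown parents as founders).
    add_missing_founders
        If True, parent ids that never appear as individuals are inserted as
        founder records (sex inferred from the role they play).
    """

    def __init__(self, records: Iterable[PedigreeRecord], *,
                 add_missing_founders: bool = False) -> None:
        records = list(records)
        ids = [r.id for r in records]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate individual id {i!r}")
            seen.add(i)

        if add_missing_founders:
            known = set(ids)
            extra: list[PedigreeRecord] = []
            for r in records:
                for pid, sex in ((r.sire_id, "male"), (r.dam_id, "female")):
                    if pid is not None and pid not in known:
                        extra.append(PedigreeRecord(pid, None, None, sex))
                        known.add(pid)
            records = extra + records
            ids = [r.id for r in records]

        by_id = {r.id: r for r in records}
        for r in records:
            for pid in (r.sire_id, r.dam_id):
                if pid is not None and pid not in by_id:
                    raise PedigreeError(
                        f"parent id {pid!r} of {r.id!r} not in pedigree "
                        "(pass add_missing_founders=True to insert founders)")

        sires = {r.sire_id for r in records if r.sire_id is not None}
        dams = {r.dam_id for r in records if r.dam_id is not None}
        both = sires & dams
        if both:
            raise PedigreeError(
                f"individual(s) appear as both sire and dam: {sorted(both)[:5]}")

        self.input_order: tuple[str, ...] = tuple(ids)
        self.records: tuple[PedigreeRecord, ...] = tuple(
            _topological_sort(records, by_id))
        self.index: dict[str, int] = {r.id: k for k, r in enumerate(self.records)}

        n = len(self.records)
        self.sire = np.full(n, -1, dtype=np.int64)
        self.dam = np.full(n, -1, dtype=np.int64)
        for k, r in enumerate(self.records):
            if r.sire_id is not None:
                self.sire[k] = self.index[r.sire_id]
            if r.dam_id is not None:
                self.dam[k] = self.index[r.dam_id]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, id_: str) -> PedigreeRecord:
        return self.records[self.index[id_]]

    def __contains__(self, id_: str) -> bool:
        return id_ in self.index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def generation_depth(self) -> np.ndarray:
        """Longest ancestral path per individual (founders have depth 0)."""
        n = len(self)
        depth = np.zeros(n, dtype=np.int64)
        for k in range(n):
            s, d = self.sire[k], self.dam[k]
            ds = depth[s] + 1 if s >= 0 else 0
            dd = depth[d] + 1 if d >= 0 else 0
            depth[k] = max(ds, dd)
        return depth

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sire": [r.sire_id or "" for r in self.records],
                "dam": [r.dam_id or "" for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )


def _topological_sort(records: Sequence[PedigreeRecord],
                      by_id: Mapping[str, PedigreeRecord]
                      ) -> list[PedigreeRecord]:
    order: list[PedigreeRecord] = []
    state: dict[str, int] = {}  # 0 unseen / 1 on stack / 2 done

    for root in records:
        if state.get(root.id, 0) == 2:
            continue
        stack: list[tuple[str, int]] = [(root.id, 0)]
        while stack:
            cur, phase = stack.pop()
            if phase == 0:
                st = state.get(cur, 0)
                if st == 2:
                    continue
                if st == 1:
                    cycle = _find_cycle(cur, by_id)
                    raise PedigreeError(f"pedigree cycle: {' -> '.join(cycle)}")
                state[cur] = 1
                stack.append((cur, 1))
                rec = by_id[cur]
                for pid in (rec.sire_id, rec.dam_id):
                    if pid is not None and state.get(pid, 0) != 2:
                        if state.get(pid, 0) == 1:
                            cycle = _find_cycle(pid, by_id)
                            raise PedigreeError(
                                f"pedigree cycle: {' -> '.join(cycle)}")
                        stack.append((pid, 0))
            else:
                state[cur] = 2
                order.append(by_id[cur])
    return order


def _find_cycle(start: str, by_id: Mapping[str, PedigreeRecord]) -> list[str]:
    path = [start]
    cur = start
    visited = {start}
    while True:
        rec = by_id[cur]
        for pid in (rec.sire_id, rec.dam_id):
            if pid is not None:
                path.append(pid)
                if pid in visited:
                    return path
                visited.add(pid)
                cur = pid
                break
        else:  # pragma: no cover - only reached on malformed call
            return path


# ---------------------------------------------------------------------------
# I/O


def _norm_parent(tok: str) -> str | None:
    tok = tok.strip()
    return None if tok in ("", "0", "NA", "na", ".") else tok


_SEX_ALIASES = {
    "f": "female", "female": "female", "2": "female",
    "m": "male", "male": "male", "1": "male",
    "": "unknown", "u": "unknown", "unknown": "unknown", "0": "unknown",
}


def read_pedigree(path, *, add_missing_founders: bool = False) -> Pedigree:
    """Read a pedigree from a CSV (or whitespace-delimited) file.

    The file must carry a header with columns ``id, sire, dam, sex``
    (case-insensitive; ``sire_id``/``dam_id`` also accepted).  ``""`` and
    ``"0"`` both mean an unknown parent.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] == 1:  # whitespace-delimited fallback
        df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=r"\s+")
    cols = {c.lower().replace("_id", ""): c for c in df.columns}
    missing = [c for c in ("id", "sire", "dam", "sex") if c not in cols]
    if missing:
        raise PedigreeError(f"pedigree file missing column(s): {missing}")
    recs = [
        PedigreeRecord(
            id=row[cols["id"]].strip(),
            sire_id=_norm_parent(row[cols["sire"]]),
            dam_id=_norm_parent(row[cols["dam"]]),
            sex=_SEX_ALIASES.get(row[cols["sex"]].strip().lower(), "unknown"),
        )
        for row in df.to_dict("records")
    ]
    return Pedigree(recs, add_missing_founders=add_missing_founders)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inbreeding and relationship matrices


class InbreedingTracker:
    """Incremental Meuwissen–Luo inbreeding over a growing pedigree.

    Individuals are appended in topological order (parents first).  Uses the
    generalized Cholesky decomposition A = L D Lᵀ: the diagonal
    ``a_ii = Σ_j L_ij² D_j`` is accumulated by traversing i's ancestors
    youngest-first, where ``L_ij`` is the expected genome fraction i derives
    from ancestor j and ``D_j`` the Mendelian-sampling variance of j (a
    function of the parents' F only, hence already available).  Founders
    have F = 0; no dense matrix is formed.
    """

    def __init__(self) -> None:
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.F: list[float] = []
        self.D: list[float] = []

    def add(self, sire: int, dam: int) -> float:
        """Append an individual (parent indices, -1 if unknown); returns F."""
        import heapq

        i = len(self.F)
        if sire >= 0 and dam >= 0:
            d_i = 0.5 - 0.25 * (self.F[sire] + self.F[dam])
        elif sire >= 0 or dam >= 0:
            d_i = 0.75 - 0.25 * self.F[max(sire, dam)]
        else:
            d_i = 1.0
        self.sire.append(sire)
        self.dam.append(dam)
        self.D.append(d_i)
        if sire < 0 or dam < 0:
            self.F.append(0.0)
            return 0.0
        coef: dict[int, float] = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            cj = coef.pop(j)
            aii += cj * cj * (self.D[j] if j < i else d_i)
            for p in ((self.sire[j], self.dam[j]) if j < i else (sire, dam)):
                if p >= 0:
                    if p in coef:
                        coef[p] += 0.5 * cj
                    else:
                        coef[p] = 0.5 * cj
                        heapq.heappush(heap, -p)
        f_i = aii - 1.0
        self.F.append(f_i)
        # D_i depends only on the *parents'* F, so no correction needed
        return f_i


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen–Luo algorithm."""
    tracker = InbreedingTracker()
    for s, d in zip(ped.sire, ped.dam):
        tracker.add(int(s), int(d))
    return np.asarray(tracker.F)


def relationship_matrix(ped: Pedigree) -> "RelationshipMatrix":
    """Dense additive relationship matrix A by the tabular method.

    ``a_ij = ½(a_{i,s(j)} + a_{i,d(j)})`` for i earlier than j, and
    ``a_jj = 1 + ½ a_{s(j),d(j)}``; unknown-parent terms contribute 0.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        if j > 0:
            row = np.zeros(j)
            if s >= 0:
                row += 0.5 * A[:j, s]
            if d >= 0:
                row += 0.5 * A[:j, d]
            A[:j, j] = row
            A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    F = np.diag(A) - 1.0
    return RelationshipMatrix(values=A, inbreeding=F, ids=ped.ids)


@dataclass
class RelationshipMatrix:
    """Additive relationships a_ij with per-individual inbreeding F."""

    values: np.ndarray
    inbreeding: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("relationship matrix must be symmetric")


def mendelian_sampling_variance(ped: Pedigree, F: np.ndarray | None = None
                                ) -> np.ndarray:
    """Per-individual Mendelian-sampling variance d_i (in units of V_A).

    d_i = ½ − ¼(F_s + F_d) with both parents known, ¾ − ¼F_p with one,
    and 1 for founders (Quaas adjustment for inbred parents).
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    n = len(ped)
    d = np.ones(n)
    for i in range(n):
        s, de = ped.sire[i], ped.dam[i]
        if s >= 0 and de >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[de])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * F[s]
        elif de >= 0:
            d[i] = 0.75 - 0.25 * F[de]
    return d


def relationship_inverse(ped: Pedigree, F: np.ndarray | None = None
                         ) -> sparse.csc_matrix:
    """Sparse A⁻¹ by Henderson's rules with the inbreeding adjustment.

    Each individual contributes w wᵀ / d_i over (individual, sire, dam) with
    weights (1, −½, −½); nonzeros therefore only link an individual with its
    parents and the two parents with each other.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    d = mendelian_sampling_variance(ped, F)
    n = len(ped)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for i in range(n):
        members = [i]
        weights = [1.0]
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                members.append(p)
                weights.append(-0.5)
        m = np.asarray(members)
        w = np.asarray(weights) / np.sqrt(d[i])
        rows.append(np.repeat(m, len(m)))
        cols.append(np.tile(m, len(m)))
        vals.append(np.outer(w, w).ravel())
    Ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    Ainv.sum_duplicates()
    return Ainv


def export_relationship_inverse(ainv: sparse.spmatrix, path) -> None:
    """Write A⁻¹ as a coordinate triplet file (i, j, value), 0-based."""
    coo = ainv.tocoo()
    pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data}).to_csv(
        path, index=False)


def sample_breeding_values(ped: Pedigree, G: np.ndarray | float,
                           rng: np.random.Generator,
                           F: np.ndarray | None = None) -> np.ndarray:
    """Draw breeding values down the pedigree: a ~ N(0, G ⊗ A).

    Founders are MVN(0, G); offspring are the parent average plus a
    Mendelian-sampling deviation MVN(0, k_i G) with
    k_i = d_i (the Mendelian-sampling variance share).  Vectorised by
    generation depth.  Returns an (n, t) array (t = 1 for scalar G).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    t = G.shape[0]
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:  # PSD but singular: eigen factor
        w, v = np.linalg.eigh(G)
        L = v * np.sqrt(np.clip(w, 0.0, None))
    n = len(ped)
    if F is None:
        F = inbreeding_coefficients(ped)
    d = mendelian_sampling_variance(ped, F)
    a = np.zeros((n, t))
    depth = ped.generation_depth()
    for g in np.unique(depth):
        idx = np.where(depth == g)[0]
        z = rng.standard_normal((len(idx), t)) @ L.T
        mean = np.zeros((len(idx), t))
        s, de = ped.sire[idx], ped.dam[idx]
        mean[s >= 0] += 0.5 * a[s[s >= 0]]
        mean[de >= 0] += 0.5 * a[de[de >= 0]]
        a[idx] = mean + np.sqrt(d[idx])[:, None] * z
    return a


# ---------------------------------------------------------------------------
# Mean ancestor score


@dataclass(frozen=True)
class AncestorScore:
    """Generations of previously screened ancestors on each parental side."""

    maternal: float
    paternal: float

    @property
    def mean_score(self) -> float:
        return 0.5 * (self.maternal + self.paternal)


def mean_ancestor_score(ped: Pedigree, screened: Mapping[str, float],
                        subject: str, *,
                        subject_date: float | None = None,
                        mode: Literal["discounted", "strict"] = "discounted",
                        ) -> AncestorScore:
    """Generations of previously-screened ancestors, averaged over sides.

    ``screened`` maps individual id -> assessment date (any comparable
    numeric, e.g. days or decimal years).  An ancestor counts only if its
    assessment is strictly before the subject's (ties are not "previous").

    In the default ``discounted`` mode the per-ancestor recursion is
    ``g(x) = 1 + ½ (g(sire) + g(dam))`` when x is screened-before, else 0,
    which degrades smoothly through unscreened gaps; ``strict`` counts only
    unbroken fully screened generations, ``g(x) = 1 + min(g(sire), g(dam))``.
    """
    if subject not in ped:
        raise KeyError(f"unknown subject id {subject!r}")
    if subject_date is None:
        if subject not in screened:
            raise ValueError(
                f"subject {subject!r} has no assessment date; pass subject_date")
        subject_date = screened[subject]

    memo: dict[int, float] = {}

    def g(k: int) -> float:
        if k < 0:
            return 0.0
        if k in memo:
            return memo[k]
        rid = ped.records[k].id
        date = screened.get(rid)
        if date is None or not (date < subject_date):
            val = 0.0
        else:
            gs, gd = g(ped.sire[k]), g(ped.dam[k])
            if mode == "strict":
                val = 1.0 + min(gs, gd)
            else:
                val = 1.0 + 0.5 * (gs + gd)
        memo[k] = val
        return val

    k = ped.index[subject]
    return AncestorScore(maternal=g(ped.dam[k]), paternal=g(ped.sire[k]))


def mean_ancestor_scores(ped: Pedigree, screened: Mapping[str, float],
                         subjects: Sequence[str] | None = None,
                         mode: Literal["discounted", "strict"] = "discounted",
                         ) -> pd.Series:
    """Vector of mean ancestor scores for many subjects (shared recursion)."""
    if subjects is None:
        subjects = [i for i in ped.ids if i in screened]
    out = {}
    for s in subjects:
        sc = mean_ancestor_score(ped, screened, s, mode=mode)
        out[s] = sc.mean_score
    return pd.Series(out, name="mean_ancestor_score")
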
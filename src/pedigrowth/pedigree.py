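"""Pedigree handling: validation, kinship and maternal-household matrices.

The pedigree is the backbone of every genetic analysis in this package: the
kinship matrix Phi scales the additive polygenic covariance (2*Phi*sigma2_g)
and the maternal-household matrix defines the shared-environment component
(c2).  Kinship is computed by the standard recursive (tabular) method, with
founders assumed unrelated and non-inbred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "CycleError",
    "SexInconsistencyError",
    "DuplicateIdError",
    "UnknownIdError",
    "Pedigree",
    "kinship_matrix",
    "household_matrix",
]

DAYS_PER_YEAR = 365.25

#: sentinels accepted for a missing parent in input tables
MISSING_PARENT = {"", "0", "NA", "nan", "None", None}


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class CycleError(PedigreeError):
    """The parent-offspring graph contains a cycle (incl. self-parentage)."""


class SexInconsistencyError(PedigreeError):
    """An individual is used as sire but recorded female, or vice versa."""


class DuplicateIdError(PedigreeError):
    """The same id occurs on more than one row."""


class UnknownIdError(PedigreeError, KeyError):
    """An id was requested that is not in the pedigree."""


def _norm_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in MISSING_PARENT else s


def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    s = str(value).strip()
    if not s or s in MISSING_PARENT:
        return None
    return date.fromisoformat(s)


@dataclass(frozen=True)
class Individual:
    id: str
    sire_id: str | None
    dam_id: str | None
    sex: str  # "M" or "F"
    birth_date: date | None = None
    birth_location: str | None = None


@dataclass
class Pedigree:
    """Validated pedigree in topological order (parents before offspring).

    Construct with :meth:`from_records` / :meth:`from_csv`; the constructor
    itself does not validate.
    """

    individuals: list[Individual]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {ind.id: i for i, ind in enumerate(self.individuals)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build and validate a pedigree from tabular rows.

        ``records`` may be a DataFrame or an iterable of mappings with keys
        id, sire, dam, sex and optionally birth_date, birth_location.
        Missing parents may be encoded as empty, "0" or NA.
        """
        if isinstance(records, pd.DataFrame):
            records = records.to_dict("records")
        inds: dict[str, Individual] = {}
        for row in records:
            iid = str(row["id"]).strip()
            sire = _norm_parent(row.get("sire"))
            dam = _norm_parent(row.get("dam"))
            sex = str(row.get("sex", "")).strip().upper()[:1]
            if sex not in ("M", "F"):
                raise PedigreeError(f"individual {iid!r}: sex must be M or F, got {row.get('sex')!r}")
            if iid in inds:
                raise DuplicateIdError(f"duplicate id {iid!r}")
            if iid == sire or iid == dam:
                raise CycleError(f"individual {iid!r} is its own parent")
            inds[iid] = Individual(
                id=iid,
                sire_id=sire,
                dam_id=dam,
                sex=sex,
                birth_date=_parse_date(row.get("birth_date")),
                birth_location=(str(row["birth_location"]) if row.get("birth_location") not in (None, "") else None),
            )
        # parent sex consistency (only checkable for parents present as rows)
        for ind in inds.values():
            if ind.sire_id is not None and ind.sire_id in inds and inds[ind.sire_id].sex != "M":
                raise SexInconsistencyError(
                    f"sire {ind.sire_id!r} of {ind.id!r} is recorded with sex "
                    f"{inds[ind.sire_id].sex!r}"
                )
            if ind.dam_id is not None and ind.dam_id in inds and inds[ind.dam_id].sex != "F":
                raise SexInconsistencyError(
                    f"dam {ind.dam_id!r} of {ind.id!r} is recorded with sex "
                    f"{inds[ind.dam_id].sex!r}"
                )
        # topological order via the parent->offspring DAG; input order not trusted
        g = nx.DiGraph()
        g.add_nodes_from(inds)
        for ind in inds.values():
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None and pid in inds:
                    g.add_edge(pid, ind.id)
        try:
            order = list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            raise CycleError("pedigree parent-offspring graph contains a cycle") from exc
        return cls([inds[i] for i in order])

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_records(df)

    # -- accessors ---------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self.individuals[self._index[iid]]
        except KeyError:
            raise UnknownIdError(iid) from None

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        ind = self[iid]
        return ind.sire_id, ind.dam_id

    def founders(self) -> list[str]:
        return [i.id for i in self.individuals if i.sire_id is None and i.dam_id is None]

    def age_at(self, iid: str, on: date) -> float:
        """Age in decimal years at a calendar date ((date - birth)/365.25)."""
        bd = self[iid].birth_date
        if bd is None:
            raise PedigreeError(f"individual {iid!r} has no birth date")
        return (on - bd).days / DAYS_PER_YEAR

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "sire": [i.sire_id or "0" for i in self.individuals],
                "dam": [i.dam_id or "0" for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "birth_date": [i.birth_date.isoformat() if i.birth_date else "" for i in self.individuals],
                "birth_location": [i.birth_location or "" for i in self.individuals],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_fam(self, path, family_id: str = "1") -> None:
        """Export PLINK-style .fam columns (single collapsed family)."""
        df = self.to_dataframe()
        fam = pd.DataFrame(
            {
                "fid": family_id,
                "iid": df["id"],
                "sire": df["sire"],
                "dam": df["dam"],
                "sex": df["sex"].map({"M": 1, "F": 2}),
                "pheno": -9,
            }
        )
        fam.to_csv(path, sep="\t", header=False, index=False)


def kinship_matrix(ped: Pedigree, ids: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Kinship coefficients Phi by the recursive tabular method.

    Phi_ii = 0.5 * (1 + Phi_sire,dam); Phi_ij = 0.5 * (Phi_j,sire(i) +
    Phi_j,dam(i)) for j earlier in the (topological) order.  Founders are
    unrelated and non-inbred; a missing parent contributes kinship 0.

    Returns ``(ids, phi)`` where ``phi`` follows the pedigree's topological
    order, or the requested ``ids`` subset/order if given.
    """
    n = len(ped)
    order = ped.ids
    pos = {iid: k for k, iid in enumerate(order)}
    phi = np.zeros((n, n))
    sire_pos = np.full(n, -1, dtype=int)
    dam_pos = np.full(n, -1, dtype=int)
    for k, ind in enumerate(ped.individuals):
        if ind.sire_id is not None and ind.sire_id in pos:
            sire_pos[k] = pos[ind.sire_id]
        if ind.dam_id is not None and ind.dam_id in pos:
            dam_pos[k] = pos[ind.dam_id]
    for i in range(n):
        s, d = sire_pos[i], dam_pos[i]
        # cross terms with all earlier individuals (vectorised over j < i)
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += phi[s, :i]
            if d >= 0:
                row += phi[d, :i]
            phi[i, :i] = phi[:i, i] = 0.5 * row
        phi[i, i] = 0.5 * (1.0 + (phi[s, d] if s >= 0 and d >= 0 else 0.0))
    if ids is not None:
        idx = [pos[i] if i in pos else _raise_unknown(i) for i in ids]
        return list(ids), phi[np.ix_(idx, idx)]
    return order, phi


def _raise_unknown(iid):
    raise UnknownIdError(iid)


def household_matrix(ped: Pedigree, ids: list[str]) -> tuple[list[str], np.ndarray]:
    """0/1 maternal-household matrix: h_ij = 1 iff dam(i) == dam(j), both known.

    Individuals with unknown dam form singleton households (diagonal 1).
    """
    dams = []
    for iid in ids:
        dams.append(ped[iid].dam_id)
    n = len(ids)
    h = np.eye(n)
    arr = np.array([d if d is not None else f"__solo_{k}" for k, d in enumerate(dams)], dtype=object)
    same = arr[:, None] == arr[None, :]
    h[same] = 1.0
    return list(ids), h
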
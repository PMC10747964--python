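"""Pedigree container, recursive kinship coefficients and ancestor queries.

Kinship is computed by the standard tabular (recursive) method:

    phi(i,i) = 1/2 * (1 + phi(sire_i, dam_i))
    phi(i,j) = 1/2 * (phi(sire_i, j) + phi(dam_i, j))   for i after j

with founders phi(i,i) = 1/2 and phi between founders 0.  Twice the kinship
matrix is the numerator relationship matrix, so the result is symmetric
positive semidefinite with diagonal in [1/2, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InputError


@dataclass
class Pedigree:
    """Directed acyclic parent structure, parents before offspring.

    ``sire``/``dam`` hold parent ids or ``None`` for a founder (an unknown
    single parent is treated as founder-by-proxy: it contributes no
    kinship).
    """

    ids: list[str]
    sire: list[str | None]
    dam: list[str | None]
    sex: list[int] | None = None
    generation: list[int] | None = None
    case_flag: list[bool] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicated individual ids in pedigree")
        if not (len(self.ids) == len(self.sire) == len(self.dam)):
            raise InputError("pedigree columns have unequal lengths")
        index = {pid: i for i, pid in enumerate(self.ids)}
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            for parent in (s, d):
                if parent is None:
                    continue
                j = index.get(parent)
                if j is None:
                    raise InputError(f"unknown parent {parent!r} of {self.ids[i]!r}")
                if j >= i:
                    raise InputError(
                        f"parent {parent!r} does not precede offspring {self.ids[i]!r} "
                        "(cycle or misordered pedigree)"
                    )
        self._index = index

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> list[str]:
        return [
            pid
            for pid, s, d in zip(self.ids, self.sire, self.dam)
            if s is None and d is None
        ]

    def children_of(self) -> dict[str, list[str]]:
        kids: dict[str, list[str]] = {pid: [] for pid in self.ids}
        for pid, s, d in zip(self.ids, self.sire, self.dam):
            if s is not None:
                kids[s].append(pid)
            if d is not None:
                kids[d].append(pid)
        return kids


def kinship_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Kinship coefficients phi for every pair, by the tabular method."""
    n = len(pedigree)
    idx = pedigree._index
    phi = np.zeros((n, n))
    for i in range(n):
        s = pedigree.sire[i]
        d = pedigree.dam[i]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        if si is None and di is None:
            phi[i, i] = 0.5
        else:
            phi_sd = phi[si, di] if (si is not None and di is not None) else 0.0
            phi[i, i] = 0.5 * (1.0 + phi_sd)
        for j in range(i):
            v = 0.0
            if si is not None:
                v += 0.5 * phi[si, j]
            if di is not None:
                v += 0.5 * phi[di, j]
            phi[i, j] = phi[j, i] = v
    return pd.DataFrame(phi, index=pedigree.ids, columns=pedigree.ids)


def descendants(pedigree: Pedigree, ancestor: str) -> set[str]:
    """All individuals having ``ancestor`` in their ancestor closure."""
    if ancestor not in pedigree._index:
        raise InputError(f"unknown individual {ancestor!r}")
    kids = pedigree.children_of()
    out: set[str] = set()
    stack = list(kids[ancestor])
    while stack:
        x = stack.pop()
        if x in out:
            continue
        out.add(x)
        stack.extend(kids[x])
    return out


def common_ancestor_cases(pedigree: Pedigree, ancestor: str) -> int:
    """Number of case-flagged descendants of ``ancestor``."""
    if pedigree.case_flag is None:
        raise InputError("pedigree carries no case flags")
    flag = dict(zip(pedigree.ids, pedigree.case_flag))
    return sum(1 for x in descendants(pedigree, ancestor) if flag[x])


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV: id, sire, dam[, case_flag]; 0 or empty = unknown."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sire", "dam"}
    if not required <= set(df.columns):
        raise InputError(f"pedigree file must have columns {sorted(required)}")

    def norm(v):
        return None if (pd.isna(v) or v in ("0", "", "NA")) else str(v)

    case = None
    if "case_flag" in df.columns:
        case = [str(v) in ("1", "True", "true", "case") for v in df["case_flag"]]
    return Pedigree(
        ids=[str(v) for v in df["id"]],
        sire=[norm(v) for v in df["sire"]],
        dam=[norm(v) for v in df["dam"]],
        case_flag=case,
    )


def write_pedigree(path, pedigree: Pedigree) -> None:
    df = pd.DataFrame(
        {
            "id": pedigree.ids,
            "sire": [s if s is not None else "0" for s in pedigree.sire],
            "dam": [d if d is not None else "0" for d in pedigree.dam],
        }
    )
    if pedigree.case_flag is not None:
        df["case_flag"] = [int(f) for f in pedigree.case_flag]
    df.to_csv(path, sep="\t", index=False)


def write_matrix(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")
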
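"""Pedigree parsing, validation, inbreeding and kinship.

A pedigree is a directed acyclic parent structure: every individual has a
sire and a dam, each either another individual in the pedigree or missing.
Founders (both parents missing) are assumed non-inbred and mutually
unrelated.  All identity-by-descent machinery in this package starts from
this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PedigreeError",
    "validate_pedigree",
    "kinship_matrix",
    "inbreeding",
]

#: tokens accepted as "parent unknown" in input tables
MISSING_TOKENS = {"", "0", "NA", "na", "-", "None", "nan"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


def _is_missing(tok) -> bool:
    if tok is None:
        return True
    if isinstance(tok, float) and np.isnan(tok):
        return True
    return str(tok).strip() in MISSING_TOKENS


@dataclass
class Pedigree:
    """Validated pedigree in topological order (parents precede offspring).

    Attributes
    ----------
    ids : list of str
        Individual identifiers, topologically sorted.
    sire, dam : ndarray of int
        Index of each individual's parents into ``ids``; ``-1`` for missing
        (founders only — after validation every non-founder has both).
    sex : ndarray of str
        ``"M"``, ``"F"`` or ``"U"``.
    generation : ndarray of int
        Generation number; taken from the input when given, otherwise the
        pedigree depth (founders are 0).
    hidden : ndarray of bool
        True for placeholder founders synthesized for records that named
        only one parent.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    hidden: np.ndarray
    index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.index:
            self.index = {v: i for i, v in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self, i: int) -> bool:
        return self.sire[i] < 0 and self.dam[i] < 0

    @property
    def founders(self) -> np.ndarray:
        return np.where((self.sire < 0) & (self.dam < 0))[0]

    @property
    def depth(self) -> int:
        return int(self.generation.max()) if len(self.ids) else 0

    def to_frame(self, include_hidden: bool = False) -> pd.DataFrame:
        """Return the pedigree as a ``id,sire,dam,sex,generation`` table."""
        rows = []
        for i, ind in enumerate(self.ids):
            if self.hidden[i] and not include_hidden:
                continue
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 else "0"
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 else "0"
            if not include_hidden:
                if self.sire[i] >= 0 and self.hidden[self.sire[i]]:
                    s = "0"
                if self.dam[i] >= 0 and self.hidden[self.dam[i]]:
                    d = "0"
            rows.append((ind, s, d, self.sex[i], int(self.generation[i])))
        return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"])


def _normalize_records(raw) -> list[tuple]:
    """Coerce input (DataFrame or iterable of tuples/dicts) to a list of
    (id, sire, dam, sex, generation) tuples with missing -> None."""
    if isinstance(raw, pd.DataFrame):
        cols = {c.lower(): c for c in raw.columns}
        for req in ("id", "sire", "dam"):
            if req not in cols:
                raise PedigreeError(f"pedigree table is missing column {req!r}")
        recs = []
        for _, r in raw.iterrows():
            recs.append(
                (
                    r[cols["id"]],
                    r[cols["sire"]],
                    r[cols["dam"]],
                    r[cols["sex"]] if "sex" in cols else None,
                    r[cols["generation"]] if "generation" in cols else None,
                )
            )
        return recs
    recs = []
    for rec in raw:
        if isinstance(rec, Mapping):
            recs.append(
                (rec["id"], rec.get("sire"), rec.get("dam"), rec.get("sex"), rec.get("generation"))
            )
        else:
            rec = tuple(rec)
            recs.append(rec + (None,) * (5 - len(rec)))
    return recs


def validate_pedigree(raw_records) -> Pedigree:
    """Validate raw pedigree records and return a topologically ordered
    :class:`Pedigree`.

    Rules enforced: unique ids; every named parent present; no individual is
    its own ancestor; no individual used both as a sire and as a dam.  A
    record naming only one parent gets a synthesized (hidden) founder for
    the other, which keeps the standard kinship recursion exact.

    Parameters
    ----------
    raw_records : DataFrame or iterable
        Rows of ``(id, sire, dam[, sex[, generation]])``; the tokens
        ``"" , "0", "NA", "-"`` denote a missing parent.
    """
    recs = _normalize_records(raw_records)
    ids = [str(r[0]).strip() for r in recs]
    dupes = {x for x in ids if ids.count(x) > 1} if len(set(ids)) != len(ids) else set()
    if dupes:
        raise PedigreeError(f"duplicate individual id(s): {sorted(dupes)}")
    known = set(ids)

    sires, dams, sexes, gens = {}, {}, {}, {}
    as_sire, as_dam = set(), set()
    for r, ind in zip(recs, ids):
        s = None if _is_missing(r[1]) else str(r[1]).strip()
        d = None if _is_missing(r[2]) else str(r[2]).strip()
        for p, role in ((s, "sire"), (d, "dam")):
            if p is not None and p not in known:
                raise PedigreeError(f"{role} {p!r} of {ind!r} is not a pedigree record")
        if s is not None and s == ind:
            raise PedigreeError(f"{ind!r} is listed as its own sire (cycle)")
        if d is not None and d == ind:
            raise PedigreeError(f"{ind!r} is listed as its own dam (cycle)")
        if s is not None:
            as_sire.add(s)
        if d is not None:
            as_dam.add(d)
        sires[ind], dams[ind] = s, d
        sx = r[3]
        sx = "U" if sx is None or _is_missing(sx) else str(sx).strip().upper()[:1]
        sexes[ind] = sx if sx in ("M", "F") else "U"
        g = r[4]
        gens[ind] = None if g is None or _is_missing(g) else int(g)

    both = as_sire & as_dam
    if both:
        raise PedigreeError(f"individual(s) listed as both sire and dam: {sorted(both)}")

    # synthesize hidden founders for half-known parent pairs
    hidden_ids = []
    for ind in list(ids):
        s, d = sires[ind], dams[ind]
        if (s is None) != (d is None):
            h = f"{ind}!{'sire' if s is None else 'dam'}"
            hidden_ids.append(h)
            sires[h] = dams[h] = None
            sexes[h] = "M" if s is None else "F"
            gens[h] = None
            if s is None:
                sires[ind] = h
            else:
                dams[ind] = h
    all_ids = hidden_ids + ids

    # Kahn topological sort; detects cycles
    children = {x: [] for x in all_ids}
    npar = {}
    for x in all_ids:
        ps = [p for p in (sires[x], dams[x]) if p is not None]
        npar[x] = len(ps)
        for p in ps:
            children[p].append(x)
    order = [x for x in all_ids if npar[x] == 0]
    head = 0
    pending = dict(npar)
    while head < len(order):
        x = order[head]
        head += 1
        for c in children[x]:
            pending[c] -= 1
            if pending[c] == 0:
                order.append(c)
    if len(order) != len(all_ids):
        stuck = sorted(x for x in all_ids if pending[x] > 0)
        raise PedigreeError(f"cycle detected involving id(s): {stuck}")

    idx = {x: i for i, x in enumerate(order)}
    n = len(order)
    sire = np.array([idx[sires[x]] if sires[x] is not None else -1 for x in order])
    dam = np.array([idx[dams[x]] if dams[x] is not None else -1 for x in order])
    sex = np.array([sexes[x] for x in order])
    depth = np.zeros(n, dtype=int)
    for i in range(n):
        if sire[i] >= 0 or dam[i] >= 0:
            depth[i] = 1 + max(
                depth[sire[i]] if sire[i] >= 0 else 0, depth[dam[i]] if dam[i] >= 0 else 0
            )
    gen = np.array([gens[x] if gens[x] is not None else depth[i] for i, x in enumerate(order)])
    hidden = np.array([x in set(hidden_ids) for x in order])
    return Pedigree(list(order), sire, dam, sex, gen, hidden)


def kinship_matrix(ped: Pedigree, as_frame: bool = False):
    """Kinship matrix φ over all pedigree members.

    Uses the standard tabular recursion in topological order:
    ``φ(a,b) = (φ(sire_a,b) + φ(dam_a,b)) / 2`` for ``a`` younger than ``b``
    and ``φ(a,a) = (1 + φ(sire_a, dam_a)) / 2``; founders are mutually
    unrelated and non-inbred.

    Returns an ``(n, n)`` float array in pedigree order, or a labelled
    DataFrame when ``as_frame`` is true.
    """
    n = ped.n
    K = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            K[i, i] = 0.5
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * K[s, :i]
        if d >= 0:
            row += 0.5 * K[d, :i]
        K[i, :i] = row
        K[:i, i] = row
        K[i, i] = 0.5 * (1.0 + (K[s, d] if (s >= 0 and d >= 0) else 0.0))
    if as_frame:
        return pd.DataFrame(K, index=ped.ids, columns=ped.ids)
    return K


def inbreeding(ped: Pedigree) -> dict:
    """Per-individual inbreeding coefficient ``f`` (kinship of the parents).

    Returns a mapping id -> f with founders at 0.
    """
    K = kinship_matrix(ped)
    f = 2.0 * np.diag(K) - 1.0
    f[np.abs(f) < 1e-15] = 0.0
    return {ind: float(f[i]) for i, ind in enumerate(ped.ids)}
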
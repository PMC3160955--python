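"""Condensed identity coefficients and the genetic incidence matrices.

For a pair of individuals (i, j) at an autosomal locus, the four alleles
carried by the pair fall into one of Jacquard's nine condensed identity
states; their probabilities Δ1..Δ9 summarize everything the pedigree says
about the pair's identity by descent.  The additive, dominance and
inbreeding-related covariance structures of a polygenic model are simple
linear functions of these coefficients, so they are the raw material for
every mixed-model computation downstream.

The engine here derives Δ1..Δ9 from generalized kinship coefficients.  A
generalized kinship state is a collection of "groups" of gene draws, one
random gene per listed individual per occurrence; its value is the
probability that, within every group, all drawn genes are identical by
descent.  Each state is reduced by replacing, simultaneously, every member
of the deepest generation present with its parents (a gene of a
non-founder is a random gene of its sire or of its dam, with equal
probability), which moves the computation up the pedigree one generation
at a time until only founders remain.  The synchronous sweep keeps the
members of intermediate states within a single generation on
generation-stratified pedigrees, which bounds the number of distinct
states per generation instead of letting mixed-generation states
accumulate.  The 9 condensed coefficients are then recovered from 9 such
state values by solving an exact linear system.

Memoization is performed on a sibship-canonical form of each state:
individuals with the same (sire, dam) pair — and likewise all founders —
have exchangeable ancestries, so states that differ only by such a
relabelling share one cache entry.  The relabelling is only applied to
members that are not ancestors of another member of the same state (an
ancestor is pinned to its concrete identity, since substituting it would
rewire the descent paths of the members below it).  This collapse is
exact and is what makes deep advanced-intercross pedigrees tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .pedigree import Pedigree, kinship_matrix

__all__ = [
    "IdentityCoefficients",
    "GeneticMatrices",
    "condensed_identity",
    "genetic_matrices",
    "kinship_from_identity",
]

# ---------------------------------------------------------------------------
# Linear system linking generalized kinship values to Δ1..Δ9.
#
# Rows give, for each observable quantity, its value conditional on each of
# the nine condensed states (columns Δ1..Δ9).  Quantities, in order:
#   1                       (normalisation)
#   f_i                     (i autozygous: states 1-4)
#   f_j                     (j autozygous: states 1,2,5,6)
#   φ(i,j)                  two-gene kinship
#   φ(i,i,j), φ(i,j,j)      three-gene
#   φ(i,i,j,j)              four-gene
#   φ(i,i ; j,j)            paired two-by-two
#   φ(i,j ; i,j)            paired cross
_F = Fraction
_M = [
    [1, 1, 1, 1, 1, 1, 1, 1, 1],
    [1, 1, 1, 1, 0, 0, 0, 0, 0],
    [1, 1, 0, 0, 1, 1, 0, 0, 0],
    [1, 0, _F(1, 2), 0, _F(1, 2), 0, _F(1, 2), _F(1, 4), 0],
    [1, 0, _F(1, 2), 0, _F(1, 4), 0, _F(1, 4), _F(1, 8), 0],
    [1, 0, _F(1, 4), 0, _F(1, 2), 0, _F(1, 4), _F(1, 8), 0],
    [1, 0, _F(1, 4), 0, _F(1, 4), 0, _F(1, 8), _F(1, 16), 0],
    [1, 1, _F(1, 2), _F(1, 2), _F(1, 2), _F(1, 2), _F(1, 4), _F(1, 4), _F(1, 4)],
    [1, 0, _F(1, 4), 0, _F(1, 4), 0, _F(1, 4), _F(1, 16), 0],
]


def _invert_exact(mat):
    """Gauss-Jordan inverse in exact rational arithmetic."""
    n = len(mat)
    a = [[_F(x) for x in row] + [_F(int(i == j)) for j in range(n)] for i, row in enumerate(mat)]
    for col in range(n):
        piv = next(r for r in range(col, n) if a[r][col] != 0)
        a[col], a[piv] = a[piv], a[col]
        pv = a[col][col]
        a[col] = [x / pv for x in a[col]]
        for r in range(n):
            if r != col and a[r][col] != 0:
                fac = a[r][col]
                a[r] = [x - fac * y for x, y in zip(a[r], a[col])]
    return [row[n:] for row in a]


_MINV_EXACT = _invert_exact(_M)
_MINV = np.array([[float(x) for x in row] for row in _MINV_EXACT])


class _StateEngine:
    """Memoized evaluator of generalized kinship states on one pedigree.

    ``table`` optionally holds a precomputed pairwise kinship table used as
    the base case for single two-gene groups; ``members`` restricts which
    individuals it covers (the hybrid strategy's split).
    """

    def __init__(self, ped: Pedigree, table: np.ndarray | None = None,
                 members: np.ndarray | None = None):
        self.sire = [int(x) for x in ped.sire]
        self.dam = [int(x) for x in ped.dam]
        n = ped.n
        self.founder = (ped.sire < 0) & (ped.dam < 0)
        # structural depth (founders 0), independent of any user-supplied
        # generation labels
        depth = np.zeros(n, dtype=np.int64)
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0 or d >= 0:
                depth[i] = 1 + max(depth[s] if s >= 0 else 0, depth[d] if d >= 0 else 0)
        self.depth = [int(x) for x in depth]
        # sibship classes: all founders share one class; non-founders are
        # classed by their (unordered) parent pair
        cls_map: dict = {}
        class_of = np.empty(n, dtype=np.int64)
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            key = (-1, -1) if (s < 0 and d < 0) else (min(s, d), max(s, d))
            class_of[i] = cls_map.setdefault(key, len(cls_map))
        self.class_of = [int(x) for x in class_of]
        self.n_classes = len(cls_map)
        # anc[i]: set of proper ancestors of i
        anc: list = [frozenset()] * n
        for i in range(n):
            s, d = int(ped.sire[i]), int(ped.dam[i])
            a = set()
            if s >= 0:
                a.add(s)
                a |= anc[s]
            if d >= 0:
                a.add(d)
                a |= anc[d]
            anc[i] = frozenset(a)
        self.anc = anc
        self.memo: dict = {}
        if table is not None and members is None:
            members = np.ones(n, dtype=bool)
        self.table = table
        self.in_table = members

    # -- canonical cache key ------------------------------------------------
    def _canon(self, groups):
        """Relabel state members to a canonical key.

        Members that are ancestors of another member keep their concrete
        identity; the rest are labelled by sibship class, with instance
        numbers assigned by a deterministic occurrence signature.
        """
        class_of = self.class_of
        inds = []
        for g in groups:
            for m in g:
                if m not in inds:
                    inds.append(m)
        anc = self.anc
        fixed_base = 4 * self.n_classes
        lab = {}
        by_class: dict = {}
        if len(inds) == 1:
            lab[inds[0]] = class_of[inds[0]] * 4
        else:
            for m in inds:
                pinned = False
                for m2 in inds:
                    if m2 != m and m in anc[m2]:
                        pinned = True
                        break
                if pinned:
                    lab[m] = fixed_base + 4 * m  # is an ancestor of another member
                else:
                    c = class_of[m]
                    prev = by_class.get(c)
                    if prev is None:
                        by_class[c] = [m]
                    else:
                        prev.append(m)
        multi = []
        for cls, v in by_class.items():
            if len(v) == 1:
                lab[v[0]] = cls * 4
            else:
                multi.append((cls * 4, v))
        if multi:
            # deterministic instance numbering: order same-class members by
            # their occurrence signature in the state (count per group plus
            # the group's class profile).  Any deterministic assignment
            # yields a correct key; the signature just makes equivalent
            # states land on the same one in the common cases.
            if len(groups) == 1:
                g0 = groups[0]
                for c4, v in multi:
                    sigs = sorted((g0.count(m), m) for m in v)
                    for inst, (_c, m) in enumerate(sigs):
                        lab[m] = c4 + inst
            else:
                profiles = [tuple(sorted([class_of[x] for x in g])) for g in groups]
                for c4, v in multi:
                    sigs = []
                    for m in v:
                        s = tuple(sorted(
                            (g.count(m), profiles[gi]) for gi, g in enumerate(groups) if m in g
                        ))
                        sigs.append((s, m))
                    sigs.sort()
                    for inst, (_s, m) in enumerate(sigs):
                        lab[m] = c4 + inst
        if len(groups) == 1:
            g = groups[0]
            return (tuple(sorted([lab[m] for m in g])),)
        return tuple(sorted(tuple(sorted([lab[m] for m in g])) for g in groups))

    # -- evaluation ---------------------------------------------------------
    def value(self, groups) -> float:
        """Probability that within every group all drawn genes are IBD.

        ``groups``: tuple of tuples of individual indices (each group of
        size >= 2, members sorted, groups sorted).
        """
        if not groups:
            return 1.0
        key = self._canon(groups)
        v = self.memo.get(key)
        if v is None:
            v = self._reduce(groups)
            self.memo[key] = v
        return v

    def _reduce(self, groups) -> float:
        # base: a single two-gene group covered by the kinship table
        if len(groups) == 1 and len(groups[0]) == 2 and self.table is not None:
            a, b = groups[0]
            if self.in_table[a] and self.in_table[b]:
                return float(self.table[a, b])
        depth = self.depth
        dmax = max(depth[m] for g in groups for m in g)
        if dmax == 0:
            # every member is a founder: groups are independent and IBD
            # within a group requires a single founder
            p = 1.0
            for g in groups:
                if g[0] != g[-1]:
                    return 0.0
                p *= 2.0 ** (1 - len(g))
            return p
        # all deepest members are replaced simultaneously; none can be an
        # ancestor of another member at the same depth
        deepest = sorted({m for g in groups for m in g if depth[m] == dmax})
        # per member, the groups holding it and its copy count there
        holders = {m: [] for m in deepest}
        total_slots = 0
        for gi, g in enumerate(groups):
            for m in deepest:
                c = sum(1 for x in g if x == m)
                if c:
                    holders[m].append((gi, c))
                    total_slots += c
        # enumerate, per (member, group), which of the member's two genes
        # its copies hit: only the sire-derived gene (weight 1), only the
        # dam-derived gene (1), or both (2^c - 2)
        slots = [(m, gi, c) for m in deepest for gi, c in holders[m]]
        keep = [[m for m in g if depth[m] < dmax] for g in groups]
        table = self.table
        total = 0.0
        stack = [(0, 1.0, [])]
        while stack:
            h, wt, flags = stack.pop()
            if h == len(slots):
                child = self._child(groups, keep, flags)
                if not child:
                    total += wt
                elif len(child) == 1 and len(child[0]) == 2 and table is not None:
                    a, b = child[0]
                    if self.in_table[a] and self.in_table[b]:
                        total += wt * float(table[a, b])
                    else:
                        total += wt * self.value(child)
                else:
                    total += wt * self.value(child)
                continue
            m, gi, c = slots[h]
            stack.append((h + 1, wt, flags + [(m, gi, 1, 0)]))
            stack.append((h + 1, wt, flags + [(m, gi, 0, 1)]))
            if c > 1:
                stack.append((h + 1, wt * ((1 << c) - 2), flags + [(m, gi, 1, 1)]))
        return total / float(1 << total_slots)

    def _child(self, groups, keep, flags):
        """Construct the reduced state for one gene-assignment pattern.

        ``keep`` holds, per group, the members below the reduced depth;
        ``flags`` is a list of (member, group index, hits-sire-gene,
        hits-dam-gene).  Copies of a member that hit the same gene collapse
        to one draw from the corresponding parent; a gene hit from two
        different groups merges those groups.
        """
        if len(groups) == 1:
            # single group: no cross-group merging possible
            mem = list(keep[0])
            for m, _gi, hp, hq in flags:
                if hp:
                    mem.append(self.sire[m])
                if hq:
                    mem.append(self.dam[m])
            if len(mem) >= 2:
                return (tuple(sorted(mem)),)
            return ()
        # mutable groups: surviving older members + gene symbols (member, 0|1)
        members = [list(k) for k in keep]
        symbols = [set() for _ in groups]
        for m, gi, hp, hq in flags:
            if hp:
                symbols[gi].add((m, 0))
            if hq:
                symbols[gi].add((m, 1))
        # union-find over groups sharing a symbol
        parent = list(range(len(groups)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        sym_home: dict = {}
        for gi in range(len(groups)):
            for s in symbols[gi]:
                if s in sym_home:
                    ra, rb = find(sym_home[s]), find(gi)
                    if ra != rb:
                        parent[rb] = ra
                else:
                    sym_home[s] = gi
        merged_members: dict = {}
        merged_syms: dict = {}
        for gi in range(len(groups)):
            r = find(gi)
            merged_members.setdefault(r, []).extend(members[gi])
            merged_syms.setdefault(r, set()).update(symbols[gi])
        out = []
        for r, mem in merged_members.items():
            mem = list(mem)
            for m, which in merged_syms[r]:
                mem.append(int(self.sire[m]) if which == 0 else int(self.dam[m]))
            if len(mem) >= 2:
                out.append(tuple(sorted(mem)))
        return tuple(sorted(out))

    # convenience wrappers
    def kinship(self, a: int, b: int) -> float:
        return self.value(((a, b) if a <= b else (b, a),))

    def inbreeding_of(self, a: int) -> float:
        return 2.0 * self.value(((a, a),)) - 1.0


@dataclass
class IdentityCoefficients:
    """Condensed identity coefficients Δ1..Δ9 for a set of target pairs.

    ``delta`` maps an unordered id pair (stored in target order, including
    self pairs) to a length-9 array; ``f`` maps each target id to its
    inbreeding coefficient.
    """

    ids: list
    delta: dict
    f: dict

    def get(self, i, j) -> np.ndarray:
        """Coefficients oriented for the pair ``(i, j)``.

        Δ3/Δ4 concern autozygosity of the first individual and Δ5/Δ6 of
        the second, so querying a stored pair in reverse order swaps those
        two index pairs; the other five states are order-symmetric.
        """
        if (i, j) in self.delta:
            return self.delta[(i, j)]
        d = self.delta[(j, i)]
        return d[[0, 1, 4, 5, 2, 3, 6, 7, 8]]

    def kinship(self, i, j) -> float:
        d = self.get(i, j)
        return float(d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, j, *map(float, d)) for (i, j), d in self.delta.items()
        ]
        return pd.DataFrame(rows, columns=["id1", "id2"] + [f"d{k}" for k in range(1, 10)])

    def f_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": list(self.f), "f": [self.f[i] for i in self.f]})


_STRATEGIES = ("bottom_up", "top_down", "hybrid")


def condensed_identity(ped: Pedigree, target_ids=None, strategy: str = "hybrid",
                       split_generation: int | None = None) -> IdentityCoefficients:
    """Compute Δ1..Δ9 for every unordered pair (including self pairs) of
    ``target_ids``.

    All three strategies return identical values; they differ in how the
    two-gene (pairwise kinship) base cases are obtained, trading storage
    for recomputation:

    - ``bottom_up``: pure lazy recursion from the targets toward the
      founders; minimal storage, cost grows with pedigree depth.
    - ``top_down``: the full pairwise kinship table is first computed
      iteratively from the founders downward and used as the base case.
    - ``hybrid``: the kinship table is computed top-down only for
      generations ``<= split_generation`` (default ``depth - 6``); state
      reduction recurses bottom-up from the targets until it reaches the
      cached generations.
    """
    if strategy not in _STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {_STRATEGIES}")
    if target_ids is None:
        target_ids = [x for i, x in enumerate(ped.ids) if not ped.hidden[i]]
    target_ids = list(target_ids)
    unknown = [t for t in target_ids if t not in ped.index]
    if unknown:
        raise KeyError(f"target id(s) not in pedigree: {unknown}")

    depth = ped.depth
    if strategy == "bottom_up":
        engine = _StateEngine(ped)
    elif strategy == "top_down":
        engine = _StateEngine(ped, table=kinship_matrix(ped))
    else:
        if split_generation is None:
            split_generation = max(0, depth - 6)
        if not (0 <= split_generation <= depth):
            raise ValueError(
                f"split_generation {split_generation} outside pedigree depth range [0, {depth}]"
            )
        members = ped.generation <= split_generation
        table = _limited_kinship(ped, members)
        engine = _StateEngine(ped, table=table, members=members)

    idx = [ped.index[t] for t in target_ids]
    f = {t: engine.inbreeding_of(i) for t, i in zip(target_ids, idx)}

    delta = {}
    for a in range(len(idx)):
        i = idx[a]
        ti = target_ids[a]
        for b in range(a, len(idx)):
            j = idx[b]
            tj = target_ids[b]
            if i == j:
                d = np.zeros(9)
                d[0] = f[ti]
                d[6] = 1.0 - f[ti]
            else:
                lo, hi = (i, j) if i < j else (j, i)
                # generalized kinship values; (i, j) ordering matters for
                # the three-gene terms, so track which target is "i"
                g = np.array([
                    1.0,
                    f[ti],
                    f[tj],
                    engine.value(((lo, hi),)),
                    engine.value((tuple(sorted((i, i, j))),)),
                    engine.value((tuple(sorted((i, j, j))),)),
                    engine.value((tuple(sorted((i, i, j, j))),)),
                    engine.value(tuple(sorted(((i, i), (j, j))))),
                    engine.value(((lo, hi), (lo, hi))),
                ])
                d = _MINV @ g
                d[(d < 0) & (d > -1e-9)] = 0.0
            delta[(ti, tj)] = d
    return IdentityCoefficients(target_ids, delta, f)


def _limited_kinship(ped: Pedigree, members: np.ndarray) -> np.ndarray:
    """Kinship table over the ancestor-closed subset ``members`` only;
    entries outside the subset are never read (guarded by the engine)."""
    n = ped.n
    K = np.zeros((n, n))
    sel = np.where(members)[0]
    pos = {int(i): k for k, i in enumerate(sel)}
    sub = np.zeros((len(sel), len(sel)))
    for k, i in enumerate(sel):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            sub[k, k] = 0.5
            continue
        ks, kd = pos[int(s)], pos[int(d)]
        row = 0.5 * (sub[ks, :k] + sub[kd, :k])
        sub[k, :k] = row
        sub[:k, k] = row
        sub[k, k] = 0.5 * (1.0 + sub[ks, kd])
    K[np.ix_(sel, sel)] = sub
    return K


def kinship_from_identity(ic: IdentityCoefficients) -> pd.DataFrame:
    """Pairwise kinship matrix implied by condensed identity coefficients."""
    ids = ic.ids
    n = len(ids)
    K = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            K[a, b] = K[b, a] = ic.kinship(ids[a], ids[b])
    return pd.DataFrame(K, index=ids, columns=ids)


@dataclass
class GeneticMatrices:
    """The five genetic incidence matrices entering the polygenic covariance.

    With φ the kinship, f the inbreeding coefficients and Δk the condensed
    identity coefficients of a pair:

    - ``AA`` (additive):            2 φ_ij,   diagonal 1 + f_i
    - ``DD`` (dominance):           Δ7,       diagonal 1 - f_i
    - ``HH`` (homozygous dominance): Δ1,      diagonal f_i
    - ``AD`` (additive-dominance):  4Δ1 + Δ3 + Δ5, diagonal 4 f_i
    - ``MH`` (inbreeding depression): Δ1 + Δ2 - f_i f_j, diagonal f_i (1 - f_i)

    For a completely outbred pedigree HH = AD = MH = 0.
    """

    ids: list
    AA: np.ndarray
    DD: np.ndarray
    AD: np.ndarray
    HH: np.ndarray
    MH: np.ndarray

    def as_dict(self) -> dict:
        return {"AA": self.AA, "DD": self.DD, "AD": self.AD, "HH": self.HH, "MH": self.MH}


def genetic_matrices(ic: IdentityCoefficients, ids=None) -> GeneticMatrices:
    """Assemble the five incidence matrices from identity coefficients.

    ``ids`` selects/orders the individuals (default: the coefficient set's
    own order); every pair of ``ids`` must be covered by ``ic``.
    """
    if ids is None:
        ids = list(ic.ids)
    n = len(ids)
    AA = np.zeros((n, n))
    DD = np.zeros((n, n))
    AD = np.zeros((n, n))
    HH = np.zeros((n, n))
    MH = np.zeros((n, n))
    f = ic.f
    for a in range(n):
        for b in range(a, n):
            try:
                d = ic.get(ids[a], ids[b])
            except KeyError:
                raise KeyError(f"identity coefficients missing for pair ({ids[a]}, {ids[b]})")
            phi = d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7]
            AA[a, b] = 2.0 * phi
            DD[a, b] = d[6]
            HH[a, b] = d[0]
            AD[a, b] = 4.0 * d[0] + d[2] + d[4]
            MH[a, b] = d[0] + d[1] - f[ids[a]] * f[ids[b]]
            AA[b, a] = AA[a, b]
            DD[b, a] = DD[a, b]
            HH[b, a] = HH[a, b]
            AD[b, a] = AD[a, b]
            MH[b, a] = MH[a, b]
    # enforce exact symmetry against float accumulation order
    for M in (AA, DD, AD, HH, MH):
        M[:] = 0.5 * (M + M.T)
    return GeneticMatrices(list(ids), AA, DD, AD, HH, MH)
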
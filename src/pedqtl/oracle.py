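"""Brute-force identity-by-descent oracle.

Independent verifier for the condensed identity machinery: every founder
gets two globally unique allele labels, every non-founder independently
inherits one of its sire's two alleles and one of its dam's two alleles,
and all 4**m transmission patterns (m = number of non-founders) are
enumerated with exact rational weights.  The pair's four allele labels are
classified into one of Jacquard's nine condensed states per pattern.

This path shares no code with the production engine and works in exact
:class:`fractions.Fraction` arithmetic; it is only feasible for small
pedigrees (guarded at m <= 12).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .pedigree import Pedigree

__all__ = ["enumerate_ibd_oracle", "enumerate_ibd_oracle_all_pairs", "jacquard_state"]

_MAX_NONFOUNDERS = 12


def jacquard_state(a: int, b: int, c: int, d: int) -> int:
    """Condensed Jacquard state (1..9) of allele labels (a,b) of one
    individual and (c,d) of the other; labels are IBD iff equal."""
    a, b, c, d = int(a), int(b), int(c), int(d)
    i_auto = a == b
    j_auto = c == d
    if i_auto and j_auto:
        return 1 if a == c else 2
    if i_auto:
        return 3 if (a == c or a == d) else 4
    if j_auto:
        return 5 if (c == a or c == b) else 6
    m = (a == c) + (a == d) + (b == c) + (b == d)
    if m == 2:
        return 7
    return 8 if m == 1 else 9


def _transmission_counts(ped: Pedigree, pairs: list[tuple[int, int]]):
    nonf = [i for i in range(ped.n) if not ped.is_founder(i)]
    m = len(nonf)
    if m > _MAX_NONFOUNDERS:
        raise ValueError(
            f"{m} non-founders exceeds the 4^m enumeration guard ({_MAX_NONFOUNDERS})"
        )
    sire, dam = ped.sire, ped.dam
    # allele labels: founders fixed, non-founders filled per pattern
    pat = np.zeros((ped.n, 2), dtype=np.int64)
    for k, i in enumerate(ped.founders):
        pat[i] = (2 * k, 2 * k + 1)
    counts = {p: np.zeros(9, dtype=np.int64) for p in pairs}
    for code in range(4**m):
        z = code
        for i in nonf:
            pat[i, 0] = pat[sire[i], z & 1]
            z >>= 1
            pat[i, 1] = pat[dam[i], z & 1]
            z >>= 1
        for p in pairs:
            i, j = p
            st = jacquard_state(pat[i, 0], pat[i, 1], pat[j, 0], pat[j, 1])
            counts[p][st - 1] += 1
    return counts, m


def enumerate_ibd_oracle(ped: Pedigree, i, j) -> list[Fraction]:
    """Exact Δ1..Δ9 for the pair ``(i, j)`` (ids) by full enumeration.

    Returns nine :class:`Fraction` values summing to 1 exactly.
    """
    ii, jj = ped.index[str(i)], ped.index[str(j)]
    counts, m = _transmission_counts(ped, [(ii, jj)])
    tot = 4**m
    return [Fraction(int(c), tot) for c in counts[(ii, jj)]]


def enumerate_ibd_oracle_all_pairs(ped: Pedigree, target_ids=None) -> dict:
    """Exact Δ1..Δ9 for every unordered pair (incl. self pairs) of targets,
    sharing one sweep over all transmission patterns."""
    if target_ids is None:
        target_ids = list(ped.ids)
    idx = [ped.index[str(t)] for t in target_ids]
    pairs = [(idx[a], idx[b]) for a in range(len(idx)) for b in range(a, len(idx))]
    counts, m = _transmission_counts(ped, pairs)
    tot = 4**m
    out = {}
    for a in range(len(idx)):
        for b in range(a, len(idx)):
            key = (target_ids[a], target_ids[b])
            out[key] = [Fraction(int(c), tot) for c in counts[(idx[a], idx[b])]]
    return out
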
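"""Pedigree-based inbreeding (F_PED).

Malecot kinship by the standard recursion, per-individual inbreeding
coefficients, a recent/ancient split obtained by truncating the pedigree a
fixed number of generations above the focal individual, and pedigree
completeness statistics.

Founders (unknown parents) are treated as unrelated and non-inbred; a single
unknown parent contributes no relatedness.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .data_io import Pedigree, UNKNOWN_PARENT


class _Kinship:
    """Memoized Malecot coancestry on one pedigree."""

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self._memo: dict[tuple[str, str], float] = {}

    def __call__(self, a: str, b: str) -> float:
        for x in (a, b):
            if x not in self.ped:
                raise KeyError(f"unknown individual id: {x}")
        return self._f(a, b)

    def _f(self, a: str, b: str) -> float:
        if a == UNKNOWN_PARENT or b == UNKNOWN_PARENT:
            return 0.0
        if self.ped.topo_index(a) > self.ped.topo_index(b):
            a, b = b, a
        key = (a, b)
        got = self._memo.get(key)
        if got is not None:
            return got
        if a == b:
            s, d = self.ped.parents(a)
            val = 0.5 * (1.0 + self._f(s, d))
        else:
            # b is the (topologically) younger: recurse through its parents
            s, d = self.ped.parents(b)
            val = 0.5 * (self._f(s, a) + self._f(d, a))
        self._memo[key] = val
        return val


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Malecot coancestry f(a, b); f(x, x) = (1 + F_x) / 2."""
    return _Kinship(ped)(a, b)


def inbreeding_pedigree(ped: Pedigree) -> pd.Series:
    """F_PED for every individual: F_x = f(sire_x, dam_x); founders get 0."""
    kin = _Kinship(ped)
    out = {}
    for x in ped.ids:
        s, d = ped.parents(x)
        out[x] = 0.0 if UNKNOWN_PARENT in (s, d) else kin._f(s, d)
    return pd.Series(out, name="f_ped")


def partition_by_generation(ped: Pedigree, x: str, g: int) -> tuple[float, float]:
    """Split F_PED(x) into recent (ancestors within ``g`` generations) + ancient.

    The recent part is F_PED computed on the pedigree truncated at depth ``g``
    above ``x``: an ancestor contributes only through paths whose every link
    lies within depth ``g`` (a parent is depth 1).  When a common ancestor is
    reached at depths ``da``/``db`` on the two sides of a loop, its own
    inbreeding is evaluated with the residual budget ``g - max(da, db)``.
    Ancient = total - recent.
    """
    if g < 1:
        raise ValueError("generation horizon g must be >= 1")
    if x not in ped:
        raise KeyError(f"unknown individual id: {x}")
    total = float(inbreeding_pedigree(ped)[x])
    s, d = ped.parents(x)
    if UNKNOWN_PARENT in (s, d):
        return 0.0, 0.0

    memo: dict[tuple, float] = {}

    def f_lim(a: str, da: int, b: str, db: int) -> float:
        """Kinship between a at depth da and b at depth db, links capped at g."""
        if a == UNKNOWN_PARENT or b == UNKNOWN_PARENT:
            return 0.0
        if (ped.topo_index(a), da) > (ped.topo_index(b), db):
            a, da, b, db = b, db, a, da
        key = (a, da, b, db)
        got = memo.get(key)
        if got is not None:
            return got
        if a == b:
            dd = max(da, db)
            if dd < g:
                ps, pd_ = ped.parents(a)
                fa = f_lim(ps, dd + 1, pd_, dd + 1)
            else:
                fa = 0.0  # ancestor's own loops lie beyond the horizon
            val = 0.5 * (1.0 + fa)
        elif db >= g:
            val = 0.0  # cannot climb past depth g
        else:
            ps, pd_ = ped.parents(b)
            val = 0.5 * (f_lim(ps, db + 1, a, da) + f_lim(pd_, db + 1, a, da))
        memo[key] = val
        return val

    recent = f_lim(s, 1, d, 1)
    ancient = total - recent
    # guard tiny negative round-off
    if -1e-12 < ancient < 0:
        ancient = 0.0
    return recent, ancient


def partition_frame(ped: Pedigree, g: int = 5,
                    ids: list[str] | None = None) -> pd.DataFrame:
    """Per-individual total / recent / ancient F_PED at horizon ``g``."""
    ids = list(ped.ids) if ids is None else ids
    total = inbreeding_pedigree(ped)
    rows = []
    for x in ids:
        recent, ancient = partition_by_generation(ped, x, g)
        rows.append((x, total[x], recent, ancient))
    return pd.DataFrame(rows, columns=["id", "f_total", "f_recent", "f_ancient"]
                        ).set_index("id")


def completeness(ped: Pedigree, ids: list[str], g: int) -> float:
    """Mean proportion of known ancestor slots at generation ``g``.

    An individual has 2**g ancestor slots at generation ``g``; a slot counts
    as known when the whole path of parents up to it is recorded.
    """
    if g < 1:
        raise ValueError("g must be >= 1")

    @lru_cache(maxsize=None)
    def slots(x: str, k: int) -> int:
        if k == 0:
            return 1
        return sum(slots(p, k - 1) for p in ped.parents(x) if p != UNKNOWN_PARENT)

    vals = []
    for x in ids:
        if x not in ped:
            raise KeyError(f"unknown individual id: {x}")
        vals.append(slots(x, g) / 2 ** g)
    return float(np.mean(vals))
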
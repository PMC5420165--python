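"""Enumeration of all largest identifiable subsets and of the smallest
highly-collinear parameter groups.

Both procedures exploit the monotonicity of the collinearity index: adding a
parameter to a subset never decreases CI.  Hence any superset of a
highly-collinear group is itself highly collinear, which allows level-wise
growth with pruning when enumerating the admissible (CI < CI*) sets, and
guarantees that the reported collinear groups are minimal.  The combinatorics
still grow exponentially, so both operations guard against being run on more
than a few dozen parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .collinearity import (DEFAULT_CI_THRESHOLD, NormalizedSensitivityMatrix,
                           ParameterSubset, collinearity_index)

ENUMERATION_GUARD = 40   # refuse breadth-wise enumeration above this many params
GROUP_GUARD = 25         # combinatorial guard for the group search


class CombinatorialGuardError(RuntimeError):
    """Too many parameters for exhaustive enumeration; pass force=True."""


@dataclass(frozen=True)
class CollinearityGroup:
    """A minimal highly-collinear parameter group, labelled G{size}({index})."""

    members: tuple[str, ...]
    ci: float
    label: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EnumerationResult:
    """All identifiable subsets of maximal size."""

    max_size: int
    subsets: list[ParameterSubset]
    ci_range: tuple[float, float]

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


def all_largest_subsets(nsm: NormalizedSensitivityMatrix,
                        threshold: float = DEFAULT_CI_THRESHOLD,
                        force: bool = False) -> EnumerationResult:
    """Enumerate every maximum-size subset with CI < CI*.

    Level-wise growth in canonical (ascending index) order: admissible sets
    of size n are extended by parameters of larger index only, so each set
    is generated exactly once, and a candidate is evaluated only if all its
    size-n subsets are admissible (CI monotonicity makes the pruning exact).
    """
    names = list(nsm.param_names)
    n = len(names)
    if n == 0:
        return EnumerationResult(0, [], (float("nan"), float("nan")))
    if n > ENUMERATION_GUARD and not force:
        raise CombinatorialGuardError(
            f"{n} parameters exceeds the enumeration guard ({ENUMERATION_GUARD})")
    idx_of = {p: i for i, p in enumerate(names)}

    # singletons always have CI = 1 and are admissible for any CI* > 1
    level: dict[tuple[int, ...], ParameterSubset] = {}
    for i, p in enumerate(names):
        ps = collinearity_index(nsm, (p,))
        if ps.ci < threshold:
            level[(i,)] = ps
    best_level = level
    while level:
        admissible = set(level)
        nxt: dict[tuple[int, ...], ParameterSubset] = {}
        for key in level:
            for j in range(key[-1] + 1, n):
                cand = key + (j,)
                # prune: every size-n subset of cand must be admissible
                if len(cand) > 2 and any(
                        cand[:k] + cand[k + 1:] not in admissible
                        for k in range(len(cand) - 1)):
                    continue
                if len(cand) == 2 and (cand[1],) not in admissible:
                    continue
                ps = collinearity_index(nsm, tuple(names[i] for i in cand))
                if ps.ci < threshold:
                    nxt[cand] = ps
        if nxt:
            best_level = nxt
        level = nxt
    subsets = list(best_level.values())
    if not subsets:
        return EnumerationResult(0, [], (float("nan"), float("nan")))
    cis = [s.ci for s in subsets]
    return EnumerationResult(len(subsets[0].members), subsets,
                             (float(min(cis)), float(max(cis))))


def smallest_collinear_groups(nsm: NormalizedSensitivityMatrix,
                              threshold: float = DEFAULT_CI_THRESHOLD,
                              max_size: int = 6,
                              force: bool = False) -> list[CollinearityGroup]:
    """Minimal groups with CI >= CI*, for sizes 2..max_size.

    Starting from all pairs and growing one size at a time, a candidate is
    reported when its CI reaches the threshold and it contains no
    already-reported smaller group (so every reported group is minimal:
    removing any member drops CI below CI*).  Labels follow the G{size}({i})
    convention, the index running in discovery order within each size class.
    """
    names = list(nsm.param_names)
    if len(names) > GROUP_GUARD and not force:
        raise CombinatorialGuardError(
            f"{len(names)} parameters exceeds the group-search guard ({GROUP_GUARD})")
    reported: list[CollinearityGroup] = []
    reported_sets: list[frozenset[str]] = []
    for size in range(2, max_size + 1):
        counter = 0
        for combo in combinations(names, size):
            cs = frozenset(combo)
            if any(r <= cs for r in reported_sets):
                continue
            ps = collinearity_index(nsm, combo)
            if ps.ci >= threshold:
                counter += 1
                reported.append(CollinearityGroup(tuple(combo), ps.ci,
                                                  f"G{size}({counter})"))
                reported_sets.append(cs)
    return reported


def groups_table(groups: list[CollinearityGroup]) -> pd.DataFrame:
    """Tabular view of the collinear groups (label, CI, members)."""
    return pd.DataFrame(
        [(g.label, g.ci, " ".join(g.members)) for g in groups],
        columns=["set_id", "ci", "parameters"])


def brute_force_largest(nsm: NormalizedSensitivityMatrix,
                        threshold: float = DEFAULT_CI_THRESHOLD
                        ) -> EnumerationResult:
    """Naive exhaustive enumeration over all 2^N subsets (testing oracle)."""
    names = list(nsm.param_names)
    n = len(names)
    if n > 16:
        raise CombinatorialGuardError("brute force limited to 16 parameters")
    best_size, best = 0, []
    for mask in range(1, 2 ** n):
        members = tuple(names[i] for i in range(n) if mask >> i & 1)
        if len(members) < best_size:
            continue
        ps = collinearity_index(nsm, members)
        if ps.ci < threshold:
            if len(members) > best_size:
                best_size, best = len(members), [ps]
            else:
                best.append(ps)
    if not best:
        return EnumerationResult(0, [], (float("nan"), float("nan")))
    cis = [s.ci for s in best]
    return EnumerationResult(best_size, best, (float(min(cis)), float(max(cis))))
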
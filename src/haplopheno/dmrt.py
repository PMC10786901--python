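"""Duncan's multiple range test with compact-letter display.

Groups are compared after a one-way ANOVA.  For two groups separated by a
span of p consecutive ordered means, the least significant range is

    R_p = q(alpha_p, p, df_error) * sqrt(MSE / n_h)

where q is the studentized-range quantile at Duncan's protection level
alpha_p = 1 - (1 - alpha)^(p-1) and n_h is the harmonic mean of the group
sizes (the usual convention for unbalanced data).  Pairs whose observed mean
difference falls below the applicable R_p share a letter; letters come from
the standard insert-and-absorb construction, so two groups share a letter if
and only if they are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .panel import ValidationError


@lru_cache(maxsize=4096)
def duncan_q(alpha: float, span: int, df: int) -> float:
    """Duncan's critical studentized-range quantile for a span of ``span`` means."""
    if span < 2 or df < 1:
        raise ValueError("span must be >= 2 and df >= 1")
    protection = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(studentized_range.ppf(1.0 - protection, span, df))


@dataclass
class AnovaStats:
    f: float
    df1: int
    df2: int
    p: float
    mse: float


@dataclass
class DmrtResult:
    """Letters and summary statistics of a Duncan multiple range test.

    ``letters`` maps group name -> letter string ("a", "ab", ...); groups
    sharing any letter are not significantly different at ``alpha``.
    """

    anova: AnovaStats
    means: dict[str, float]
    n: dict[str, int]
    letters: dict[str, str]
    alpha: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _one_way_anova(values: Sequence[np.ndarray]) -> AnovaStats:
    k = len(values)
    ns = np.array([len(v) for v in values])
    n_tot = int(ns.sum())
    grand = np.concatenate(values).mean()
    means = np.array([v.mean() for v in values])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df1, df2 = k - 1, n_tot - k
    mse = ssw / df2 if df2 > 0 else 0.0
    if mse > 0:
        f = (ssb / df1) / mse
        p = float(f_dist.sf(f, df1, df2))
    else:
        f = float("inf") if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    return AnovaStats(f=f, df1=df1, df2=df2, p=p, mse=mse)


def _letters_from_sig(order: list[str], sig: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` lists groups by descending mean; ``sig[i, j]`` is True when
    groups i and j (indices into ``order``) differ significantly.
    """
    k = len(order)
    sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            nxt: list[set[int]] = []
            for s in sets:
                if i in s and j in s:
                    nxt.append(s - {i})
                    nxt.append(s - {j})
                else:
                    nxt.append(s)
            # absorb: drop duplicates and strict subsets
            nxt = [s for s in nxt if s]
            sets = [
                s
                for idx, s in enumerate(nxt)
                if not any(s < t or (s == t and idx2 < idx) for idx2, t in enumerate(nxt) if idx2 != idx)
            ]
    sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in order}
    for pos, s in enumerate(sets):
        sym = alphabet[pos] if pos < 26 else f"({pos})"
        for idx in sorted(s):
            letters[order[idx]].append(sym)
    return {g: "".join(ls) for g, ls in letters.items()}


def dmrt(
    groups: Mapping[str, Sequence[float]] | Sequence[tuple[str, Sequence[float]]],
    alpha: float = 0.05,
) -> DmrtResult:
    """Run a one-way ANOVA plus Duncan's multiple range test on named groups.

    Accepts a mapping or sequence of (name, values).  Requires >= 2 groups and
    total n greater than the number of groups.  When MSE is zero, groups with
    unequal means are trivially separated and equal means share a letter.
    """
    items = list(groups.items()) if isinstance(groups, Mapping) else list(groups)
    if len(items) < 2:
        raise ValidationError("DMRT needs at least two groups")
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate group names")
    values = [np.asarray(v, dtype=float) for _, v in items]
    if any(len(v) == 0 for v in values):
        raise ValidationError("empty group supplied")
    if sum(len(v) for v in values) <= len(values):
        raise ValidationError("total n must exceed the number of groups")

    anova = _one_way_anova(values)
    means = {name: float(v.mean()) for name, v in zip(names, values)}
    n = {name: len(v) for name, v in zip(names, values)}
    # descending means; deterministic tie-break by name
    order = sorted(names, key=lambda g: (-means[g], g))
    k = len(order)
    n_h = k / sum(1.0 / n[g] for g in order)

    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[order[i]] - means[order[j]]
            if anova.mse == 0.0:
                sig[i, j] = sig[j, i] = diff > 0
                continue
            span = j - i + 1
            r_p = duncan_q(alpha, span, anova.df2) * np.sqrt(anova.mse / n_h)
            sig[i, j] = sig[j, i] = diff >= r_p
    letters = _letters_from_sig(order, sig)
    return DmrtResult(anova=anova, means=means, n=n, letters=letters, alpha=alpha)
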
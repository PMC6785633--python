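"""Circadian-time-order randomization test for LAD border periodicity.

Detected periodicity is trusted only if it is *imposed by the true CT
order*: the measured border values are re-ordered by random permutations of
the CT labels (replicate pairing within each CT preserved, the same global
permutations applied to every LAD), the rhythm engine is re-run, and the
experimental period group is compared with each shuffle's group. With the
default 3 shuffles, a border passes when its experimental periodicity
differs from at least two of the randomized orders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rhythm import meta_fit


@dataclass(frozen=True)
class RandomizationVerdict:
    series_id: str
    experimental_group: int | None
    p_experimental: float
    shuffle_groups: tuple[int | None, ...]
    n_shuffles: int
    n_discordant: int
    passes: bool


def shuffle_ct_orders(
    n_ct: int, n: int = 3, seed: int | None = None
) -> list[tuple[int, ...]]:
    """Draw ``n`` distinct non-identity permutations of the CT indices."""
    if n < 1:
        raise ValueError("need at least one shuffle")
    if n_ct < 3:
        raise ValueError("need at least 3 time points to shuffle")
    available = math.factorial(n_ct) - 1
    if n > available:
        raise ValueError(f"only {available} non-identity permutations exist for {n_ct} CTs")
    rng = np.random.default_rng(seed)
    identity = tuple(range(n_ct))
    out: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(out) < n:
        perm = tuple(int(i) for i in rng.permutation(n_ct))
        if perm == identity or perm in seen:
            continue
        seen.add(perm)
        out.append(perm)
    return out


def randomization_verdict(
    values: Sequence[float] | np.ndarray,
    times: Sequence[float],
    permutations: Sequence[tuple[int, ...]],
    *,
    series_id: str = "",
    alpha: float = 0.05,
    min_discordant: int = 2,
    **engine_kwargs,
) -> RandomizationVerdict:
    """Compare experimental periodicity with CT-shuffled refits.

    A group is recorded only when the (re)fit is significant at ``alpha``;
    otherwise the group is None ("no rhythm"). Discordance means the
    shuffle's group differs from the experimental group (including
    significant -> none). A series with no significant experimental rhythm
    cannot pass: there is no periodicity to validate.
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    exp = meta_fit(arr, times, series_id=series_id, **engine_kwargs)
    exp_group = exp.period_group if exp.p_combined < alpha else None
    shuffle_groups: list[int | None] = []
    for perm in permutations:
        refit = meta_fit(arr[:, list(perm)], times, **engine_kwargs)
        shuffle_groups.append(refit.period_group if refit.p_combined < alpha else None)
    n_discordant = sum(g != exp_group for g in shuffle_groups)
    passes = exp_group is not None and n_discordant >= min_discordant
    return RandomizationVerdict(
        series_id=series_id,
        experimental_group=exp_group,
        p_experimental=float(exp.p_combined),
        shuffle_groups=tuple(shuffle_groups),
        n_shuffles=len(permutations),
        n_discordant=n_discordant,
        passes=passes,
    )
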
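"""Cross-cancer conservation of altered boundaries via the hypergeometric test.

Given identifier sets of altered boundaries/motifs per cancer type within a
common universe, the pairwise overlap is scored with the upper-tail
hypergeometric probability P(X >= k) — the probability of observing at least
the seen overlap when drawing the smaller set at random from the universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Hashable, Mapping

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OverlapTest:
    universe_size: int
    set_a_size: int
    set_b_size: int
    observed_overlap: int
    p_value: float


def hypergeometric_overlap(set_a: Collection[Hashable],
                           set_b: Collection[Hashable],
                           universe: Collection[Hashable]) -> OverlapTest:
    """Upper-tail hypergeometric test of the overlap of two identifier sets.

    Both sets must be subsets of the universe. Computed via scipy's
    hypergeometric survival function (log-space stable for large universes).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be contained in the universe")
    big_n, big_k, n = len(u), len(a), len(b)
    k = len(a & b)
    # P(X >= k) with X ~ Hypergeometric(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    p = min(max(p, 0.0), 1.0)
    return OverlapTest(universe_size=big_n, set_a_size=big_k, set_b_size=n,
                       observed_overlap=k, p_value=p)


def pairwise_conservation(sets_by_cancer: Mapping[str, Collection[Hashable]],
                          universe: Collection[Hashable]) -> pd.DataFrame:
    """Symmetric matrix of pairwise upper-tail overlap p-values.

    The diagonal is left as NaN.
    """
    names = list(sets_by_cancer)
    if len(names) < 2:
        raise ValueError("need at least two cancer sets")
    frame = pd.DataFrame(float("nan"), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p = hypergeometric_overlap(sets_by_cancer[a], sets_by_cancer[b],
                                       universe).p_value
            frame.loc[a, b] = p
            frame.loc[b, a] = p
    return frame
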
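"""Bayesian expected false discovery rate control over posterior calls.

Given posterior probabilities ``p_i`` that the event of interest is real at
site ``i``, the expected FDR of a selected set ``S`` is
``mean(1 - p_i, i in S)``.  Selecting the longest prefix of the sites
sorted by descending posterior whose expected FDR stays at or below the
nominal level alpha yields the largest selection with controlled expected
FDR: prefix means of the ascending ``1 - p_i`` sequence are non-decreasing,
so the feasible prefixes are exactly those up to the break point.

Sites tied at the threshold posterior are treated all-or-none: a posterior
value must map to a single decision, so a tied group is included only if
the constraint holds with every member of the group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = ["FdrSelection", "control_fdr"]

#: Threshold sentinel reported when nothing is selected: just above 1, so
#: "posterior >= threshold" selects nothing.
EMPTY_THRESHOLD = float(np.nextafter(1.0, 2.0))


@dataclass(frozen=True)
class FdrSelection:
    """Result of expected-FDR control at nominal level ``alpha``."""

    alpha: float
    selected: tuple
    threshold: float
    achieved_efdr: float


def control_fdr(
    posteriors: Iterable[tuple[Hashable, float]], alpha: float
) -> FdrSelection:
    """Select the largest posterior-sorted prefix with expected FDR <= alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    items = list(posteriors)
    for _, p in items:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"posterior probabilities must lie in [0, 1], got {p}")
    items.sort(key=lambda item: -item[1])

    selected: list = []
    threshold = EMPTY_THRESHOLD
    achieved = 0.0
    loss = 0.0  # running sum of (1 - p) over the candidate prefix
    count = 0
    candidate: list = []
    for p, group in groupby(items, key=lambda item: item[1]):
        group = list(group)
        loss += (1.0 - p) * len(group)
        count += len(group)
        if loss / count > alpha:
            break
        candidate.extend(site_id for site_id, _ in group)
        selected = list(candidate)
        threshold = p
        achieved = loss / count
    return FdrSelection(
        alpha=alpha,
        selected=tuple(selected),
        threshold=threshold,
        achieved_efdr=achieved,
    )
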
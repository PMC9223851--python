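"""Per-position variant-occurrence spectrum across a dataset.

The histogram behind circular mitogenome plots: every difference in the
dataset is counted at its reference np, except the universal variants
shared by all samples, length heteroplasmy and poly-C stretch insertions.
PHPs count as full differences; a multi-base block insertion is a single
event at its anchor np; deletions count at their reference np.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .matching import DEFAULT_RULES, MatchRules, _is_length_variant
from .nomenclature import DELETION, INSERTION, SUBSTITUTION, Haplotype, region_of

#: Differences carried by every sample of an MCH dataset; excluded from the
#: spectrum because they carry no contrast.
UNIVERSAL_NPS = frozenset({263, 750, 4769, 8860, 15326, 16519})


@dataclass
class SpectrumHistogram:
    counts: dict[int, int]
    excluded_universal: frozenset[int]

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())


def spectrum(
    hs: Sequence[Haplotype],
    rules: MatchRules = DEFAULT_RULES,
    excluded_universal: frozenset[int] = UNIVERSAL_NPS,
) -> SpectrumHistogram:
    if not hs:
        raise ValueError("empty dataset")
    counts: Counter[int] = Counter()
    for h in hs:
        insertion_blocks: set[int] = set()
        for v in h.variants:
            if v.position in excluded_universal:
                continue
            if _is_length_variant(v, rules):
                continue
            if v.heteroplasmic and v.kind != SUBSTITUTION:
                continue  # length heteroplasmy
            if v.kind == INSERTION:
                if v.position == 315:
                    continue  # part of the universal motif (315.1C)
                insertion_blocks.add(v.position)  # block counts once
            else:
                counts[v.position] += 1
        for pos in insertion_blocks:
            counts[pos] += 1
    return SpectrumHistogram(
        counts=dict(sorted(counts.items())),
        excluded_universal=excluded_universal,
    )


def spectrum_table(
    hist: SpectrumHistogram, min_count: int = 5
) -> pd.DataFrame:
    """Circular-plot-ready table: np, count, region, label (label set iff
    the np reaches ``min_count`` occurrences)."""
    rows = [
        {
            "np": pos,
            "count": n,
            "region": region_of(pos),
            "label": f"{pos} ({n})" if n >= min_count else "",
        }
        for pos, n in sorted(hist.counts.items())
    ]
    return pd.DataFrame(rows, columns=["np", "count", "region", "label"])
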
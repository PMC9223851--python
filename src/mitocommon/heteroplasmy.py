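"""Point- and length-heteroplasmy extraction and summary statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    Haplotype,
    Variant,
    region_of,
)
from .reference import ReferenceGenome, get_reference

#: The study called variants above a 10% relative read depth; fractions
#: below that are metadata inconsistencies worth flagging, not errors.
DETECTION_THRESHOLD = 0.10


@dataclass(frozen=True)
class PHPRecord:
    """One point heteroplasmy (PHP): a two-state IUPAC position."""

    sample_id: str
    position: int
    code: str
    major_base: str = ""
    minor_base: str = ""
    minor_fraction: Optional[float] = None
    region: str = ""
    platform: Optional[str] = None
    is_transition: bool = True


def extract_phps(
    h: Haplotype, reference: Optional[ReferenceGenome] = None
) -> list[PHPRecord]:
    """One record per heteroplasmic substitution in the haplotype.

    Length heteroplasmies (lowercase insertion/deletion tokens) are not
    PHPs and are counted separately by :func:`php_summary`.  When a minor
    fraction is known, the major/minor bases are oriented by it (the
    reference base is taken as major otherwise, when determinable).
    """
    ref = get_reference(reference)
    records = []
    for v in h.variants:
        if v.kind != SUBSTITUTION or not v.heteroplasmic:
            continue
        comps = sorted(v.components)
        if len(comps) != 2:
            continue
        fraction = None
        if h.php_fractions:
            fraction = h.php_fractions.get(v.position)
        if fraction is not None and fraction < DETECTION_THRESHOLD:
            warnings.warn(
                f"{h.sample_id}: np {v.position} minor fraction "
                f"{fraction:.2f} below the 10% detection threshold",
                stacklevel=2,
            )
        ref_base = ref.base_at(v.position)
        if ref_base in comps:
            major = ref_base
            minor = comps[0] if comps[1] == ref_base else comps[1]
        else:
            major, minor = comps
        records.append(
            PHPRecord(
                sample_id=h.sample_id,
                position=v.position,
                code=v.observed,
                major_base=major,
                minor_base=minor,
                minor_fraction=fraction,
                region=region_of(v.position),
                platform=h.platform,
                is_transition=bool(v.is_transition),
            )
        )
    return records


def has_length_heteroplasmy(h: Haplotype) -> bool:
    """True when the haplotype carries a heteroplasmic length event
    (lowercase insertion or deletion token, e.g. 524.1a 524.2c)."""
    return any(
        v.heteroplasmic and v.kind in (INSERTION, DELETION) for v in h.variants
    )


def _level_stats(fractions: Sequence[float]) -> dict:
    if not fractions:
        return {"n": 0, "min": None, "max": None, "mean": None, "median": None}
    arr = np.asarray(fractions, dtype=float)
    return {
        "n": int(arr.size),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
    }


def php_summary(
    hs: Sequence[Haplotype],
    reference: Optional[ReferenceGenome] = None,
) -> dict:
    """Dataset-level PHP summary.

    Reports totals, the carrier count/fraction, distinct positions and
    their CR/codR split, multi-PHP samples, recurrent positions, level
    statistics overall and per platform, and length-heteroplasmy carriers.
    """
    if not hs:
        raise ValueError("empty dataset")
    N = len(hs)
    records: list[PHPRecord] = []
    per_sample: dict[str, int] = {}
    for h in hs:
        recs = extract_phps(h, reference)
        records.extend(recs)
        per_sample[h.sample_id] = len(recs)

    positions = sorted({r.position for r in records})
    pos_counts: dict[int, int] = {}
    for r in records:
        pos_counts[r.position] = pos_counts.get(r.position, 0) + 1
    carriers = sum(1 for n in per_sample.values() if n >= 1)
    fractions = [r.minor_fraction for r in records if r.minor_fraction is not None]

    by_platform: dict[str, dict] = {}
    platforms = sorted({r.platform for r in records if r.platform})
    for plat in platforms:
        plat_f = [
            r.minor_fraction
            for r in records
            if r.platform == plat and r.minor_fraction is not None
        ]
        plat_carriers = sum(
            1
            for h in hs
            if h.platform == plat and per_sample[h.sample_id] >= 1
        )
        plat_n = sum(1 for h in hs if h.platform == plat)
        by_platform[plat] = {
            "samples": plat_n,
            "carriers": plat_carriers,
            "carrier_fraction": plat_carriers / plat_n if plat_n else None,
            "levels": _level_stats(plat_f),
        }

    return {
        "N": N,
        "total_phps": len(records),
        "carriers": carriers,
        "carrier_fraction": carriers / N,
        "distinct_positions": len(positions),
        "cr_positions": sum(1 for p in positions if region_of(p) == "CR"),
        "codr_positions": sum(1 for p in positions if region_of(p) == "codR"),
        "samples_with_multiple_phps": sum(
            1 for n in per_sample.values() if n >= 2
        ),
        "recurrent_positions": sorted(
            p for p, c in pos_counts.items() if c > 1
        ),
        "transitions": sum(1 for r in records if r.is_transition),
        "transversions": sum(1 for r in records if not r.is_transition),
        "levels": _level_stats(fractions),
        "by_platform": by_platform,
        "length_heteroplasmy_carriers": sum(
            1 for h in hs if has_length_heteroplasmy(h)
        ),
    }


def php_table(
    hs: Sequence[Haplotype],
    reference: Optional[ReferenceGenome] = None,
) -> pd.DataFrame:
    """All PHP records of a dataset as a tidy table."""
    rows = []
    for h in hs:
        for r in extract_phps(h, reference):
            rows.append(r.__dict__)
    columns = [
        "sample_id", "position", "code", "major_base", "minor_base",
        "minor_fraction", "region", "platform", "is_transition",
    ]
    return pd.DataFrame(rows, columns=columns)
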
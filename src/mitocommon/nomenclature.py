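"""rCRS-relative mtDNA variant nomenclature.

Human mtDNA haplotypes are conventionally reported as lists of differences
from the revised Cambridge Reference Sequence (rCRS), e.g. the most common
West Eurasian control-region motif ``263G 315.1C 16519C``.  This module
parses, validates and serialises that token grammar and classifies
nucleotide positions (nps) into the canonical mitogenome regions.

Token grammar
-------------
``<np><base>``
    substitution; an IUPAC ambiguity code (R/Y/W/S/K/M) denotes a point
    heteroplasmy (PHP), e.g. ``6253Y``.
``<np>.<k><base>``
    the k-th inserted base after ``np`` (k >= 1), e.g. ``315.1C``; a
    lowercase base denotes a heteroplasmic length event, e.g. ``524.1a``.
``<np>DEL`` / ``<np>del``
    deletion of the reference base at ``np``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

MT_LENGTH = 16569

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

#: IUPAC symbol -> constituent base set (two-state codes only; mtDNA point
#: heteroplasmies are two-state by forensic convention).
IUPAC_COMPONENTS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

AMBIGUITY_CODES = frozenset("RYWSKM")

_TOKEN_RE = re.compile(r"^(\d+)(?:\.(\d+))?([A-Za-z]+)$")


class NomenclatureError(ValueError):
    """Raised for malformed variant tokens or invalid haplotypes."""


@dataclass(frozen=True, order=True)
class Variant:
    """One rCRS-relative difference.

    Ordering is by (position, insertion_index) which matches the canonical
    serialisation order of haplotype strings.
    """

    position: int
    insertion_index: int = 0
    kind: str = SUBSTITUTION
    observed: str = ""
    heteroplasmic: bool = False
    reference_base: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise NomenclatureError(
                f"position {self.position} outside 1..{MT_LENGTH}"
            )
        if self.insertion_index < 0:
            raise NomenclatureError("insertion_index must be >= 0")
        if self.insertion_index > 0 and self.kind != INSERTION:
            raise NomenclatureError(
                "insertion_index > 0 requires kind='insertion'"
            )
        if self.kind == INSERTION and self.insertion_index == 0:
            raise NomenclatureError("insertions need insertion_index >= 1")
        if self.kind == DELETION:
            if self.observed:
                raise NomenclatureError("deletions carry no observed base")
        else:
            if self.observed not in IUPAC_COMPONENTS:
                raise NomenclatureError(
                    f"illegal observed base {self.observed!r}"
                )

    @property
    def key(self) -> tuple[int, int]:
        """Site identity: (position, insertion_index)."""
        return (self.position, self.insertion_index)

    @property
    def components(self) -> frozenset[str]:
        """Constituent bases of the observed symbol ({'-'} for deletions)."""
        if self.kind == DELETION:
            return frozenset("-")
        return IUPAC_COMPONENTS[self.observed]

    @property
    def is_transition(self) -> Optional[bool]:
        """For two-state PHPs: True if the two components are a transition
        pair (A/G or C/T), False if a transversion, None if not a PHP."""
        if len(self.components) != 2 or self.kind == DELETION:
            return None
        return self.components in (frozenset("AG"), frozenset("CT"))


def ambiguity_components(code: str) -> frozenset[str]:
    """Constituent base set of an IUPAC symbol (singleton for A/C/G/T)."""
    try:
        return IUPAC_COMPONENTS[code.upper()]
    except KeyError:
        raise NomenclatureError(f"unsupported IUPAC symbol {code!r}") from None


def parse_variant(token: str) -> Variant:
    """Parse one EMPOP-style token into a :class:`Variant`.

    >>> parse_variant("315.1C").kind
    'insertion'
    >>> parse_variant("6253Y").heteroplasmic
    True
    """
    m = _TOKEN_RE.match(token)
    if m is None:
        raise NomenclatureError(f"malformed variant token {token!r}")
    pos = int(m.group(1))
    if not 1 <= pos <= MT_LENGTH:
        raise NomenclatureError(
            f"token {token!r}: position {pos} outside 1..{MT_LENGTH}"
        )
    idx = int(m.group(2)) if m.group(2) else 0
    tail = m.group(3)

    if tail.upper() == "DEL":
        if m.group(2):
            raise NomenclatureError(f"token {token!r}: deletion with insertion index")
        return Variant(position=pos, kind=DELETION)

    if len(tail) != 1 or tail.upper() not in IUPAC_COMPONENTS:
        raise NomenclatureError(f"token {token!r}: illegal base {tail!r}")
    base = tail.upper()
    lowercase = tail.islower()
    heteroplasmic = lowercase or base in AMBIGUITY_CODES

    if m.group(2):
        if idx == 0:
            raise NomenclatureError(f"token {token!r}: insertion index 0")
        return Variant(
            position=pos,
            insertion_index=idx,
            kind=INSERTION,
            observed=base,
            heteroplasmic=heteroplasmic,
        )
    return Variant(
        position=pos,
        kind=SUBSTITUTION,
        observed=base,
        heteroplasmic=heteroplasmic,
    )


def serialize_variant(v: Variant) -> str:
    """Canonical token for a variant (deletions uppercase ``DEL``;
    heteroplasmic non-ambiguity bases lowercase)."""
    if v.kind == DELETION:
        return f"{v.position}DEL"
    base = v.observed
    if v.heteroplasmic and base not in AMBIGUITY_CODES:
        base = base.lower()
    if v.kind == INSERTION:
        return f"{v.position}.{v.insertion_index}{base}"
    return f"{v.position}{base}"


# ---------------------------------------------------------------------------
# Haplotype

@dataclass(frozen=True)
class Haplotype:
    """A sample's rCRS-relative variant set plus its sequenced range.

    ``range_start > range_end`` encodes a range wrapping the circular
    origin (e.g. the control region 16024..576); the full mitogenome is
    canonically 1..16569.
    """

    sample_id: str
    variants: tuple[Variant, ...]
    range_start: int = 1
    range_end: int = MT_LENGTH
    region_of_origin: Optional[str] = None
    platform: Optional[str] = None
    php_fractions: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.variants))
        object.__setattr__(self, "variants", ordered)
        seen: set[tuple[int, int]] = set()
        for v in ordered:
            if v.key in seen:
                raise NomenclatureError(
                    f"{self.sample_id}: duplicate variant at np "
                    f"{v.position}.{v.insertion_index}"
                )
            seen.add(v.key)
            if not self.covers(v.position):
                raise NomenclatureError(
                    f"{self.sample_id}: variant at np {v.position} outside "
                    f"declared range {self.range_start}-{self.range_end}"
                )

    def covers(self, position: int) -> bool:
        if self.range_start <= self.range_end:
            return self.range_start <= position <= self.range_end
        return position >= self.range_start or position <= self.range_end

    def covers_interval(self, start: int, end: int) -> bool:
        return all(self.covers(p) for p in (start, end)) and (
            self.range_start > self.range_end
            or (self.range_start <= start and end <= self.range_end)
        )

    def covers_control_region(self) -> bool:
        """True when the declared range spans nps 16024..16569 and 1..576."""
        return self.covers(16024) and self.covers(16569) and self.covers(1) and self.covers(576)

    @property
    def range_string(self) -> str:
        return f"{self.range_start}-{self.range_end}"

    def variant_at(self, position: int, insertion_index: int = 0) -> Optional[Variant]:
        for v in self.variants:
            if v.key == (position, insertion_index):
                return v
        return None


def make_haplotype(sample_id: str, tokens: Iterable[str] | str, **kwargs) -> Haplotype:
    """Build a haplotype from a token iterable or space-separated string."""
    if isinstance(tokens, str):
        tokens = tokens.split()
    return Haplotype(
        sample_id=sample_id,
        variants=tuple(parse_variant(t) for t in tokens),
        **kwargs,
    )


def parse_haplotype_string(sample_id: str, text: str, **kwargs) -> Haplotype:
    return make_haplotype(sample_id, text, **kwargs)


def serialize_haplotype(h: Haplotype) -> str:
    """Space-separated canonical tokens sorted by (np, insertion index)."""
    return " ".join(serialize_variant(v) for v in sorted(h.variants))


def with_variants(h: Haplotype, variants: Iterable[Variant]) -> Haplotype:
    return replace(h, variants=tuple(variants))


# ---------------------------------------------------------------------------
# Regions

#: Control region: 16024..16569 wrapping the origin to 1..576.
CR_INTERVALS = ((16024, MT_LENGTH), (1, 576))
CODR_INTERVAL = (577, 16023)

#: Hypervariable segments. HVS-II and HVS-III overlap at np 340 exactly as
#: cited in the source nomenclature; region queries therefore return sets.
HVS_INTERVALS = {
    "HVS-I": (16024, 16365),
    "HVS-II": (73, 340),
    "HVS-III": (340, 576),
}


def in_control_region(position: int) -> bool:
    return any(a <= position <= b for a, b in CR_INTERVALS)


def region_of(position: int) -> str:
    """'CR' or 'codR' — every np belongs to exactly one."""
    if not 1 <= position <= MT_LENGTH:
        raise NomenclatureError(f"np {position} outside 1..{MT_LENGTH}")
    return "CR" if in_control_region(position) else "codR"


def classify_region(position: int) -> frozenset[str]:
    """All region labels containing the np (CR/codR plus any HVS)."""
    labels = {region_of(position)}
    for name, (a, b) in HVS_INTERVALS.items():
        if a <= position <= b:
            labels.add(name)
    return frozenset(labels)
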
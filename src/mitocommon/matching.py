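"""Forensic haplotype comparison.

Implements the forensic conventions for comparing mitogenomes: point
heteroplasmy (PHP) and poly-C stretch length variation are not preclusive
of a match, so comparison happens on a normalised ("comparable") variant
set, and a PHP can make one sample compatible with two otherwise distinct
haplotypes.  The identity partition then carries such samples as members of
more than one group, under the configurable double-match scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .nomenclature import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    Haplotype,
    Variant,
    in_control_region,
)
from .reference import ReferenceGenome, get_reference

#: nps whose insertions are poly-C / homopolymer length variants.
DEFAULT_C_STRETCH_ANCHORS = frozenset(
    {309, 315, 455, 463, 573, 960, 965, 5899, 8276, 16193}
)
#: The AC dinucleotide repeat: 523/524 insertions and deletions are length
#: variants as well.
DINUCLEOTIDE_NPS = frozenset({523, 524})

#: The most common West Eurasian CR haplotype motif.
MCH_MOTIF_TOKENS = ("263G", "315.1C", "16519C")


@dataclass(frozen=True)
class MatchRules:
    """Normalisation rules applied before any forensic comparison."""

    ignore_length_variation: bool = True
    heteroplasmy_compatible: bool = True
    c_stretch_anchors: frozenset[int] = DEFAULT_C_STRETCH_ANCHORS
    dinucleotide_nps: frozenset[int] = DINUCLEOTIDE_NPS


DEFAULT_RULES = MatchRules()


class Scenario(str, Enum):
    """How a sample matching two groups (via a PHP) enters the partition."""

    DOUBLE_MATCH = "double_match"
    INFLATE_TOTAL = "inflate_total"
    ASSIGN_TO_MAJOR = "assign_to_major"
    ASSIGN_TO_MINOR = "assign_to_minor"


def _is_length_variant(v: Variant, rules: MatchRules) -> bool:
    if v.kind == INSERTION:
        if v.position == 315 and v.insertion_index == 1:
            # 315.1C is part of the motif itself, never stripped
            return False
        return v.position in rules.c_stretch_anchors or (
            v.position in rules.dinucleotide_nps
        )
    if v.kind == DELETION:
        return v.position in rules.dinucleotide_nps
    return False


def comparable_variants(
    h: Haplotype, rules: MatchRules = DEFAULT_RULES
) -> tuple[Variant, ...]:
    """The variant set entering forensic comparison.

    Length-variant insertions/deletions at the anchor nps and heteroplasmic
    length events are removed; PHP substitutions are retained (their
    compatibility is handled by the match predicates).
    """
    out = []
    for v in h.variants:
        if rules.ignore_length_variation:
            if _is_length_variant(v, rules):
                continue
            if v.heteroplasmic and v.kind != SUBSTITUTION:
                continue  # heteroplasmic length event, e.g. 524.1a
        out.append(v)
    return tuple(out)


class RangeError(ValueError):
    """Raised when haplotype ranges preclude the requested comparison."""


_MCH_SUBSTITUTIONS = {263: "G", 16519: "C"}
_MCH_INSERTION = (315, 1)


def is_mch(
    h: Haplotype,
    rules: MatchRules = DEFAULT_RULES,
    reference: Optional[ReferenceGenome] = None,
) -> bool:
    """Screen one haplotype for the MCH (263G 315.1C 16519C).

    The CR-restricted comparable variant set must equal the motif exactly,
    except that a PHP is tolerated when its components include either the
    motif base (at a motif np) or the reference base (elsewhere).
    """
    if not h.covers_control_region():
        raise RangeError(
            f"{h.sample_id}: declared range {h.range_string} does not cover "
            "the control region"
        )
    ref = get_reference(reference)
    satisfied: set[tuple[int, int]] = set()
    for v in comparable_variants(h, rules):
        if not in_control_region(v.position):
            continue
        if v.kind == INSERTION:
            if v.key == _MCH_INSERTION and "C" in v.components:
                satisfied.add(v.key)
                continue
            return False
        if v.kind == DELETION:
            return False
        motif_base = _MCH_SUBSTITUTIONS.get(v.position)
        if v.heteroplasmic:
            if motif_base is not None and motif_base in v.components:
                satisfied.add(v.key)
            elif ref.base_at(v.position) in v.components:
                continue  # PHP around the reference base: not preclusive
            else:
                return False
        else:
            if motif_base is not None and v.observed == motif_base:
                satisfied.add(v.key)
            else:
                return False
    required = {(p, 0) for p in _MCH_SUBSTITUTIONS} | {_MCH_INSERTION}
    return satisfied == required


def _entries_agree(a: Variant, b: Variant) -> bool:
    return bool(a.components & b.components)


def _absence_compatible(v: Variant, ref: ReferenceGenome) -> bool:
    """A variant present in one sample and absent in the other matches only
    if it is heteroplasmic and its components include the reference base."""
    if not v.heteroplasmic or v.kind != SUBSTITUTION:
        return False
    return ref.base_at(v.position) in v.components


def haplotypes_match(
    h1: Haplotype,
    h2: Haplotype,
    rules: MatchRules = DEFAULT_RULES,
    reference: Optional[ReferenceGenome] = None,
) -> bool:
    """Categorical forensic match decision between two haplotypes."""
    if (h1.range_start, h1.range_end) != (h2.range_start, h2.range_end):
        raise RangeError(
            f"incomparable ranges {h1.range_string} vs {h2.range_string}"
        )
    ref = get_reference(reference)
    m1 = {v.key: v for v in comparable_variants(h1, rules)}
    m2 = {v.key: v for v in comparable_variants(h2, rules)}
    for key in m1.keys() | m2.keys():
        a, b = m1.get(key), m2.get(key)
        if a is not None and b is not None:
            if not _entries_agree(a, b):
                return False
        else:
            present = a if a is not None else b
            if not _absence_compatible(present, ref):
                return False
    return True


# ---------------------------------------------------------------------------
# Identity partition


@dataclass
class IdentityPartition:
    """Groups of matching haplotypes; PHP carriers may sit in two groups.

    ``N`` is the statistical denominator: the number of physical samples
    under every scenario except ``inflate_total``, where each extra
    membership inflates it.
    """

    groups: list[list[str]]
    scenario: Scenario
    N: int

    @property
    def group_sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    @property
    def total_membership(self) -> int:
        return sum(self.group_sizes)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_dict(self) -> dict:
        return {
            "groups": [sorted(g) for g in self.groups],
            "scenario": self.scenario.value,
            "N": self.N,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IdentityPartition":
        return cls(
            groups=[list(g) for g in d["groups"]],
            scenario=Scenario(d["scenario"]),
            N=int(d["N"]),
        )

    @classmethod
    def from_group_sizes(
        cls,
        sizes: Iterable[int],
        scenario: Scenario = Scenario.DOUBLE_MATCH,
        N: Optional[int] = None,
        shared_members: int = 0,
        prefix: str = "S",
    ) -> "IdentityPartition":
        """Abstract partition from a printed group-size multiset.

        ``shared_members`` of the members are double-assigned, so
        ``N = total_membership - shared_members`` unless given explicitly.
        """
        sizes = list(sizes)
        total = sum(sizes)
        if N is None:
            N = total - shared_members
        groups, nid = [], 0
        for s in sizes:
            groups.append([f"{prefix}{nid + i:04d}" for i in range(s)])
            nid += s
        return cls(groups=groups, scenario=scenario, N=N)


def _has_php(h: Haplotype, rules: MatchRules) -> bool:
    return any(
        v.heteroplasmic and v.kind == SUBSTITUTION
        for v in comparable_variants(h, rules)
    )


def build_identity_partition(
    hs: Sequence[Haplotype],
    rules: MatchRules = DEFAULT_RULES,
    scenario: Scenario = Scenario.DOUBLE_MATCH,
    reference: Optional[ReferenceGenome] = None,
) -> IdentityPartition:
    """Partition samples into groups of matching haplotypes.

    PHP-free comparable haplotypes form true equivalence classes (exact
    comparable-set equality).  Each PHP carrier is then attached to every
    class it matches; multi-class carriers are resolved per scenario.
    """
    ref = get_reference(reference)
    ids = [h.sample_id for h in hs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in dataset")
    ranges = {(h.range_start, h.range_end) for h in hs}
    if len(ranges) > 1:
        raise RangeError(f"haplotypes cover unequal ranges: {sorted(ranges)}")

    clean: dict[frozenset, list[Haplotype]] = {}
    hets: list[Haplotype] = []
    for h in hs:
        if _has_php(h, rules):
            hets.append(h)
        else:
            key = frozenset(
                (v.key, v.kind, v.observed) for v in comparable_variants(h, rules)
            )
            clean.setdefault(key, []).append(h)

    groups: list[list[Haplotype]] = [list(v) for v in clean.values()]
    extra_memberships = 0

    leftovers: list[list[Haplotype]] = []  # PHP carriers matching no clean class
    for h in hets:
        matched = [
            g for g in groups if haplotypes_match(h, g[0], rules, ref)
        ]
        if not matched:
            placed = False
            for g in leftovers:
                if all(haplotypes_match(h, m, rules, ref) for m in g):
                    g.append(h)
                    placed = True
                    break
            if not placed:
                leftovers.append([h])
            continue
        if len(matched) == 1 or scenario in (
            Scenario.ASSIGN_TO_MAJOR,
            Scenario.ASSIGN_TO_MINOR,
        ):
            if len(matched) == 1:
                target = matched[0]
            elif scenario is Scenario.ASSIGN_TO_MAJOR:
                target = max(matched, key=len)
            else:
                target = min(matched, key=len)
            target.append(h)
        else:  # double_match / inflate_total: member of every matched group
            for g in matched:
                g.append(h)
            extra_memberships += len(matched) - 1

    groups.extend(leftovers)
    n_samples = len(hs)
    N = n_samples + extra_memberships if scenario is Scenario.INFLATE_TOTAL else n_samples
    return IdentityPartition(
        groups=[[m.sample_id for m in g] for g in groups],
        scenario=scenario,
        N=N,
    )


# ---------------------------------------------------------------------------
# Shared-variant clusters (candidate unnamed branches)


@dataclass(frozen=True)
class VariantCluster:
    """Non-identical haplotypes sharing private variants beyond their
    haplogroup expectation — candidate novel/modified branches."""

    base_haplogroup: str
    shared_tokens: tuple[str, ...]
    members: tuple[str, ...]

    @property
    def label(self) -> str:
        return "-".join((self.base_haplogroup,) + self.shared_tokens)


def shared_variant_clusters(
    hs: Sequence[Haplotype],
    expected: Mapping[str, tuple[str, frozenset[Variant]]],
    min_shared: int = 1,
    rules: MatchRules = DEFAULT_RULES,
) -> list[VariantCluster]:
    """Group samples by shared non-signature variants.

    ``expected`` maps sample_id -> (haplogroup call, expected variant set).
    PHPs and poly-C length variation never define branching; the shared
    pattern of a cluster is the intersection of its members' private
    variant sets, and must contain at least ``min_shared`` variants.
    """
    privates: dict[str, tuple[str, frozenset[Variant]]] = {}
    for h in hs:
        call, exp = expected[h.sample_id]
        exp_keys = {v.key for v in exp}
        extras = frozenset(
            v
            for v in comparable_variants(h, rules)
            if not v.heteroplasmic and v.key not in exp_keys
        )
        privates[h.sample_id] = (call, extras)

    clusters: dict[tuple, VariantCluster] = {}
    by_variant: dict[tuple[str, Variant], list[str]] = {}
    for sid, (call, extras) in privates.items():
        for v in extras:
            by_variant.setdefault((call, v), []).append(sid)

    for (call, v), members in by_variant.items():
        if len(members) < 2:
            continue
        pattern = frozenset.intersection(
            *(privates[m][1] for m in members)
        )
        if len(pattern) < min_shared:
            continue
        tokens = tuple(
            f"{u.position}{u.observed}" for u in sorted(pattern)
        )
        key = (call, tokens, tuple(sorted(members)))
        clusters[key] = VariantCluster(
            base_haplogroup=call,
            shared_tokens=tokens,
            members=tuple(sorted(members)),
        )
    return sorted(
        clusters.values(), key=lambda c: (c.base_haplogroup, c.shared_tokens)
    )
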
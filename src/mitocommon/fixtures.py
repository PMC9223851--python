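"""Bundled fixtures: the printed study structures as in-memory datasets.

The raw mitogenomes behind the study live in GenBank (ON597628–ON597814,
KM252727–KM252755) and are never required here.  What the tables print —
the identity-group size multiset, the PHP catalogue, the rapid-panel class
sizes, the haplogroup inventory — is reconstructed as datasets of abstract
haplotypes: group contents are arbitrary-but-fixed private variants, since
the per-sample variant lists are not printed.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from ._synthetic import PHP_CATALOGUE, transition
from .haplogroups import HaplogroupTree
from .matching import IdentityPartition, Scenario
from .nomenclature import (
    INSERTION,
    SUBSTITUTION,
    Haplotype,
    Variant,
    parse_variant,
)
from .reference import ReferenceGenome, bundled_reference

#: §2.1 group-size multiset under the double-match convention: one septet,
#: two quintets, two quartets, seven triplets, 20 pairs, 131 singletons;
#: 216 physical samples, total membership 217 (one double assignment).
PAPER_GROUP_SIZES: tuple[int, ...] = (7, 5, 5, 4, 4) + (3,) * 7 + (2,) * 20 + (1,) * 131

#: Rapid 3-SNP panel class sizes among the 216 samples.
PAPER_PANEL_SIZES: dict[str, int] = {"H1": 98, "H3": 30, "H7": 16, "other": 72}

#: EMPOP MCH screening frequencies: (k-equivalent frequency, CI) as printed.
EMPOP_WEST_EURASIA = {"n": 15782, "frequency": 0.040, "ci": (0.037, 0.043)}
EMPOP_EUROPE = {"n": 8039, "frequency": 0.047, "ci": (0.042, 0.052)}
ITALY_MCH_FREQUENCY = 0.056


@lru_cache(maxsize=1)
def haplogroup_tree() -> HaplogroupTree:
    """The bundled haplogroup-H tree (synthetic signatures; see data file)."""
    path = resources.files("mitocommon.data").joinpath("haplogroup_h_tree_synthetic.txt")
    return HaplogroupTree.from_text(path.read_text())


def reference() -> ReferenceGenome:
    return bundled_reference()


def paper_partition(
    scenario: Scenario = Scenario.DOUBLE_MATCH,
) -> IdentityPartition:
    """The printed partition as an abstract id structure.

    Under double_match the septet and one pair share a member (the
    heteroplasmic sample), so total membership is 217 over N=216.  The
    assign-to-major/minor scenarios resolve that sample into the septet
    (leaving a 6253C singleton) or into the pair (leaving a sextet).
    """
    if scenario in (Scenario.DOUBLE_MATCH, Scenario.INFLATE_TOTAL):
        p = IdentityPartition.from_group_sizes(
            PAPER_GROUP_SIZES, scenario=scenario, shared_members=1, prefix="ITA"
        )
        # make the double assignment explicit: the last member of the
        # first pair group is the same sample as the last member of the
        # septet
        septet = p.groups[0]
        first_pair = next(g for g in p.groups if len(g) == 2)
        first_pair[-1] = septet[-1]
        if scenario is Scenario.INFLATE_TOTAL:
            p.N = p.total_membership
        return p
    if scenario is Scenario.ASSIGN_TO_MAJOR:
        sizes = (7, 5, 5, 4, 4) + (3,) * 7 + (2,) * 19 + (1,) * 132
    else:  # ASSIGN_TO_MINOR: the septet loses its heteroplasmic member
        sizes = (6, 5, 5, 4, 4) + (3,) * 7 + (2,) * 20 + (1,) * 131
    return IdentityPartition.from_group_sizes(
        sizes, scenario=scenario, shared_members=0, prefix="ITA"
    )


_BASE_TOKENS = ("263G", "315.1C", "750G", "1438G", "4769G", "8860G",
                "15326G", "16519C")

_FIXTURE_RESERVED = {
    263, 315, 750, 1438, 4769, 8860, 15326, 16519, 3010, 6776, 4793, 6253,
    309, 455, 463, 573, 960, 965, 5899, 8276, 16193, 523, 524,
} | {p for p, _ in PHP_CATALOGUE}


def _base_variants() -> tuple[Variant, ...]:
    return tuple(parse_variant(t) for t in _BASE_TOKENS)


def _group_marker_positions(n: int) -> list[int]:
    """Deterministic distinct codR positions for abstract group contents."""
    out, pos = [], 12007
    ref = bundled_reference()
    while len(out) < n:
        if pos not in _FIXTURE_RESERVED:
            out.append(pos)
        pos += 13
        if pos > 16000:
            raise RuntimeError("fixture position pool exhausted")
    return out


def paper_partition_dataset() -> list[Haplotype]:
    """216 full-mitogenome haplotypes reproducing the §2.1 match structure.

    Every sample carries the MCH motif plus the universal substitutions.
    The septet content is the printed most common motif (haplogroup H1,
    3010A); its heteroplasmic member UniPV_046 carries 6253Y and also
    matches a 6253C carrier, giving the double assignment.  The other
    groups receive arbitrary-but-fixed private coding-region variants.
    """
    ref = bundled_reference()
    base = _base_variants()
    hs: list[Haplotype] = []
    nid = 0

    def add(tokens: tuple[str, ...], sample_id: str | None = None) -> None:
        nonlocal nid
        sid = sample_id if sample_id is not None else f"ITA{nid:04d}"
        nid += 1
        hs.append(
            Haplotype(
                sample_id=sid,
                variants=base + tuple(parse_variant(t) for t in tokens),
            )
        )

    # septet: six clean 3010A carriers + UniPV_046 (6253Y); the pair's
    # other member carries a fixed 6253C
    for _ in range(6):
        add(("3010A",))
    add(("3010A", "6253Y"), sample_id="UniPV_046")
    add(("3010A", "6253C"))

    # remaining groups: 2 quintets, 2 quartets, 7 triplets, 19 pairs,
    # 131 singletons, each with a distinct private marker variant
    remaining = [5, 5, 4, 4] + [3] * 7 + [2] * 19 + [1] * 131
    markers = _group_marker_positions(len(remaining))
    for size, pos in zip(remaining, markers):
        token = f"{pos}{transition(ref.base_at(pos))}"
        for _ in range(size):
            add((token,))
    assert len(hs) == 216
    return hs


def php_dataset() -> list[Haplotype]:
    """216 haplotypes carrying the printed 50-PHP catalogue.

    The 47 distinct PHPs go to 47 carriers; nps 215, 9180 and 11914 recur
    in a second sample each, giving three samples with two PHPs.  Which
    sample carries which PHP is not printed; this assignment is
    arbitrary-but-fixed.
    """
    base = _base_variants()
    events = [f"{p}{c}" for p, c in PHP_CATALOGUE]
    extras = ["215R", "9180R", "11914R"]  # the recurrent positions
    hs: list[Haplotype] = []
    for i in range(216):
        tokens: list[str] = []
        if i < len(events):
            tokens.append(events[i])
            if i < len(extras):
                tokens.append(extras[i])
        platform = "Ion" if i % 8 != 7 else "Illumina"
        # a PHP at a universal np (e.g. 16519Y) replaces the fixed variant
        variants = {v.key: v for v in base}
        for t in tokens:
            v = parse_variant(t)
            variants[v.key] = v
        hs.append(
            Haplotype(
                sample_id=f"PHP{i:04d}",
                variants=tuple(variants.values()),
                platform=platform,
            )
        )
    return hs


def panel_dataset() -> list[Haplotype]:
    """216 haplotypes reproducing the printed 3-SNP panel class sizes."""
    base = _base_variants()
    marker = {"H1": "3010A", "H3": "6776C", "H7": "4793G", "other": None}
    hs: list[Haplotype] = []
    nid = 0
    for label, size in PAPER_PANEL_SIZES.items():
        tok = marker[label]
        for _ in range(size):
            extra = (parse_variant(tok),) if tok else ()
            hs.append(
                Haplotype(sample_id=f"PNL{nid:04d}", variants=base + extra)
            )
            nid += 1
    return hs
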
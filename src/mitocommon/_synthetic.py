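"""Builders for the bundled SYNTHETIC reference and haplogroup-tree fixtures.

The package cannot ship the actual rCRS (NC_012920.1) sequence, so the
bundled FASTA is a synthetic 16,569-np stand-in: pseudo-random bases with
the real rCRS base imposed at every position that the bundled fixtures,
tests and documented examples touch (the MCH motif, the universal
haplogroup-H substitutions, the rapid-panel markers, poly-C tracts, the
point-heteroplasmy catalogue, reported cluster variants).  Analyses that
depend only on those positions behave identically to runs against the real
reference; users with the real NC_012920.1 FASTA can load it instead.

The bundled haplogroup-H tree is likewise synthetic-but-plausible: clade
names are real, and signature motifs are real where the study prints them
(H = the universal set, H1 = 3010A, H3 = 6776C, H7 = 4793G, H23 = 10211T);
all other signatures are deterministic placeholders at otherwise-unused
coding-region positions, so that every clade's members remain
control-region identical (MCH) as in the study dataset.
"""

from __future__ import annotations

import random

from .nomenclature import MT_LENGTH

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Fixed seed for the frozen fixture content (not a user-facing knob).
_FIXTURE_SEED = 16569


def transition(base: str) -> str:
    return _TRANSITION[base]


# -- positions with bases imposed to match the real rCRS -------------------

_IMPOSED: dict[int, str] = {
    # MCH motif context
    263: "A", 310: "T", 316: "G", 16519: "T",
    # universal haplogroup H substitutions (relative to the rCRS)
    750: "A", 1438: "A", 4769: "A", 8860: "A", 15326: "A",
    # rapid-panel markers H1/H3/H7 and the heteroplasmy showcase np
    3010: "G", 6776: "T", 4793: "A", 6253: "T",
    # H23 marker
    10211: "C",
    # common CR polymorphisms used as non-MCH decoys
    146: "T", 152: "T", 195: "T", 16093: "T", 16311: "T",
    # reported shared-variant cluster positions
    930: "G", 3531: "G", 4703: "T", 15217: "G", 709: "G", 15470: "T",
    14329: "C", 13938: "C", 15930: "G", 16037: "A", 11266: "C",
    6827: "T", 7664: "G", 8406: "C", 11200: "A", 2851: "A", 12372: "G",
    14148: "A", 2320: "A", 4823: "T", 6216: "T", 11914: "G",
}

# poly-C / length-variant tracts
for _p in range(303, 310):
    _IMPOSED[_p] = "C"
for _p in range(311, 316):
    _IMPOSED[_p] = "C"
for _p in range(568, 574):
    _IMPOSED[_p] = "C"
for _p in range(16184, 16194):
    _IMPOSED[_p] = "C"
# AC dinucleotide repeat ending at np 524
for _i, _p in enumerate(range(515, 525)):
    _IMPOSED[_p] = "AC"[_i % 2]
for _p in (455, 960, 965, 5899, 8276):
    _IMPOSED.setdefault(_p, "C")
_IMPOSED[455] = "T"
_IMPOSED[463] = "C"

#: The study's 47 distinct point-heteroplasmy positions with their codes.
PHP_CATALOGUE: tuple[tuple[int, str], ...] = (
    (146, "Y"), (150, "Y"), (195, "Y"), (204, "W"), (215, "R"), (246, "Y"),
    (2090, "R"), (2289, "R"), (3003, "R"), (3278, "Y"), (3534, "Y"),
    (3550, "R"), (3729, "R"), (3943, "R"), (4086, "Y"), (4856, "Y"),
    (5585, "R"), (6221, "Y"), (6253, "Y"), (6267, "R"), (6716, "R"),
    (7746, "R"), (7961, "Y"), (8251, "R"), (8252, "M"), (8344, "R"),
    (8634, "Y"), (9180, "R"), (9828, "R"), (10237, "Y"), (10750, "R"),
    (11914, "R"), (12373, "R"), (12892, "Y"), (13641, "Y"), (14121, "Y"),
    (14249, "R"), (14563, "Y"), (14754, "Y"), (14798, "Y"), (15927, "R"),
    (16080, "R"), (16172, "Y"), (16256, "Y"), (16311, "Y"), (16519, "Y"),
    (16527, "Y"),
)

_CODE_DEFAULT_REF = {"R": "A", "Y": "T", "M": "A", "W": "A", "S": "C", "K": "G"}
for _pos, _code in PHP_CATALOGUE:
    _IMPOSED.setdefault(_pos, _CODE_DEFAULT_REF[_code])


def build_synthetic_reference() -> str:
    """Deterministic 16,569-base synthetic rCRS stand-in (see module doc)."""
    rng = random.Random(_FIXTURE_SEED)
    seq = [rng.choice("ACGT") for _ in range(MT_LENGTH)]
    for pos, base in _IMPOSED.items():
        seq[pos - 1] = base
    return "".join(seq)


# -- haplogroup tree fixture ------------------------------------------------

#: Universal substitutions shared by every sample in an MCH dataset; these
#: are the haplogroup-H expectation relative to the rCRS (which itself
#: belongs to H2a2a1).
H_ROOT_SIGNATURE = "263G 315.1C 750G 1438G 4769G 8860G 15326G 16519C"

# (name, parent, fixed signature or None -> deterministic placeholder)
_CLADE_DEFS: tuple[tuple[str, str | None, str | None], ...] = (
    ("H", None, H_ROOT_SIGNATURE),
    ("H1", "H", "3010A"),
    ("H1aj", "H1", None), ("H1aj1", "H1aj", None),
    ("H1ax", "H1", None), ("H1bm", "H1", None), ("H1bw", "H1", None),
    ("H1c", "H1", None), ("H1c2", "H1c", None),
    ("H1e", "H1", None), ("H1e1", "H1e", None), ("H1e1a", "H1e1", None),
    ("H1e1a2", "H1e1a", None), ("H1e2", "H1e", None),
    ("H1h", "H1", None), ("H1h1", "H1h", None),
    ("H1j", "H1", None), ("H1j3", "H1j", None),
    ("H1q", "H1", None), ("H1q2", "H1q", None), ("H1q3", "H1q", None),
    ("H1r", "H1", None), ("H1t", "H1", None),
    ("H1u", "H1", None), ("H1u1", "H1u", None),
    ("H1w", "H1", None),
    ("H2", "H", None),
    ("H3", "H", "6776C"),
    ("H3ag", "H3", None), ("H3ap", "H3", None), ("H3ar", "H3", None),
    ("H3e", "H3", None), ("H3q", "H3", None),
    ("H7", "H", "4793G"),
    ("H7a", "H7", None), ("H7b", "H7", None), ("H7b1", "H7b", None),
    ("H7b6", "H7b", None), ("H7c", "H7", None), ("H7c2", "H7c", None),
    ("H7d", "H7", None), ("H7d3", "H7d", None), ("H7e", "H7", None),
    ("H10", "H", None), ("H10a", "H10", None), ("H10c", "H10", None),
    ("H13", "H", None), ("H13a", "H13", None), ("H13a1", "H13a", None),
    ("H13a1a", "H13a1", None), ("H13a1a1", "H13a1a", None),
    ("H13a2", "H13a", None), ("H13a2a", "H13a2", None),
    ("H17", "H", None),
    ("H18", "H", None), ("H18b", "H18", None),
    ("H23", "H", "10211T"),
    ("H26", "H", None), ("H26a", "H26", None), ("H26a1", "H26a", None),
    ("H30", "H", None), ("H30a", "H30", None),
    ("H35", "H", None),
    ("H51", "H", None),
    ("H58", "H", None),
    ("H59", "H", None), ("H59a", "H59", None),
    ("H64", "H", None), ("H65", "H", None), ("H72", "H", None),
    ("H73", "H", None), ("H75", "H", None), ("H84", "H", None),
    ("H86", "H", None), ("H87", "H", None),
)

#: nps that placeholder signatures must not use.
_RESERVED = set(_IMPOSED) | {309, 315, 455, 463, 573, 960, 965, 5899, 8276,
                             16193, 523, 524}


def build_synthetic_tree_text() -> str:
    """Tab-separated tree fixture: ``name<TAB>parent<TAB>signature``."""
    reference = build_synthetic_reference()
    lines = []
    cursor = 601
    used: set[int] = set()

    def next_free() -> int:
        nonlocal cursor
        while cursor in _RESERVED or cursor in used or cursor > 16023:
            cursor += 1
        used.add(cursor)
        pos, cursor = cursor, cursor + 37
        return pos

    for name, parent, sig in _CLADE_DEFS:
        if sig is None:
            pos = next_free()
            sig = f"{pos}{transition(reference[pos - 1])}"
        lines.append(f"{name}\t{parent or ''}\t{sig}")
    return "\n".join(lines) + "\n"
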
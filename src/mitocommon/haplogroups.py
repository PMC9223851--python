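"""Haplogroup tree representation, parsimony assignment and the 3-SNP panel.

The tree is a rooted, named clade hierarchy where each node carries
signature variants accumulated along its root path; an ``@``-prefixed
token (e.g. ``@16037``) is a back mutation that removes a previously
accumulated variant.  Assignment is transparent weighted parsimony: the
cost of placing a haplotype on a node is the weighted size of the
symmetric difference between the sample's comparable variants and the
node's expected set, with PHPs counting as carrying either of their
component bases and length variation ignored.  Samples with several
candidates within a cost tolerance fall back to the candidates' most
recent common ancestor (MRCA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .matching import DEFAULT_RULES, MatchRules, comparable_variants
from .nomenclature import (
    SUBSTITUTION,
    Haplotype,
    NomenclatureError,
    Variant,
    parse_variant,
)
from .reference import ReferenceGenome, get_reference

#: Classic mutational hotspots down-weighted in the parsimony cost.
DEFAULT_HOTSPOT_WEIGHTS: Mapping[int, float] = {
    16519: 0.5,
    152: 0.5,
    146: 0.5,
    195: 0.5,
}


class TreeError(ValueError):
    """Malformed haplogroup tree input."""


@dataclass
class HaplogroupNode:
    name: str
    parent: Optional[str]
    signature: tuple[str, ...]


class HaplogroupTree:
    """Named clades with signature variants and ``@`` back mutations."""

    def __init__(self, nodes: Iterable[HaplogroupNode]):
        self.nodes: dict[str, HaplogroupNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise TreeError(f"duplicate haplogroup name {node.name!r}")
            self.nodes[node.name] = node
        if not self.nodes:
            raise TreeError("empty haplogroup tree")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0].name
        self._children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for node in self.nodes.values():
            if node.parent is None:
                continue
            if node.parent not in self.nodes:
                raise TreeError(
                    f"{node.name!r}: unknown parent {node.parent!r}"
                )
            self._children[node.parent].append(node.name)
        for name in self.nodes:
            self.root_path(name)  # cycle detection
        self._expected_cache: dict[str, frozenset[Variant]] = {}

    @classmethod
    def from_text(cls, text: str) -> "HaplogroupTree":
        """One node per line: ``name<TAB>parent<TAB>token token ...``;
        the root line has an empty parent field."""
        nodes = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TreeError(f"line {lineno}: expected name<TAB>parent")
            name = parts[0].strip()
            parent = parts[1].strip() or None
            tokens = tuple(parts[2].split()) if len(parts) > 2 else ()
            nodes.append(HaplogroupNode(name=name, parent=parent, signature=tokens))
        return cls(nodes)

    @classmethod
    def from_file(cls, path: str | Path) -> "HaplogroupTree":
        return cls.from_text(Path(path).read_text())

    def children(self, name: str) -> list[str]:
        return list(self._children[name])

    def root_path(self, name: str) -> list[str]:
        """Names from the root down to ``name`` (inclusive)."""
        path: list[str] = []
        seen = set()
        cur: Optional[str] = name
        while cur is not None:
            if cur in seen:
                raise TreeError(f"cyclic parentage at {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def depth(self, name: str) -> int:
        return len(self.root_path(name)) - 1

    def first_level(self, name: str) -> str:
        """The depth-1 ancestor of ``name`` ('H*' for the root itself)."""
        path = self.root_path(name)
        if len(path) == 1:
            return f"{self.root}*"
        return path[1]

    def expected_variants(self, name: str) -> frozenset[Variant]:
        """Accumulated signature variants on the root path of ``name``."""
        if name not in self.nodes:
            raise TreeError(f"unknown haplogroup {name!r}")
        if name in self._expected_cache:
            return self._expected_cache[name]
        acc: dict[tuple[int, int], Variant] = {}
        for node_name in self.root_path(name):
            for token in self.nodes[node_name].signature:
                if token.startswith("@"):
                    pos_text = token[1:].rstrip("ACGTacgt")
                    try:
                        pos = int(pos_text)
                    except ValueError:
                        raise TreeError(
                            f"{node_name!r}: malformed back mutation {token!r}"
                        ) from None
                    if (pos, 0) not in acc:
                        raise TreeError(
                            f"{node_name!r}: back mutation {token!r} reverts "
                            "nothing on the root path"
                        )
                    del acc[(pos, 0)]
                else:
                    try:
                        v = parse_variant(token)
                    except NomenclatureError as e:
                        raise TreeError(f"{node_name!r}: {e}") from None
                    acc[v.key] = v
        result = frozenset(acc.values())
        self._expected_cache[name] = result
        return result

    def mrca(self, names: Sequence[str]) -> str:
        """Deepest node ancestral to (or equal to) every input."""
        if not names:
            raise TreeError("mrca of an empty node list")
        paths = [self.root_path(n) for n in names]
        mrca = self.root
        for level in range(min(len(p) for p in paths)):
            step = {p[level] for p in paths}
            if len(step) != 1:
                break
            mrca = step.pop()
        return mrca

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes


def load_tree(text: str) -> HaplogroupTree:
    return HaplogroupTree.from_text(text)


# ---------------------------------------------------------------------------
# Parsimony assignment


@dataclass(frozen=True)
class Candidate:
    name: str
    cost: float
    missing_signature: tuple[str, ...]
    private_variants: tuple[str, ...]


@dataclass(frozen=True)
class AssignmentResult:
    sample_id: str
    call: str
    mrca_applied: bool
    tie_tolerance: float
    candidates: tuple[Candidate, ...]

    @property
    def best_cost(self) -> float:
        return self.candidates[0].cost


def _effective_site_map(
    h: Haplotype,
    rules: MatchRules,
) -> dict[tuple[int, int], Variant]:
    return {v.key: v for v in comparable_variants(h, rules)}


def _node_cost(
    sites: Mapping[tuple[int, int], Variant],
    expected: frozenset[Variant],
    weights: Mapping[int, float],
    reference: ReferenceGenome,
) -> tuple[float, tuple[str, ...], tuple[str, ...]]:
    exp_map = {v.key: v for v in expected}
    cost = 0.0
    missing: list[str] = []
    private: list[str] = []
    for key, v in sites.items():
        w = weights.get(v.position, 1.0)
        e = exp_map.get(key)
        if e is not None:
            # PHP at a signature np counts as carrying the signature
            if v.components & e.components:
                continue
            cost += w
            private.append(f"{v.position}{v.observed}")
        else:
            if v.heteroplasmic and v.kind == SUBSTITUTION and (
                reference.base_at(v.position) in v.components
            ):
                continue  # PHP around the reference base: no difference
            cost += w
            private.append(
                f"{v.position}{v.observed}" if v.kind == SUBSTITUTION
                else f"{v.position}.{v.insertion_index}{v.observed}"
                if v.kind == "insertion"
                else f"{v.position}DEL"
            )
    for key, e in exp_map.items():
        if key not in sites:
            cost += weights.get(e.position, 1.0)
            missing.append(f"{e.position}{e.observed}")
    return cost, tuple(sorted(missing)), tuple(sorted(private))


def assign_haplogroup(
    h: Haplotype,
    tree: HaplogroupTree,
    weights: Optional[Mapping[int, float]] = None,
    tie_tolerance: float = 0.0,
    rules: MatchRules = DEFAULT_RULES,
    reference: Optional[ReferenceGenome] = None,
    max_candidates: int = 5,
) -> AssignmentResult:
    """Weighted-parsimony placement with MRCA fallback for near ties."""
    if len(tree) == 0:
        raise TreeError("empty haplogroup tree")
    ref = get_reference(reference)
    w = dict(DEFAULT_HOTSPOT_WEIGHTS)
    if weights:
        w.update(weights)
    sites = _effective_site_map(h, rules)
    scored = []
    for name in tree.nodes:
        cost, missing, private = _node_cost(
            sites, tree.expected_variants(name), w, ref
        )
        scored.append(Candidate(name, cost, missing, private))
    scored.sort(key=lambda c: (c.cost, c.name))
    best = scored[0].cost
    tied = [c for c in scored if c.cost <= best + tie_tolerance]
    if len(tied) == 1:
        call, mrca_applied = tied[0].name, False
    else:
        # nested ties (all candidates on one root path, e.g. a PHP at a
        # signature np making H and H1 equally cheap) resolve to the
        # deepest node: the PHP counts as carrying the signature
        deepest = max((c.name for c in tied), key=tree.depth)
        chain = set(tree.root_path(deepest))
        if all(c.name in chain for c in tied):
            call, mrca_applied = deepest, False
        else:
            call, mrca_applied = tree.mrca([c.name for c in tied]), True
    return AssignmentResult(
        sample_id=h.sample_id,
        call=call,
        mrca_applied=mrca_applied,
        tie_tolerance=tie_tolerance,
        candidates=tuple(scored[:max_candidates]),
    )


# ---------------------------------------------------------------------------
# Rapid 3-SNP panel (H1/H3/H7)

#: Diagnostic coding-region markers: derived allele -> class.
PANEL_MARKERS: Mapping[int, str] = {3010: "A", 6776: "C", 4793: "G"}
PANEL_CLASSES: Mapping[int, str] = {3010: "H1", 6776: "H3", 4793: "H7"}


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class PanelCall:
    sample_id: str
    label: str  # H1 | H3 | H7 | other
    conflict: bool = False  # more than one marker derived


def rapid_panel_classify(
    h: Haplotype, rules: MatchRules = DEFAULT_RULES
) -> PanelCall:
    """Classify one sample by the three diagnostic markers.

    A PHP containing the derived allele counts as derived.
    """
    derived = []
    for pos, allele in PANEL_MARKERS.items():
        if not h.covers(pos):
            raise PanelError(
                f"{h.sample_id}: declared range {h.range_string} lacks "
                f"panel np {pos}"
            )
        v = h.variant_at(pos)
        if v is not None and v.kind == SUBSTITUTION and allele in v.components:
            derived.append(pos)
    if not derived:
        return PanelCall(h.sample_id, "other")
    label = PANEL_CLASSES[derived[0]]
    return PanelCall(h.sample_id, label, conflict=len(derived) > 1)


def evaluate_panel(
    hs: Sequence[Haplotype], rules: MatchRules = DEFAULT_RULES
):
    """Forensic parameters of the 4-class panel partition."""
    from .matching import IdentityPartition, Scenario
    from .stats import forensic_params

    calls = [rapid_panel_classify(h, rules) for h in hs]
    conflicts = [c.sample_id for c in calls if c.conflict]
    if conflicts:
        raise PanelError(
            f"samples with more than one derived marker: {conflicts}"
        )
    groups: dict[str, list[str]] = {}
    for c in calls:
        groups.setdefault(c.label, []).append(c.sample_id)
    partition = IdentityPartition(
        groups=list(groups.values()),
        scenario=Scenario.DOUBLE_MATCH,
        N=len(hs),
    )
    return forensic_params(partition)


def first_level_summary(
    assignments: Mapping[str, str] | Sequence[AssignmentResult],
    tree: HaplogroupTree,
    N: Optional[int] = None,
) -> pd.DataFrame:
    """Counts and percentages by first-level subhaplogroup.

    Terminal calls aggregate to their depth-1 ancestor; calls to the root
    itself form the paragroup (e.g. ``H*``).
    """
    if not isinstance(assignments, Mapping):
        assignments = {a.sample_id: a.call for a in assignments}
    N = N if N is not None else len(assignments)
    counts: dict[str, int] = {}
    for call in assignments.values():
        level = tree.first_level(call)
        counts[level] = counts.get(level, 0) + 1
    from .stats import as_percent

    rows = [
        {
            "first_level": name,
            "n": n,
            "percent": as_percent(n / N),
        }
        for name, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)
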
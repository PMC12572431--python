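"""Lung ultrasound finding hierarchy, named label sets and exclusivity rules.

Seven findings are annotated at the video level: two compatible with a
normal lung (scattering-only, A-lines) and five on the pathology side
(<3 B-lines, >=3 B-lines, coalescent B-lines, consolidation, pleural
effusion).  They form a tree::

    root
    |- Normal finding          -> Scattering-only, A-lines
    `- Indicative finding
       |- Non-pathological     -> <3 B-lines
       `- Pathological
          |- B positive        -> >=3 B-lines, Coalescent B-lines
          `- Other pathologies -> Consolidation, Pleural effusion

Named label sets (mlS1..mlS4 multi-label, cLS1..cLS4 categorical) pick a
frontier of this tree: a set either contains a high-level node or *all*
leaves beneath it, never a partial subset.  Exclusivity rules: the
normal-side and pathology-side findings are mutually exclusive, and the
three B-line findings are pairwise exclusive; the "Other pathologies"
leaves may coexist with any B-line finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

# Canonical finding / category names (printed order preserved everywhere).
SCATTERING = "Scattering-only"
A_LINES = "A-lines"
LT3_BLINES = "<3 B-lines"
GE3_BLINES = "≥3 B-lines"
COALESCENT = "Coalescent B-lines"
CONSOLIDATION = "Consolidation"
EFFUSION = "Pleural effusion"

NORMAL = "Normal finding"
INDICATIVE = "Indicative finding"
NON_PATHOLOGICAL = "Non-pathological"
PATHOLOGICAL = "Pathological"
B_POSITIVE = "B positive"
OTHER_PATHOLOGIES = "Other pathologies"

FINDINGS = (SCATTERING, A_LINES, LT3_BLINES, GE3_BLINES, COALESCENT,
            CONSOLIDATION, EFFUSION)
NORMAL_FINDINGS = (SCATTERING, A_LINES)
PATHOLOGY_FINDINGS = (LT3_BLINES, GE3_BLINES, COALESCENT, CONSOLIDATION, EFFUSION)
B_LINE_FINDINGS = (LT3_BLINES, GE3_BLINES, COALESCENT)


class LabelError(ValueError):
    """Raised for unknown labels, malformed sets or incompatible mappings."""


@dataclass
class LabelNode:
    name: str
    children: list["LabelNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class LabelHierarchy:
    """A finding tree with name lookup and leaf expansion."""

    def __init__(self, root: LabelNode):
        self.root = root
        self._by_name: dict[str, LabelNode] = {}
        self._index(root)

    def _index(self, node: LabelNode) -> None:
        if node.name in self._by_name:
            raise LabelError(f"duplicate node name {node.name!r}")
        self._by_name[node.name] = node
        for c in node.children:
            self._index(c)

    def node(self, name: str) -> LabelNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise LabelError(f"unknown label {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def leaves(self, name: str | None = None) -> tuple[str, ...]:
        """Leaf finding names beneath (or equal to) ``name``; whole tree if None."""
        node = self.root if name is None else self.node(name)
        out: list[str] = []

        def walk(n: LabelNode) -> None:
            if n.is_leaf:
                out.append(n.name)
            for c in n.children:
                walk(c)

        walk(node)
        return tuple(out)

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is a strict ancestor of ``b``."""
        if a == b:
            return False
        return set(self.leaves(b)) <= set(self.leaves(a))

    def to_dict(self) -> dict:
        def conv(n: LabelNode) -> dict:
            d: dict = {"name": n.name}
            if n.children:
                d["children"] = [conv(c) for c in n.children]
            return d

        return conv(self.root)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LabelHierarchy":
        def conv(e: Mapping) -> LabelNode:
            return LabelNode(e["name"], [conv(c) for c in e.get("children", [])])

        return cls(conv(d))


def build_default_hierarchy() -> LabelHierarchy:
    """The fixed finding tree used throughout (7 leaves)."""
    root = LabelNode("root", [
        LabelNode(NORMAL, [LabelNode(SCATTERING), LabelNode(A_LINES)]),
        LabelNode(INDICATIVE, [
            LabelNode(NON_PATHOLOGICAL, [LabelNode(LT3_BLINES)]),
            LabelNode(PATHOLOGICAL, [
                LabelNode(B_POSITIVE, [LabelNode(GE3_BLINES), LabelNode(COALESCENT)]),
                LabelNode(OTHER_PATHOLOGIES, [LabelNode(CONSOLIDATION), LabelNode(EFFUSION)]),
            ]),
        ]),
    ])
    return LabelHierarchy(root)


@dataclass(frozen=True)
class LabelSet:
    """An ordered frontier of the hierarchy with a prediction mode."""

    name: str
    labels: tuple[str, ...]
    mode: str  # "categorical" | "multi-label"

    def __post_init__(self) -> None:
        if self.mode not in ("categorical", "multi-label"):
            raise LabelError(f"unknown mode {self.mode!r}")
        if len(set(self.labels)) != len(self.labels):
            raise LabelError("duplicate labels in set")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def validate_against(self, h: LabelHierarchy) -> None:
        for lab in self.labels:
            if lab not in h:
                raise LabelError(f"label {lab!r} not in hierarchy")
        for a in self.labels:
            for b in self.labels:
                if a != b and h.is_ancestor(a, b):
                    raise LabelError(f"{a!r} is an ancestor of {b!r} within one set")
        # frontier rule: a high-level node or ALL leaves beneath it
        covered = [leaf for lab in self.labels for leaf in h.leaves(lab)]
        if len(covered) != len(set(covered)):
            raise LabelError("labels overlap in leaf coverage")


_LABEL_SETS: dict[str, LabelSet] = {
    "mlS1": LabelSet("mlS1", (SCATTERING, A_LINES, LT3_BLINES, B_POSITIVE,
                              OTHER_PATHOLOGIES), "multi-label"),
    "mlS2": LabelSet("mlS2", (SCATTERING, A_LINES, LT3_BLINES, B_POSITIVE,
                              CONSOLIDATION, EFFUSION), "multi-label"),
    "mlS3": LabelSet("mlS3", (SCATTERING, A_LINES, LT3_BLINES, GE3_BLINES,
                              COALESCENT, OTHER_PATHOLOGIES), "multi-label"),
    "mlS4": LabelSet("mlS4", FINDINGS, "multi-label"),
    "cLS1": LabelSet("cLS1", (NORMAL, INDICATIVE), "categorical"),
    "cLS2": LabelSet("cLS2", (NORMAL, NON_PATHOLOGICAL, PATHOLOGICAL), "categorical"),
    "cLS3": LabelSet("cLS3", (SCATTERING, A_LINES, INDICATIVE), "categorical"),
    "cLS4": LabelSet("cLS4", (SCATTERING, A_LINES, NON_PATHOLOGICAL,
                              PATHOLOGICAL), "categorical"),
}

LABEL_SET_NAMES = tuple(_LABEL_SETS)


def resolve_label_set(name: str) -> LabelSet:
    """Look up one of the eight named label sets (mlS1..4, cLS1..4)."""
    try:
        return _LABEL_SETS[name]
    except KeyError:
        raise LabelError(f"unknown label set {name!r}") from None


@dataclass
class LabelVector:
    """Per-label values aligned to a :class:`LabelSet` plus reliability bits."""

    values: np.ndarray
    label_set: LabelSet
    reliability: np.ndarray | None = None  # g in {0,1}; None means all-reliable

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.label_set),):
            raise LabelError(
                f"vector of length {self.values.size} misaligned with "
                f"{self.label_set.name} ({len(self.label_set)} labels)")
        if self.reliability is None:
            self.reliability = np.ones(len(self.label_set), dtype=np.int8)
        else:
            self.reliability = np.asarray(self.reliability, dtype=np.int8)
            if self.reliability.shape != self.values.shape:
                raise LabelError("reliability misaligned with values")

    @property
    def is_hard(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))

    def positives(self) -> tuple[str, ...]:
        return tuple(l for l, v in zip(self.label_set.labels, self.values) if v == 1)

    @classmethod
    def from_positives(cls, label_set: LabelSet, positives: Iterable[str]) -> "LabelVector":
        v = np.zeros(len(label_set))
        for p in positives:
            v[label_set.index(p)] = 1.0
        return cls(v, label_set)


@dataclass(frozen=True)
class ConstraintSet:
    """Mutual-exclusivity groups over leaf findings (at most one active each)."""

    groups: tuple[frozenset[str], ...]

    @classmethod
    def default(cls) -> "ConstraintSet":
        groups = [frozenset({n, p}) for n in NORMAL_FINDINGS for p in PATHOLOGY_FINDINGS]
        groups += [frozenset({a, b})
                   for i, a in enumerate(B_LINE_FINDINGS)
                   for b in B_LINE_FINDINGS[i + 1:]]
        return cls(tuple(groups))


@dataclass
class ValidityReport:
    valid: bool
    violations: list[tuple[str, str]]  # pairs of co-positive labels in conflict
    empty: bool
    not_one_hot: bool = False

    def __bool__(self) -> bool:
        return self.valid


def validate_label_vector(v: LabelVector, label_set: LabelSet | None = None,
                          constraints: ConstraintSet | None = None,
                          hierarchy: LabelHierarchy | None = None) -> ValidityReport:
    """Check a hard label vector against the exclusivity rules.

    A pair of positive labels violates a group when both labels'
    leaf expansions intersect that group (so a single high-level label
    such as "B positive" never conflicts with itself).
    """
    label_set = label_set or v.label_set
    if label_set is not v.label_set and label_set.labels != v.label_set.labels:
        raise LabelError("vector is not aligned to the given label set")
    constraints = constraints or ConstraintSet.default()
    hierarchy = hierarchy or build_default_hierarchy()

    pos = v.positives()
    leafsets = {p: set(hierarchy.leaves(p)) for p in pos}
    violations: list[tuple[str, str]] = []
    for i, a in enumerate(pos):
        for b in pos[i + 1:]:
            for grp in constraints.groups:
                if leafsets[a] & grp and leafsets[b] & grp and \
                        (leafsets[a] & grp) != (leafsets[b] & grp):
                    violations.append((a, b))
                    break
    not_one_hot = False
    if label_set.mode == "categorical" and v.is_hard:
        not_one_hot = int(np.sum(v.values)) != 1
    empty = len(pos) == 0
    return ValidityReport(valid=not violations and not not_one_hot,
                          violations=violations, empty=empty,
                          not_one_hot=not_one_hot)


def low_to_high_map(source: LabelSet, target: LabelSet,
                    hierarchy: LabelHierarchy | None = None) -> dict[str, tuple[str, ...]]:
    """Map each target label to the source labels beneath-or-equal-to it.

    Source and target must cover the same finding categories: every
    target label is either present verbatim in the source or is covered
    *exactly* by a set of source labels.  Every source label must be
    used; partial category coverage raises :class:`LabelError`.
    """
    hierarchy = hierarchy or build_default_hierarchy()
    mapping: dict[str, tuple[str, ...]] = {}
    used: list[str] = []
    for t in target.labels:
        if t in source.labels:
            mapping[t] = (t,)
            used.append(t)
            continue
        t_leaves = set(hierarchy.leaves(t))
        srcs = tuple(s for s in source.labels
                     if set(hierarchy.leaves(s)) <= t_leaves)
        covered = set().union(*(set(hierarchy.leaves(s)) for s in srcs)) if srcs else set()
        if not srcs or covered != t_leaves:
            raise LabelError(
                f"cannot express target label {t!r} from source set {source.name}")
        mapping[t] = srcs
        used.extend(srcs)
    if set(used) != set(source.labels) or len(used) != len(source.labels):
        raise LabelError(
            f"source {source.name} has labels outside target {target.name} coverage")
    return mapping


# ---------------------------------------------------------------------------
# YAML serialization (labels.yaml schema)

def labels_to_yaml(hierarchy: LabelHierarchy | None = None,
                   sets: Mapping[str, LabelSet] | None = None,
                   constraints: ConstraintSet | None = None) -> str:
    hierarchy = hierarchy or build_default_hierarchy()
    sets = dict(sets or _LABEL_SETS)
    constraints = constraints or ConstraintSet.default()
    doc = {
        "hierarchy": hierarchy.to_dict(),
        "label_sets": {n: {"labels": list(s.labels), "mode": s.mode}
                       for n, s in sets.items()},
        "exclusive_groups": [sorted(g) for g in constraints.groups],
    }
    return yaml.safe_dump(doc, allow_unicode=True, sort_keys=False)


def labels_from_yaml(text: str) -> tuple[LabelHierarchy, dict[str, LabelSet], ConstraintSet]:
    doc = yaml.safe_load(text)
    h = LabelHierarchy.from_dict(doc["hierarchy"])
    sets = {n: LabelSet(n, tuple(d["labels"]), d["mode"])
            for n, d in doc.get("label_sets", {}).items()}
    for s in sets.values():
        s.validate_against(h)
    cs = ConstraintSet(tuple(frozenset(g) for g in doc.get("exclusive_groups", [])))
    return h, sets, cs
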
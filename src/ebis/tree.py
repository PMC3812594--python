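"""Hierarchical threshold-tree classification of hemisphere feature vectors.

The classifier is a fixed chain of single-feature threshold nodes.  At each
non-final node, records on the node's *exit* side of the threshold receive
that node's label and leave the tree; the rest continue.  The final node is a
split: it labels both sides.  The default three-node tree is:

    node 1: f2 < 1.01  -> exit "healthy"   (symmetric high-frequency ratio)
    node 2: f3 < 0.4   -> exit "damaged"   (collapsed mid-band phase ratio)
    node 3: f1 < 0.9   -> "damaged", else "healthy"

Ties (value exactly equal to a threshold) always continue to the next node;
at the final node a tie goes to the *above* side.  Besides classification,
`tune_thresholds` re-derives the thresholds from labelled training data while
keeping the tree skeleton (feature order, directions, exit labels) fixed —
the form of calibration used inside cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import TuningError, ValidationError
from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "NodeSpec",
    "TreeSpec",
    "ClassificationOutcome",
    "BatchCounts",
    "default_tree",
    "classify",
    "classify_batch",
    "tune_thresholds",
]

LABELS = ("healthy", "damaged")
DIRECTIONS = ("below", "above")


@dataclass(frozen=True)
class NodeSpec:
    """One threshold node: which feature, where the cut sits, which side exits."""

    feature: str
    threshold: float
    direction: str  # side that exits: "below" | "above"
    exit_label: str

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ValidationError(f"unknown feature {self.feature!r}")
        if not (self.threshold > 0.0):
            raise ValidationError(f"threshold must be > 0, got {self.threshold}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}")
        if self.exit_label not in LABELS:
            raise ValidationError(f"exit_label must be one of {LABELS}")

    def exits(self, value: float) -> bool:
        """Whether a record with this feature value leaves at this node.

        Exits are strict inequalities; a value exactly on the threshold
        continues down the tree.
        """
        if self.direction == "below":
            return value < self.threshold
        return value > self.threshold


@dataclass(frozen=True)
class TreeSpec:
    """An ordered chain of threshold nodes plus the final split's two labels.

    ``nodes[:-1]`` are filter nodes (one exit side each); ``nodes[-1]`` is
    the final split, whose below/above sides receive ``final_below`` and
    ``final_above``.  The last node's own direction/exit_label are kept
    consistent with ``final_below`` for serialisation but the final mapping
    is authoritative.
    """

    nodes: Tuple[NodeSpec, ...]
    final_below: str = "damaged"
    final_above: str = "healthy"

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise ValidationError("tree must have at least one node")
        if self.final_below not in LABELS or self.final_above not in LABELS:
            raise ValidationError(f"final labels must be one of {LABELS}")
        object.__setattr__(self, "nodes", tuple(self.nodes))

    @property
    def final_node(self) -> NodeSpec:
        return self.nodes[-1]

    def with_thresholds(self, thresholds: Sequence[float]) -> "TreeSpec":
        if len(thresholds) != len(self.nodes):
            raise ValidationError("one threshold per node required")
        new_nodes = tuple(
            replace(n, threshold=float(t)) for n, t in zip(self.nodes, thresholds)
        )
        return replace(self, nodes=new_nodes)


def default_tree() -> TreeSpec:
    """The default three-node tree (f2 at 1.01, then f3 at 0.4, then f1 at 0.9)."""
    return TreeSpec(
        nodes=(
            NodeSpec("f2", 1.01, "below", "healthy"),
            NodeSpec("f3", 0.40, "below", "damaged"),
            NodeSpec("f1", 0.90, "below", "damaged"),
        ),
        final_below="damaged",
        final_above="healthy",
    )


@dataclass(frozen=True)
class ClassificationOutcome:
    """Where one record landed: a leaf identifier and its predicted label.

    Leaf ids are "node<i>-below" / "node<i>-above" with 1-based node numbers;
    in the default tree the final split's leaves (node3-below damaged,
    node3-above healthy) play the roles conventionally drawn as the two
    terminal leaves of the diagram.
    """

    leaf_id: str
    predicted_label: str


@dataclass
class BatchCounts:
    """Per-node bookkeeping for a classified batch: arrivals and departures."""

    reached: Dict[int, int]  # node number (1-based) -> records arriving
    exited: Dict[int, int]  # node number -> records leaving at that node
    leaves: Dict[str, int]  # leaf_id -> records

    @property
    def total(self) -> int:
        return sum(self.leaves.values())


def classify(v: FeatureVector, tree: TreeSpec) -> ClassificationOutcome:
    """Run one feature vector through the tree; every vector reaches one leaf."""
    for i, node in enumerate(tree.nodes[:-1], start=1):
        if node.exits(v.value(node.feature)):
            return ClassificationOutcome(
                leaf_id=f"node{i}-{node.direction}", predicted_label=node.exit_label
            )
    n = len(tree.nodes)
    final = tree.final_node
    if v.value(final.feature) < final.threshold:
        return ClassificationOutcome(
            leaf_id=f"node{n}-below", predicted_label=tree.final_below
        )
    return ClassificationOutcome(
        leaf_id=f"node{n}-above", predicted_label=tree.final_above
    )


def classify_batch(
    vs: Sequence[FeatureVector], tree: TreeSpec
) -> Tuple[List[ClassificationOutcome], BatchCounts]:
    """Classify a batch, preserving order, with per-node arrival/exit counts.

    Leaf counts always partition the batch: they sum to ``len(vs)``.
    """
    if len(vs) == 0:
        raise ValidationError("classify_batch requires a non-empty batch")
    n = len(tree.nodes)
    counts = BatchCounts(
        reached={i: 0 for i in range(1, n + 1)},
        exited={i: 0 for i in range(1, n + 1)},
        leaves={},
    )
    outcomes: List[ClassificationOutcome] = []
    for v in vs:
        depth = 1
        for node in tree.nodes[:-1]:
            counts.reached[depth] += 1
            if node.exits(v.value(node.feature)):
                break
            depth += 1
        else:
            counts.reached[n] += 1
        out = classify(v, tree)
        exited_at = int(out.leaf_id.split("-")[0][4:])
        counts.exited[exited_at] += 1
        counts.leaves[out.leaf_id] = counts.leaves.get(out.leaf_id, 0) + 1
        outcomes.append(out)
    return outcomes, counts


def _other_label(label: str) -> str:
    return LABELS[1] if label == LABELS[0] else LABELS[0]


def _candidate_thresholds(values: Sequence[float]) -> List[float]:
    """Midpoints between consecutive distinct sorted values."""
    uniq = sorted(set(values))
    return [(a + b) / 2.0 for a, b in zip(uniq, uniq[1:])]


def _stump_cost(
    node: NodeSpec, threshold: float, records: Sequence[FeatureVector], exit_label: str
) -> int:
    """Misclassifications if the tree ended at this node with this threshold.

    Records on the exit side are labelled ``exit_label``; records on the
    continue side are scored as the complementary label.
    """
    probe = replace(node, threshold=threshold)
    other = _other_label(exit_label)
    cost = 0
    for r in records:
        if probe.exits(r.value(node.feature)):
            cost += r.label != exit_label
        else:
            cost += r.label != other
    return cost


def _final_cost(
    node: NodeSpec,
    threshold: float,
    records: Sequence[FeatureVector],
    below: str,
    above: str,
) -> int:
    cost = 0
    for r in records:
        side = below if r.value(node.feature) < threshold else above
        cost += r.label != side
    return cost


def tune_thresholds(
    training: Sequence[FeatureVector], skeleton: TreeSpec
) -> TreeSpec:
    """Re-derive node thresholds from labelled data on a fixed skeleton.

    Nodes are tuned greedily in order.  For each node, candidate thresholds
    are the midpoints between consecutive sorted training values of the
    node's feature; the candidate minimising the misclassification count of
    the node viewed as a one-feature stump is chosen, ties broken towards
    the skeleton's default threshold and then towards the smaller candidate.
    A node whose remaining records are single-class (or absent) carries no
    information about its cut and keeps the skeleton default.  Records
    exiting at the tuned node are removed before tuning the next one.
    Deterministic throughout.
    """
    labels = {r.label for r in training}
    if None in labels:
        raise TuningError("all training records must carry a label")
    if len(labels) < 2:
        raise TuningError(
            f"training set contains a single class {labels}; cannot tune"
        )

    remaining = list(training)
    thresholds: List[float] = []
    for i, node in enumerate(skeleton.nodes):
        is_final = i == len(skeleton.nodes) - 1
        if len({r.label for r in remaining}) < 2:
            cands = [node.threshold]
        else:
            cands = _candidate_thresholds([r.value(node.feature) for r in remaining])
            if not cands:
                cands = [node.threshold]
        best: Optional[Tuple[int, float, float]] = None  # (cost, |cand-default|, cand)
        for cand in cands:
            if is_final:
                cost = _final_cost(
                    node, cand, remaining, skeleton.final_below, skeleton.final_above
                )
            else:
                cost = _stump_cost(node, cand, remaining, node.exit_label)
            key = (cost, abs(cand - node.threshold), cand)
            if best is None or key < best:
                best = key
        assert best is not None
        chosen = best[2]
        thresholds.append(chosen)
        if not is_final:
            probe = replace(node, threshold=chosen)
            remaining = [r for r in remaining if not probe.exits(r.value(node.feature))]
    return skeleton.with_thresholds(thresholds)
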
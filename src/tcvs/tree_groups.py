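"""Taxonomic-tree group structures for tree-guided penalties.

A taxonomic tree over ``p`` leaf taxa induces, for every internal node
``v``, a membership indicator vector ``m_v`` in {0,1}^p marking the leaves
of the subtree rooted at ``v``.  The collection of these leaf sets is a
laminar family (any two are nested or disjoint), which is what makes the
exact leaf-to-root hierarchical proximal operator in :mod:`tcvs.solver`
valid.  Each group carries the weight ``|L_v| = ||m_v||_1`` used as the
divisor of its group-norm penalty term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaxonomicTree",
    "Group",
    "GroupStructure",
    "AugmentedGroupStructure",
    "build_groups",
    "augment_groups",
    "group_penalty_value",
]


@dataclass
class TaxonomicTree:
    """A rooted hierarchy over ordered leaf taxa.

    Parameters
    ----------
    leaves
        Ordered leaf (taxon) identifiers; position defines the column
        index in count/CLR matrices.
    internal_nodes
        Mapping from internal-node identifier (e.g. a lineage prefix such
        as ``"Firmicutes;Clostridia"``) to the frozenset of leaf *indices*
        (0-based) in its subtree.  Must include the root (all leaves).
    ranks
        Optional mapping from internal-node id to its depth (root = 0);
        used to attribute collapsed unary chains to the deepest rank.
    """

    leaves: list[str]
    internal_nodes: dict[str, frozenset[int]]
    ranks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.leaves)
        if len(set(self.leaves)) != p:
            raise ValueError("duplicate leaf identifiers in tree")
        all_idx = frozenset(range(p))
        for node, members in self.internal_nodes.items():
            if not members:
                raise ValueError(f"internal node {node!r} has an empty leaf set")
            if not members <= all_idx:
                raise ValueError(f"internal node {node!r} references unknown leaf indices")
        if all_idx not in self.internal_nodes.values():
            raise ValueError("tree must contain a root node covering every leaf")
        self._check_laminar()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def _check_laminar(self) -> None:
        sets = list(self.internal_nodes.items())
        for i, (ni, si) in enumerate(sets):
            for nj, sj in sets[i + 1 :]:
                inter = si & sj
                if inter and not (si <= sj or sj <= si):
                    raise ValueError(
                        f"leaf sets of {ni!r} and {nj!r} overlap without nesting; "
                        "tree groups must form a laminar family"
                    )

    def leaf_index(self, label: str) -> int:
        return self.leaves.index(label)


@dataclass(frozen=True)
class Group:
    """One penalty group: internal node id, membership vector, L1 weight."""

    node: str
    members: np.ndarray  # bool mask over coefficient dimension
    weight: int

    def __post_init__(self) -> None:
        if int(self.members.sum()) != self.weight:
            raise ValueError("group weight must equal the membership count")
        if self.weight == 0:
            raise ValueError("empty group")


@dataclass
class GroupStructure:
    """Groups over the original p coefficients."""

    groups: list[Group]
    p: int

    def __post_init__(self) -> None:
        seen: set[bytes] = set()
        for g in self.groups:
            if g.members.shape != (self.p,):
                raise ValueError("membership dimension mismatch")
            key = np.packbits(g.members).tobytes()
            if key in seen:
                raise ValueError(f"duplicate membership vector at node {g.node!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.groups)

    def member_indices(self) -> list[np.ndarray]:
        """Integer index arrays per group, cached (groups are immutable)."""
        cache = getattr(self, "_member_idx", None)
        if cache is None:
            cache = [np.flatnonzero(g.members) for g in self.groups]
            self._member_idx = cache
        return cache

    def to_json(self, tree: TaxonomicTree | None = None) -> str:
        """Serialize groups for audit output (node id, member leaf ids)."""
        records = []
        for g in self.groups:
            idx = np.flatnonzero(g.members)
            rec: dict = {"node": g.node, "weight": g.weight}
            rec["members"] = (
                [tree.leaves[i] for i in idx if i < len(tree.leaves)]
                if tree is not None
                else idx.tolist()
            )
            records.append(rec)
        return json.dumps(records, indent=2)


@dataclass
class AugmentedGroupStructure(GroupStructure):
    """Groups over the stacked (beta, beta_tilde) coefficient vector.

    Each membership vector spans 2p coordinates with the original pattern
    duplicated on the knockoff half, so a group norm couples a subtree's
    original and knockoff coefficients.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        half = self.p // 2
        for g in self.groups:
            if not np.array_equal(g.members[:half], g.members[half:]):
                raise ValueError("augmented membership must duplicate the original half")


def _sorted_unique_groups(
    node_sets: dict[str, frozenset[int]], ranks: dict[str, int]
) -> list[tuple[str, frozenset[int]]]:
    """Collapse duplicate leaf sets (unary chains), keeping the deepest rank."""
    by_set: dict[frozenset[int], str] = {}
    for node, members in node_sets.items():
        prev = by_set.get(members)
        if prev is None or ranks.get(node, 0) > ranks.get(prev, 0):
            by_set[members] = node
    # deterministic order: by (size, sorted member tuple)
    items = sorted(by_set.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    return [(node, members) for members, node in items]


def build_groups(tree: TaxonomicTree, include_root: bool = True) -> GroupStructure:
    """Build one penalty group per (deduplicated) internal node.

    Unary taxonomic chains — distinct internal nodes with identical leaf
    sets — collapse to a single group attributed to the deepest rank,
    since duplicated groups would silently multiply the penalty weight.
    ``include_root=False`` drops the all-leaves group, removing the global
    shrinkage it contributes.
    """
    p = tree.n_leaves
    node_sets = dict(tree.internal_nodes)
    if not include_root:
        root = frozenset(range(p))
        node_sets = {k: v for k, v in node_sets.items() if v != root}
        if not node_sets:
            raise ValueError(
                "no internal nodes remain with include_root=False; the tree penalty "
                "degenerates to a plain lasso — use the classo variant explicitly"
            )
    groups = []
    for node, members in _sorted_unique_groups(node_sets, tree.ranks):
        mask = np.zeros(p, dtype=bool)
        mask[list(members)] = True
        groups.append(Group(node=node, members=mask, weight=len(members)))
    return GroupStructure(groups=groups, p=p)


def augment_groups(gs: GroupStructure) -> AugmentedGroupStructure:
    """Duplicate each membership vector over the knockoff coordinates p+1..2p."""
    if isinstance(gs, AugmentedGroupStructure):
        raise ValueError("group structure is already augmented")
    groups = [
        Group(node=g.node, members=np.concatenate([g.members, g.members]), weight=2 * g.weight)
        for g in gs.groups
    ]
    return AugmentedGroupStructure(groups=groups, p=2 * gs.p)


def group_penalty_value(beta: np.ndarray, gs: GroupStructure) -> float:
    """Tree penalty sum_v ||beta o m_v||_2 / ||m_v||_1 (size-weighted divisor)."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (gs.p,):
        raise ValueError(f"beta has length {beta.shape}, expected ({gs.p},)")
    return float(
        sum(np.linalg.norm(beta[g.members]) / g.weight for g in gs.groups)
    )
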
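import numpy as np
import pytest

from tcvs.tree_groups import Group, GroupStructure, TaxonomicTree


@pytest.fixture
def toy_tree() -> TaxonomicTree:
    """((1,2),(3,4)) with an explicit root."""
    return TaxonomicTree(
        leaves=["A", "B", "C", "D"],
        internal_nodes={
            "left": frozenset({0, 1}),
            "right": frozenset({2, 3}),
            "root": frozenset({0, 1, 2, 3}),
        },
        ranks={"root": 0, "left": 1, "right": 1},
    )


def make_group_structure(p: int, index_sets: list[list[int]]) -> GroupStructure:
    groups = []
    for i, idx in enumerate(index_sets):
        mask = np.zeros(p, dtype=bool)
        mask[idx] = True
        groups.append(Group(node=f"g{i}", members=mask, weight=len(idx)))
    return GroupStructure(groups=groups, p=p)


def random_laminar_indices(p: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random laminar family over 0..p-1 (always includes the root set)."""
    out = [np.arange(p)]

    def rec(idx: np.ndarray) -> None:
        if len(idx) <= 2 or rng.random() < 0.3:
            return
        k = int(rng.integers(1, len(idx)))
        for part in (idx[:k], idx[k:]):
            if len(part) >= 2 and rng.random() < 0.8:
                out.append(part)
                rec(part)

    rec(np.arange(p))
    seen, dedup = set(), []
    for g in out:
        key = tuple(g.tolist())
        if key not in seen:
            seen.add(key)
            dedup.append(np.asarray(g))
    return dedup
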
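"""Patristic-distance helpers shared by alpha and null-model code."""

from __future__ import annotations

import numpy as np
from skbio import TreeNode


def patristic_matrix(tree: TreeNode, taxa_order: list[str]) -> np.ndarray:
    """Dense tip-to-tip patristic distance matrix in ``taxa_order``.

    All requested taxa must be tips of the tree.
    """
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa_order if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}")
    dm = tree.tip_tip_distances(endpoints=list(taxa_order))
    # skbio preserves the endpoint order it was given
    assert list(dm.ids) == list(taxa_order)
    return np.asarray(dm.data, dtype=float)
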
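import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from phyloassembly.io import CountTable


def make_table(counts, taxa=None, samples=None) -> CountTable:
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i + 1}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(counts.shape[1])]
    return CountTable(pd.DataFrame(counts, index=taxa, columns=samples))


@pytest.fixture
def balanced4_tree() -> TreeNode:
    """Two cherries separated by long stems: ((A,B),(C,D))."""
    return TreeNode.read(["((A:1,B:1):5,(C:1,D:1):5);"])


@pytest.fixture
def three_tip_tree() -> TreeNode:
    return TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def six_tip_tree() -> TreeNode:
    return TreeNode.read(["(((A:1,B:2):1,(C:1,D:3):2):1,(E:2,F:1):3);"])
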
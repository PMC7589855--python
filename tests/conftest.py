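import pandas as pd
import pytest

import nutriscreen as ns
from nutriscreen import preprocess


@pytest.fixture(scope="session")
def fixture_data():
    """Packaged 27-extract study dataset: (table, metadata, expected latents)."""
    return ns.paper_fixture()


@pytest.fixture(scope="session")
def table(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def expected_latents(fixture_data):
    return fixture_data[2]


@pytest.fixture(scope="session")
def expected_categorical(expected_latents) -> ns.CategoricalTable:
    """Categorical table carrying the published level assignments."""
    return ns.build_categorical_table(expected_latents)


def _zscores(table, var_set):
    sel = preprocess.select_variables(table, var_set)
    return preprocess.standardize(preprocess.resolve_missing(sel, "zero"))


@pytest.fixture(scope="session")
def zscores(table) -> dict[str, pd.DataFrame]:
    """Standardized matrices per variable set (zero missing policy)."""
    return {vs: _zscores(table, vs) for vs in ("composition", "gastric", "intestinal")}


@pytest.fixture(scope="session")
def zscores_full(zscores) -> pd.DataFrame:
    return pd.concat([zscores[vs] for vs in ("composition", "gastric", "intestinal")], axis=1)


def node_leaf_sets(tree: ns.VariableTree) -> list[frozenset]:
    """Leaf set of every internal node of an agglomerative tree."""
    n = tree.n_leaves
    sets: dict[int, frozenset] = {i: frozenset([tree.labels[i]]) for i in range(n)}
    out = []
    for i, (left, right, _h, _s) in enumerate(tree.merges):
        sets[n + i] = sets[int(left)] | sets[int(right)]
        out.append(sets[n + i])
    return out
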
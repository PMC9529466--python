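from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from famnet.pedigree import Individual, Pedigree


@pytest.fixture
def nuclear_family() -> Pedigree:
    """Two parents (father BAP), two ASD boys, one NT girl."""
    fid = "1"
    members = [
        Individual("FA", fid, sex="male", phenotype="BAP"),
        Individual("MO", fid, sex="female", phenotype="NT"),
        Individual("C1", fid, father_id="FA", mother_id="MO", sex="male", phenotype="ASD"),
        Individual("C2", fid, father_id="FA", mother_id="MO", sex="male", phenotype="ASD"),
        Individual("C3", fid, father_id="FA", mother_id="MO", sex="female", phenotype="NT"),
    ]
    ped = Pedigree({fid: members})
    ped.validate()
    return ped


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def set_partitions(items: list):
    """All set partitions of ``items`` via restricted growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    codes = [0] * n

    def rec(i: int, maxc: int):
        if i == n:
            groups: dict[int, list] = {}
            for item, c in zip(items, codes):
                groups.setdefault(c, []).append(item)
            yield list(groups.values())
            return
        for c in range(maxc + 2):
            codes[i] = c
            yield from rec(i + 1, max(maxc, c))

    yield from rec(1, 0)


def best_partition_exhaustive(g: nx.Graph):
    """Global modularity optimum by scanning every set partition (tiny n)."""
    from famnet.walktrap import modularity

    best_q, best = -np.inf, None
    for groups in set_partitions(sorted(g.nodes)):
        assignment = {n: i for i, grp in enumerate(groups) for n in grp}
        q = modularity(g, assignment)
        if q > best_q:
            best_q, best = q, assignment
    return best_q, best


def partition_labels(assignment: dict, nodes: list) -> list:
    return [assignment[n] for n in nodes]
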
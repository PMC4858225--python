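"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from isoshift.orf import annotate_transcripts, annotations_to_frame
from isoshift.simulate import ScenarioConfig, simulate_scenario
from isoshift.transcripts import TranscriptModel


# ---------------------------------------------------------------- oracles

def brute_force_ptc(t: TranscriptModel, stop_end_mrna: int, distance: int = 50) -> bool:
    """PTC by direct enumeration: some exon-exon junction lies more than
    ``distance`` nt downstream of the stop codon's end.

    Walks the exon chain base by base conceptually: a junction sits after
    each non-final exon; the stop is premature if any base of the
    transcript more than ``distance`` nt past the stop end lies in a later
    exon than some junction — i.e. any junction offset exceeds
    stop_end + distance.
    """
    acc = 0
    junctions = []
    for e in t.exons[:-1]:
        acc += e.end - e.start + 1
        junctions.append(acc)
    return any(j - stop_end_mrna > distance for j in junctions)


def exact_mw_pvalue(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of rank assignments.

    Enumerates every way the pooled observations could have been split
    between the groups and counts assignments at least as extreme (in
    |U - mn/2|) as the observed one. Valid for tie-free samples.
    """
    x, y = list(x), list(y)
    m, n = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i for i, v in enumerate(pooled)}

    def u_stat(idx_x: tuple[int, ...]) -> float:
        # U = number of (x, y) pairs with x > y, from pooled positions
        sx = set(idx_x)
        u = 0
        for i in sx:
            u += sum(1 for j in range(len(pooled)) if j not in sx and j < i)
        return u

    obs = u_stat(tuple(ranks[v] for v in x))
    center = m * n / 2
    total = 0
    extreme = 0
    for comb in combinations(range(m + n), m):
        total += 1
        if abs(u_stat(comb) - center) >= abs(obs - center) - 1e-12:
            extreme += 1
    return extreme / total


@pytest.fixture(scope="session")
def ptc_oracle():
    return brute_force_ptc


@pytest.fixture(scope="session")
def mw_oracle():
    return exact_mw_pvalue


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_scenario():
    """60-gene seeded scenario with planted usage shifts and PTC isoforms."""
    return simulate_scenario(ScenarioConfig(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def small_annotations(small_scenario):
    sc = small_scenario
    return annotations_to_frame(
        annotate_transcripts(sc.transcripts, sc.reference, sc.genome)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
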
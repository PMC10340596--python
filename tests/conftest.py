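import numpy as np
import pytest

from dyadnet import (
    ROLES,
    SUBSCALES,
    TIME_POINTS,
    CohortTable,
    DyadRecord,
    SyntheticSpec,
    chain_precision,
    complete_case_filter,
    generate_cohort,
    stratify,
)


def make_record(dyad="d000", role="mother", time="t1", sex="female", **scores):
    base = {s: 3 for s in SUBSCALES}
    base.update(scores)
    return DyadRecord(
        dyad_id=dyad, parent_role=role, time_point=time, scores=base, child_sex=sex
    )


def full_dyad_records(dyad="d000", sex="female", score=3):
    return [
        make_record(dyad=dyad, role=r, time=t, sex=sex, Anxiety=score)
        for r in ROLES
        for t in TIME_POINTS
    ]


@pytest.fixture
def small_cohort():
    """Three complete dyads."""
    recs = []
    for i, sex in enumerate(["male", "female", "female"]):
        recs += full_dyad_records(dyad=f"d{i:03d}", sex=sex, score=3 + i)
    return CohortTable.from_records(recs)


@pytest.fixture
def default_cohort():
    cohort, truth = generate_cohort(SyntheticSpec(seed=42))
    return cohort, truth


@pytest.fixture
def complete_strata(default_cohort):
    cohort, _ = default_cohort
    complete, _ = complete_case_filter(cohort)
    return stratify(complete)


def chain_stratum(n=500, seed=0, r=0.3, dyad_rho=0.0, time_rho=0.0):
    """One stratum drawn from a planted chain over the 8 continuous nodes."""
    prec = chain_precision(r=r)
    spec = SyntheticSpec(
        n_dyads=n,
        precision_by_stratum={(role, t): prec for role in ROLES for t in TIME_POINTS},
        sex_effect={},
        dyad_rho=dyad_rho,
        time_rho=time_rho,
        dropout=frozenset(),
        seed=seed,
    )
    cohort, truth = generate_cohort(spec)
    complete, _ = complete_case_filter(cohort)
    return stratify(complete)[0], truth


def _block_connected(W, nodes):
    seen = {nodes[0]}
    stack = [nodes[0]]
    members = set(nodes)
    while stack:
        v = stack.pop()
        for w in np.flatnonzero(W[v]):
            w = int(w)
            if w in members and w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(nodes)


def sbm_graph(rng, p_in=0.8, p_out=0.05, block_size=3, n_blocks=3):
    """Stochastic-block-model adjacency with planted blocks.

    Redraws until every block's induced subgraph is connected: a block
    member with no within-block edge carries no information about its
    block, so such realizations do not instantiate the planted structure.
    """
    p = block_size * n_blocks
    blocks = np.repeat(np.arange(n_blocks), block_size)
    while True:
        W = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < (p_in if blocks[i] == blocks[j] else p_out):
                    W[i, j] = W[j, i] = 1.0
        ok = all(
            _block_connected(W, list(range(b * block_size, (b + 1) * block_size)))
            for b in range(n_blocks)
        )
        if ok:
            return W, blocks


def null_stratum(n=200, seed=0):
    """One stratum with fully independent nodes (empty planted graph)."""
    prec = np.eye(len(SUBSCALES))
    spec = SyntheticSpec(
        n_dyads=n,
        precision_by_stratum={(role, t): prec for role in ROLES for t in TIME_POINTS},
        sex_effect={},
        dyad_rho=0.0,
        time_rho=0.0,
        dropout=frozenset(),
        seed=seed,
    )
    cohort, _ = generate_cohort(spec)
    complete, _ = complete_case_filter(cohort)
    return stratify(complete)[0]
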
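import itertools

import numpy as np
import pytest

from clonesim import Phylogeny, SimulationParams


@pytest.fixture
def baseline_params():
    """Baseline study configuration: 3 time points, 5 clones, 20 variants."""
    return SimulationParams(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20230314)


@pytest.fixture
def linear_phylogeny():
    """Hand-built valid 3-clone linear phylogeny over 3 time points."""
    return Phylogeny(
        parents={1: 0, 2: 1, 3: 2},
        ccf=np.array([[90.0, 80.0, 70.0],
                      [50.0, 60.0, 40.0],
                      [10.0, 30.0, 20.0]]),
        variants_per_clone={1: 2, 2: 1, 3: 1},
    )


def brute_force_violations(phylo, params):
    """Independent constraint checker: plain nested loops, no shared code
    with clonesim.validate_phylogeny beyond the data structures.

    Returns a list of (constraint_name, detail) tuples.
    """
    out = []
    ntp = phylo.ccf.shape[1]
    clones = sorted(phylo.parents)

    def ccf(c):
        return [100.0] * ntp if c == 0 else list(phylo.ccf[c - 1])

    for c in clones:
        for t in range(ntp):
            if ccf(c)[t] > ccf(phylo.parents[c])[t] + 1e-9:
                out.append(("child_exceeds_parent", (c, t)))
    for parent in [0] + clones:
        kids = [c for c in clones if phylo.parents[c] == parent]
        for t in range(ntp):
            if sum(ccf(k)[t] for k in kids) > ccf(parent)[t] + 1e-9:
                out.append(("children_sum", (parent, t)))
    for c in clones:
        vals = ccf(c)
        for t1 in range(ntp):
            for t2 in range(t1 + 1, ntp):
                if vals[t1] <= 1e-9 and vals[t2] > 1e-9:
                    out.append(("eradication", (c, t1, t2)))
    for c in clones:
        if max(ccf(c)) < params.detection_threshold - 1e-9:
            out.append(("detection_threshold", (c,)))
    for a, b in itertools.combinations(clones, 2):
        if max(abs(x - y) for x, y in zip(ccf(a), ccf(b))) < params.min_clonal_distance - 1e-9:
            out.append(("clonal_distance", (a, b)))
    if phylo.variants_per_clone:
        if any(phylo.variants_per_clone[c] < 1 for c in clones):
            out.append(("variant_count", ()))
    return out
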
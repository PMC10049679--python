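"""End-to-end simulation of one patient.

Chains phylogeny generation, CNV and SNV placement, optional overlap
configuration, expected-VAF computation and read simulation into a single
:class:`~clonesim.io_export.SimulationBundle`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_export import SimulationBundle
from .params import SimulationParams
from .phylogeny import Phylogeny, simulate_phylogeny
from .variants import (
    ScenarioInfeasibleError,
    compute_expected_vafs,
    configure_overlap,
    place_snvs,
    scenario_compatible_clones,
    simulate_cnvs,
    simulate_reads,
)


@dataclass(frozen=True)
class OverlapPlan:
    """How many SNVs each CNV overlaps, and under which scenario.

    ``multiplicities`` has one entry per CNV to simulate; e.g.
    ``(1, 1, 1, 2, 2, 3)`` requests six CNVs of which three overlap one
    SNV each, two overlap two SNVs each and one overlaps three.
    """

    multiplicities: tuple[int, ...]
    scenario: str

    @property
    def n_cnvs(self) -> int:
        return len(self.multiplicities)

    @property
    def n_overlapped_snvs(self) -> int:
        return sum(self.multiplicities)


def _eligible_cnv_clones(phylo: Phylogeny, scenario: str) -> list[int]:
    """Clones a CNV may live in so that the scenario has >= 1 compatible
    SNV clone (only restrictive for the parallel scenario)."""
    return [c for c in phylo.clones
            if scenario_compatible_clones(phylo, c, scenario)]


def simulate_patient(
    params: SimulationParams,
    n_cnvs: int = 0,
    overlap: OverlapPlan | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationBundle:
    """Simulate one patient: phylogeny, ``n_cnvs`` CNVs, SNVs filling the
    remaining variant budget, configured overlaps, and reads.

    ``params.n_variants`` counts SNVs and CNVs together; with
    ``n_variants=26`` and ``n_cnvs=6``, 20 SNVs are simulated.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if overlap is not None and n_cnvs == 0:
        n_cnvs = overlap.n_cnvs
    if overlap is not None and overlap.n_cnvs != n_cnvs:
        raise ValueError("overlap plan length does not match n_cnvs")
    if n_cnvs > 0 and not params.cnv_types:
        raise ValueError("n_cnvs > 0 requires params.cnv_types to be non-empty")

    phylo = simulate_phylogeny(params, rng)
    cnvs = []
    if n_cnvs:
        eligible = None
        if overlap is not None:
            eligible = _eligible_cnv_clones(phylo, overlap.scenario)
            if not eligible:
                raise ScenarioInfeasibleError(
                    f"scenario infeasible: no clone in this phylogeny admits "
                    f"{overlap.scenario!r} overlaps")
        cnvs = simulate_cnvs(phylo, params, n_cnvs, rng, eligible_clones=eligible)
    snvs = place_snvs(phylo, cnvs, params.n_variants - n_cnvs, rng)

    if overlap is not None:
        # largest multiplicities on the longest CNVs, so every CNV interval
        # has room for the distinct SNV positions it must host
        order = sorted(cnvs, key=lambda c: c.length, reverse=True)
        mults = sorted(overlap.multiplicities, reverse=True)
        spec = [(c.id, m, overlap.scenario) for c, m in zip(order, mults)]
        snvs, cnvs = configure_overlap(snvs, cnvs, spec, phylo, rng)

    compute_expected_vafs(snvs, cnvs, phylo, params.purity)
    simulate_reads(snvs, params, rng)
    return SimulationBundle(params=params, phylogeny=phylo, cnvs=cnvs, snvs=snvs)
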
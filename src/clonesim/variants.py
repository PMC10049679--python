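"""Simulation of SNVs and (overlapping) CNVs on a clonal phylogeny.

CNVs (deletions, duplications, copy-neutral LOH; length <= 10 kb) are
placed uniformly on the GRCh37 autosomes and assigned to clones within
each clone's variant budget. SNVs are simulated under the infinite-allele
assumption at unique positions outside every CNV; overlaps between an SNV
and a CNV only exist where explicitly configured, under one of four
scenarios describing the order of acquisition:

``cnv_first``
    The CNV was acquired first; the SNV arose in a cell already carrying
    the CNV (SNV clone is a descendant of, or equal to, the CNV clone).
``snv_first_affected`` / ``snv_first_unaffected``
    The SNV was acquired first; the CNV later hit the allele carrying
    the SNV (affected) or the other allele (unaffected). The CNV clone
    is a descendant of, or equal to, the SNV clone.
``parallel``
    SNV and CNV arose in parallel branches; neither clone is an ancestor
    of the other.

The expected VAF of an SNV is the population-sum over all cell
populations at the locus: VAF = 100 * sum_p f_p * m_p / sum_p f_p * t_p,
where f_p is the population's fraction of sampled cells, m_p its number
of mutated copies and t_p its total copy number at the locus (normal and
variant-free tumor cells contribute m=0, t=2). Without any overlapping
CNV this reduces to VAF = purity * CCF / 2.

Read depths are log-normal with mu = ln(mean coverage) and sigma =
|ln 0.7| ~= 0.357; observed VAFs add N(0, 1) percent noise, clamped to
[0, 100], and alt read counts follow as depth * VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genome
from .params import CNV_TYPES, SimulationParams
from .phylogeny import GERMLINE, Phylogeny

MAX_CNV_LENGTH = 10_000
#: consecutive rejected placements before the genome is declared saturated
MAX_PLACEMENT_ATTEMPTS = 10_000

SCENARIOS = ("cnv_first", "snv_first_affected", "snv_first_unaffected", "parallel")

#: log-normal sigma of the read-depth distribution, |ln 0.7|, determined
#: empirically against targeted and WES coverage profiles
READ_DEPTH_SIGMA = abs(np.log(0.7))

_NUCLEOTIDES = ("A", "C", "G", "T")


class VariantSimulationError(RuntimeError):
    pass


class ScenarioInfeasibleError(VariantSimulationError):
    """No clone in the phylogeny satisfies the requested overlap scenario."""


@dataclass
class CNVCall:
    id: str
    chrom: int
    start: int
    end: int
    cnv_type: str
    clone: int
    #: (snv_id, scenario) for every SNV configured to overlap this CNV
    overlapped_snvs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SNVCall:
    id: str
    chrom: int
    pos: int
    ref: str
    alt: str
    clone: int
    #: (cnv_id, scenario) when this SNV overlaps a CNV
    overlap: tuple[str, str] | None = None
    expected_vaf: np.ndarray | None = None  # percent, per time point
    depth: np.ndarray | None = None         # reads, per time point
    alt_reads: np.ndarray | None = None     # reads, per time point
    vaf: np.ndarray | None = None           # observed percent, per time point


# ---------------------------------------------------------------------------
# genotype model

#: (mutated copies m, total copies t) at the SNV locus per cell population.
#: Keys: population is "snv" (SNV only), "both" (SNV + CNV) or "cnv"
#: (CNV only); "both" depends on the scenario of overlap.
_GENOTYPE_TABLE: dict[str, dict[str, tuple[int, int]]] = {
    "deletion": {
        "snv": (1, 2),
        "cnv": (0, 1),
        "both:cnv_first": (1, 1),
        "both:snv_first_affected": (0, 1),
        "both:snv_first_unaffected": (1, 1),
    },
    "duplication": {
        "snv": (1, 2),
        "cnv": (0, 3),
        "both:cnv_first": (1, 3),
        "both:snv_first_affected": (2, 3),
        "both:snv_first_unaffected": (1, 3),
    },
    "LOH": {
        "snv": (1, 2),
        "cnv": (0, 2),
        "both:cnv_first": (1, 2),
        "both:snv_first_affected": (2, 2),
        "both:snv_first_unaffected": (0, 2),
    },
}


def genotype_populations(
    snv_clone_ccf: float,
    cnv_clone_ccf: float | None,
    cnv_type: str | None,
    scenario: str | None,
    purity: float = 1.0,
) -> list[tuple[float, int, int]]:
    """Cell populations at an SNV locus as (fraction, mutated copies,
    total copies) triples summing to fraction 1.

    CCFs are cumulative percentages; ``purity`` scales tumor fractions,
    the remainder being normal cells with genotype AB (m=0, t=2).
    """
    cs = snv_clone_ccf / 100.0 * purity
    pops: list[tuple[float, int, int]] = []
    if cnv_clone_ccf is None or cnv_type is None or scenario is None:
        pops.append((cs, 1, 2))
        rest = 1.0 - cs
    else:
        if cnv_type not in CNV_TYPES:
            raise VariantSimulationError(f"unknown CNV type {cnv_type!r}")
        if scenario not in SCENARIOS:
            raise VariantSimulationError(f"unknown scenario {scenario!r}")
        table = _GENOTYPE_TABLE[cnv_type]
        cv = cnv_clone_ccf / 100.0 * purity
        if scenario == "parallel":
            if cs + cv > 1.0 + 1e-9:
                raise VariantSimulationError(
                    "parallel scenario needs SNV and CNV CCFs summing to <= 100")
            pops.append((cs, *table["snv"]))
            pops.append((cv, *table["cnv"]))
            rest = 1.0 - cs - cv
        elif scenario == "cnv_first":
            if cs > cv + 1e-9:
                raise VariantSimulationError(
                    "cnv_first scenario needs SNV clone CCF <= CNV clone CCF")
            pops.append((cs, *table[f"both:{scenario}"]))
            pops.append((cv - cs, *table["cnv"]))
            rest = 1.0 - cv
        else:  # snv_first_affected / snv_first_unaffected
            if cv > cs + 1e-9:
                raise VariantSimulationError(
                    f"{scenario} scenario needs CNV clone CCF <= SNV clone CCF")
            pops.append((cv, *table[f"both:{scenario}"]))
            pops.append((cs - cv, *table["snv"]))
            rest = 1.0 - cs
    pops.append((rest, 0, 2))
    return [(max(f, 0.0), m, t) for f, m, t in pops]


def expected_vaf(
    snv_clone_ccf: float,
    cnv_clone_ccf: float | None = None,
    cnv_type: str | None = None,
    scenario: str | None = None,
    purity: float = 1.0,
) -> float:
    """Expected (scenario-adjusted) VAF in percent via the population sum.

    Example: an SNV at CCF 100% overlapped by a deletion of the wild-type
    allele in a subclone at CCF 50% (``snv_first_unaffected``) yields
    66.7% - half the cells are AB, half hemizygous B.
    """
    pops = genotype_populations(snv_clone_ccf, cnv_clone_ccf, cnv_type,
                                scenario, purity)
    num = sum(f * m for f, m, _ in pops)
    den = sum(f * t for f, _, t in pops)
    if den <= 0:
        return 0.0
    return 100.0 * num / den


# ---------------------------------------------------------------------------
# CNV simulation

def _clone_budget(phylo: Phylogeny, cnvs: list[CNVCall]) -> dict[int, int]:
    used: dict[int, int] = {c: 0 for c in phylo.clones}
    for cnv in cnvs:
        used[cnv.clone] += 1
    return {c: phylo.variants_per_clone[c] - used[c] for c in phylo.clones}


def _intervals_overlap(a: CNVCall, chrom: int, start: int, end: int) -> bool:
    return a.chrom == chrom and a.start <= end and start <= a.end


def simulate_cnvs(
    phylo: Phylogeny,
    params: SimulationParams,
    n_cnvs: int,
    rng: np.random.Generator,
    eligible_clones: list[int] | None = None,
) -> list[CNVCall]:
    """Simulate ``n_cnvs`` CNVs at random genomic locations.

    Every CNV type selected in ``params.cnv_types`` occurs at least once;
    the remaining types are drawn uniformly. Clones are drawn uniformly
    among clones with free variant budget (optionally restricted to
    ``eligible_clones``, e.g. clones for which an overlap scenario is
    satisfiable). CNVs never overlap each other.
    """
    types = list(params.cnv_types)
    if not types:
        raise VariantSimulationError("params.cnv_types is empty; nothing to simulate")
    if n_cnvs < len(types):
        raise VariantSimulationError(
            f"n_cnvs={n_cnvs} < {len(types)} selected CNV types; "
            "every selected type must be simulated at least once")
    assigned_types = types + [str(rng.choice(types)) for _ in range(n_cnvs - len(types))]
    rng.shuffle(assigned_types)

    cnvs: list[CNVCall] = []
    for i, cnv_type in enumerate(assigned_types):
        budget = _clone_budget(phylo, cnvs)
        pool = [c for c in phylo.clones if budget[c] > 0]
        if eligible_clones is not None:
            restricted = [c for c in pool if c in eligible_clones]
            if restricted:
                pool = restricted
        if not pool:
            raise VariantSimulationError(
                "variant budget exhausted: more CNVs than variants")
        clone = int(rng.choice(pool))
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            chrom, start, end = genome.random_interval(rng, MAX_CNV_LENGTH)
            if not any(_intervals_overlap(c, chrom, start, end) for c in cnvs):
                break
        else:  # pragma: no cover - genome saturation is unreachable in practice
            raise VariantSimulationError("could not place CNV without overlap")
        cnvs.append(CNVCall(id=f"cnv{i + 1}", chrom=chrom, start=start, end=end,
                            cnv_type=cnv_type, clone=clone))
    return cnvs


# ---------------------------------------------------------------------------
# SNV simulation

def place_snvs(
    phylo: Phylogeny,
    cnvs: list[CNVCall],
    n_snvs: int,
    rng: np.random.Generator,
) -> list[SNVCall]:
    """Simulate ``n_snvs`` SNVs at unique random positions outside every
    CNV, filling each clone's remaining variant budget.

    Positions falling inside a CNV by chance are redrawn (the configured
    overlaps are introduced separately via :func:`configure_overlap`).
    """
    budget = _clone_budget(phylo, cnvs)
    if any(b < 0 for b in budget.values()):
        raise VariantSimulationError("CNV assignment exceeds a clone's variant budget")
    if sum(budget.values()) != n_snvs:
        raise VariantSimulationError(
            f"n_snvs={n_snvs} does not match remaining variant budget "
            f"{sum(budget.values())}")
    clone_order = [c for c in phylo.clones for _ in range(budget[c])]
    taken: set[tuple[int, int]] = set()
    snvs: list[SNVCall] = []
    for i, clone in enumerate(clone_order):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            chrom, pos = genome.random_position(rng)
            if (chrom, pos) in taken:
                continue
            if any(c.chrom == chrom and c.start <= pos <= c.end for c in cnvs):
                continue
            break
        else:  # pragma: no cover
            raise VariantSimulationError("could not place SNV outside CNVs")
        taken.add((chrom, pos))
        ref = str(rng.choice(_NUCLEOTIDES))
        alt = str(rng.choice([n for n in _NUCLEOTIDES if n != ref]))
        snvs.append(SNVCall(id=f"snv{i + 1}", chrom=chrom, pos=pos,
                            ref=ref, alt=alt, clone=clone))
    return snvs


# ---------------------------------------------------------------------------
# overlap configuration

def scenario_compatible_clones(phylo: Phylogeny, cnv_clone: int,
                               scenario: str) -> list[int]:
    """Clones an overlapping SNV may be assigned to, given the CNV's clone
    and the scenario's implied clonal (ancestry) relation."""
    out = []
    for c in phylo.clones:
        if scenario == "cnv_first":
            ok = c == cnv_clone or phylo.is_ancestor(cnv_clone, c)
        elif scenario in ("snv_first_affected", "snv_first_unaffected"):
            ok = c == cnv_clone or phylo.is_ancestor(c, cnv_clone)
        elif scenario == "parallel":
            ok = (c != cnv_clone and not phylo.is_ancestor(c, cnv_clone)
                  and not phylo.is_ancestor(cnv_clone, c))
        else:
            raise VariantSimulationError(f"unknown scenario {scenario!r}")
        if ok:
            out.append(c)
    return out


def configure_overlap(
    snvs: list[SNVCall],
    cnvs: list[CNVCall],
    spec: list[tuple[str, int, str]],
    phylo: Phylogeny,
    rng: np.random.Generator,
) -> tuple[list[SNVCall], list[CNVCall]]:
    """Configure SNV/CNV overlaps per ``spec`` = [(cnv_id, n_overlapping,
    scenario), ...].

    For every requested overlap, a not-yet-overlapped SNV is drawn,
    reassigned to a clone drawn uniformly among the clones satisfying the
    scenario's ancestry relation (the donor clone must keep >= 1 variant),
    and repositioned uniformly inside the CNV. Clone budgets in
    ``phylo.variants_per_clone`` are updated to reflect reassignments.
    Raises :class:`ScenarioInfeasibleError` when no clone satisfies a
    scenario. Expected VAFs must be (re)computed afterwards.
    """
    by_id = {c.id: c for c in cnvs}
    counts = {c: 0 for c in phylo.clones}
    for s in snvs:
        counts[s.clone] += 1
    for c in cnvs:
        counts[c.clone] += 1

    taken = {(s.chrom, s.pos) for s in snvs}
    for cnv_id, n_overlapping, scenario in spec:
        cnv = by_id.get(cnv_id)
        if cnv is None:
            raise VariantSimulationError(f"unknown CNV id {cnv_id!r}")
        compatible = scenario_compatible_clones(phylo, cnv.clone, scenario)
        if not compatible:
            raise ScenarioInfeasibleError(
                f"scenario infeasible: no clone satisfies {scenario!r} "
                f"relative to CNV {cnv_id} in clone {cnv.clone}")
        for _ in range(n_overlapping):
            target = int(rng.choice(compatible))
            pool = [s for s in snvs if s.overlap is None
                    and (s.clone == target or counts[s.clone] > 1)]
            if not pool:
                raise VariantSimulationError(
                    f"no free SNV available to overlap CNV {cnv_id}")
            # prefer SNVs already in the target clone; otherwise reassign
            in_target = [s for s in pool if s.clone == target]
            snv = in_target[int(rng.integers(len(in_target)))] if in_target \
                else pool[int(rng.integers(len(pool)))]
            if snv.clone != target:
                counts[snv.clone] -= 1
                counts[target] += 1
                phylo.variants_per_clone[snv.clone] -= 1
                phylo.variants_per_clone[target] += 1
                snv.clone = target
            for _ in range(MAX_PLACEMENT_ATTEMPTS):
                pos = int(rng.integers(cnv.start, cnv.end + 1))
                if (cnv.chrom, pos) not in taken:
                    break
            else:
                raise VariantSimulationError(
                    f"CNV {cnv_id} too short for {n_overlapping} distinct SNV positions")
            taken.discard((snv.chrom, snv.pos))
            taken.add((cnv.chrom, pos))
            snv.chrom, snv.pos = cnv.chrom, pos
            snv.overlap = (cnv.id, scenario)
            cnv.overlapped_snvs.append((snv.id, scenario))
    return snvs, cnvs


# ---------------------------------------------------------------------------
# expected VAFs and read simulation

def compute_expected_vafs(
    snvs: list[SNVCall],
    cnvs: list[CNVCall],
    phylo: Phylogeny,
    purity: float,
) -> None:
    """Fill ``expected_vaf`` (percent, per time point) for every SNV,
    applying the scenario adjustment where an overlap is configured."""
    by_id = {c.id: c for c in cnvs}
    for snv in snvs:
        snv_ccf = phylo.clone_ccf(snv.clone)
        if snv.overlap is None:
            snv.expected_vaf = np.array(
                [expected_vaf(v, purity=purity) for v in snv_ccf])
        else:
            cnv_id, scenario = snv.overlap
            cnv = by_id[cnv_id]
            cnv_ccf = phylo.clone_ccf(cnv.clone)
            snv.expected_vaf = np.array([
                expected_vaf(sv, cv, cnv.cnv_type, scenario, purity)
                for sv, cv in zip(snv_ccf, cnv_ccf)])


def simulate_reads(
    snvs: list[SNVCall],
    params: SimulationParams,
    rng: np.random.Generator,
) -> list[SNVCall]:
    """Simulate per-time-point read depth and alt counts for every SNV.

    depth ~ round(LogNormal(mu=ln(mean_coverage), sigma=|ln 0.7|));
    observed VAF = clamp(expected VAF + N(0,1), 0, 100), rounded to 0.1
    percent; alt reads = round(depth * VAF / 100).
    """
    if params.mean_coverage <= 0:
        raise VariantSimulationError("mean_coverage must be positive")
    mu = np.log(params.mean_coverage)
    ntp = params.n_timepoints
    for snv in snvs:
        if snv.expected_vaf is None or len(snv.expected_vaf) != ntp:
            raise VariantSimulationError(
                f"SNV {snv.id}: expected VAFs missing; run compute_expected_vafs first")
        depth = np.round(rng.lognormal(mean=mu, sigma=READ_DEPTH_SIGMA, size=ntp))
        depth = np.maximum(depth, 1).astype(int)
        vaf = np.clip(snv.expected_vaf + rng.normal(0.0, 1.0, size=ntp), 0.0, 100.0)
        vaf = np.round(vaf, 1)
        snv.depth = depth
        snv.vaf = vaf
        snv.alt_reads = np.round(depth * vaf / 100.0).astype(int)
    return snvs
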
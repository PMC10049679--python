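import numpy as np
import pytest

from clonesim import (
    SimulationParams,
    ScenarioInfeasibleError,
    configure_overlap,
    expected_vaf,
    genotype_populations,
    place_snvs,
    simulate_cnvs,
    simulate_phylogeny,
    simulate_reads,
)
from clonesim.genome import GRCH37_CHROM_LENGTHS
from clonesim.variants import (
    MAX_CNV_LENGTH,
    READ_DEPTH_SIGMA,
    VariantSimulationError,
    compute_expected_vafs,
    scenario_compatible_clones,
)


class TestExpectedVaf:
    def test_deletion_of_wildtype_allele_in_subclone_gives_67_percent(self):
        """SNV clone at 100% CCF, deletion of the un-mutated allele in a
        50% subclone: half the cells are AB, half hemizygous B, so the
        observed VAF is 2/3, not 1/2."""
        vaf = expected_vaf(100, 50, "deletion", "snv_first_unaffected", purity=1.0)
        assert vaf == pytest.approx(200 / 3)
        assert round(vaf) == 67

    def test_reduces_to_half_ccf_without_cnv(self):
        assert expected_vaf(80) == pytest.approx(40.0)
        for ccf in (0, 13.7, 50, 100):
            for purity in (1.0, 0.8, 0.35):
                assert expected_vaf(ccf, purity=purity) == pytest.approx(
                    purity * ccf / 2)

    @pytest.mark.parametrize("cnv_type,scenario,snv_ccf,cnv_ccf,expected", [
        # population-sum oracle values: sum(f*m)/sum(f*t) over the listed
        # populations, computed by hand from the genotype table
        ("LOH", "snv_first_affected", 100, 100, 100.0),       # all cells BB
        ("duplication", "cnv_first", 100, 100, 100 / 3),      # all cells ABB/AAB
        ("deletion", "cnv_first", 50, 100, 50.0),             # B in half, A in half
        ("duplication", "snv_first_affected", 100, 50, 100 * 1.5 / 2.5),
        ("LOH", "snv_first_unaffected", 100, 50, 25.0),       # AA kills half the B
        ("LOH", "cnv_first", 50, 100, 25.0),                  # copy-neutral: AB everywhere
        ("deletion", "parallel", 40, 30, 100 * 0.4 / 1.7),
    ])
    def test_population_sum_oracle(self, cnv_type, scenario, snv_ccf, cnv_ccf, expected):
        assert expected_vaf(snv_ccf, cnv_ccf, cnv_type, scenario) == pytest.approx(expected)

    def test_purity_adds_diploid_unmutated_cells(self):
        # 60% tumor: SNV population 0.6 with (1,1), normal 0.4 with (0,2)
        vaf = expected_vaf(100, 100, "deletion", "cnv_first", purity=0.6)
        assert vaf == pytest.approx(100 * 0.6 / (0.6 + 0.8))

    def test_ancestry_precondition_enforced(self):
        with pytest.raises(VariantSimulationError):
            expected_vaf(80, 50, "deletion", "cnv_first")  # SNV above CNV clone
        with pytest.raises(VariantSimulationError):
            expected_vaf(50, 80, "LOH", "snv_first_affected")
        with pytest.raises(VariantSimulationError):
            expected_vaf(60, 60, "duplication", "parallel")  # fractions > 100%

    def test_monotonicity_in_deletion_subclone_ccf(self):
        """Growing a wild-type-allele deletion subclone concentrates the
        variant (VAF up); growing a mutant-allele deletion subclone removes
        it (VAF down)."""
        grid = np.linspace(0, 80, 17)
        up = [expected_vaf(80, c, "deletion", "snv_first_unaffected") for c in grid]
        down = [expected_vaf(80, c, "deletion", "snv_first_affected") for c in grid]
        assert np.all(np.diff(up) >= -1e-12)
        assert np.all(np.diff(down) <= 1e-12)

    def test_loh_keeps_two_copies_and_ab_genotype_for_cnv_first_and_parallel(self):
        """Copy-neutral LOH acquired before the SNV, or in a parallel
        branch, leaves total copy number 2 and the SNV-bearing population
        heterozygous AB."""
        for scenario, snv_ccf, cnv_ccf in (("cnv_first", 40, 70),
                                           ("parallel", 40, 30)):
            pops = genotype_populations(snv_ccf, cnv_ccf, "LOH", scenario)
            total_cn = sum(f * t for f, _, t in pops) / sum(f for f, _, t in pops)
            assert total_cn == pytest.approx(2.0)
            snv_pops = [(m, t) for f, m, t in pops if m > 0 and f > 0]
            assert snv_pops == [(1, 2)]

    def test_population_fractions_sum_to_one(self):
        for scenario, sv, cv in (("cnv_first", 30, 60), ("snv_first_affected", 60, 30),
                                 ("snv_first_unaffected", 60, 30), ("parallel", 30, 40)):
            for cnv_type in ("deletion", "duplication", "LOH"):
                pops = genotype_populations(sv, cv, cnv_type, scenario, purity=0.9)
                assert sum(f for f, _, _ in pops) == pytest.approx(1.0)


@pytest.fixture
def phylo_and_params():
    params = SimulationParams(n_variants=26, cnv_types=("deletion",), seed=11)
    return simulate_phylogeny(params), params


class TestCnvSimulation:
    def test_single_selected_type_forces_all(self, phylo_and_params, rng):
        phylo, params = phylo_and_params
        cnvs = simulate_cnvs(phylo, params, 6, rng)
        assert [c.cnv_type for c in cnvs] == ["deletion"] * 6

    def test_every_selected_type_occurs(self, rng):
        params = SimulationParams(n_variants=26,
                                  cnv_types=("deletion", "duplication", "LOH"),
                                  seed=5)
        phylo = simulate_phylogeny(params)
        cnvs = simulate_cnvs(phylo, params, 3, rng)
        assert sorted(c.cnv_type for c in cnvs) == ["LOH", "deletion", "duplication"]

    def test_fewer_cnvs_than_types_raises(self, rng):
        params = SimulationParams(n_variants=26,
                                  cnv_types=("deletion", "duplication", "LOH"),
                                  seed=5)
        phylo = simulate_phylogeny(params)
        with pytest.raises(VariantSimulationError):
            simulate_cnvs(phylo, params, 2, rng)

    def test_lengths_and_coordinates_within_genome(self, phylo_and_params, rng):
        phylo, params = phylo_and_params
        seen = []
        for _ in range(100):
            seen += simulate_cnvs(phylo, params, 10, rng)
        for c in seen:
            assert 1 <= c.length <= MAX_CNV_LENGTH
            assert 1 <= c.start <= c.end <= GRCH37_CHROM_LENGTHS[c.chrom]

    def test_clone_budget_respected(self, phylo_and_params, rng):
        phylo, params = phylo_and_params
        cnvs = simulate_cnvs(phylo, params, 6, rng)
        per_clone = {c: 0 for c in phylo.clones}
        for c in cnvs:
            per_clone[c.clone] += 1
        assert all(per_clone[c] <= phylo.variants_per_clone[c] for c in phylo.clones)


class TestSnvPlacement:
    def test_positions_unique_and_outside_cnvs(self, phylo_and_params, rng):
        phylo, params = phylo_and_params
        cnvs = simulate_cnvs(phylo, params, 6, rng)
        snvs = place_snvs(phylo, cnvs, 20, rng)
        assert len({(s.chrom, s.pos) for s in snvs}) == 20
        for s in snvs:
            assert not any(c.chrom == s.chrom and c.start <= s.pos <= c.end
                           for c in cnvs)

    def test_clone_counts_match_budget(self, rng):
        params = SimulationParams(n_variants=20, seed=2)
        phylo = simulate_phylogeny(params)
        snvs = place_snvs(phylo, [], 20, rng)
        counts = {c: 0 for c in phylo.clones}
        for s in snvs:
            counts[s.clone] += 1
        assert counts == phylo.variants_per_clone

    def test_ref_differs_from_alt(self, rng):
        params = SimulationParams(n_variants=20, seed=2)
        phylo = simulate_phylogeny(params)
        for s in place_snvs(phylo, [], 20, rng):
            assert s.ref != s.alt and {s.ref, s.alt} <= {"A", "C", "G", "T"}


class TestOverlapConfiguration:
    def test_requested_multiplicities_are_realized(self, phylo_and_params, rng):
        phylo, params = phylo_and_params
        cnvs = simulate_cnvs(phylo, params, 6, rng)
        snvs = place_snvs(phylo, cnvs, 20, rng)
        spec = [(c.id, m, "cnv_first")
                for c, m in zip(cnvs, (1, 1, 1, 2, 2, 3))]
        snvs, cnvs = configure_overlap(snvs, cnvs, spec, phylo, rng)
        assert sum(1 for s in snvs if s.overlap) == 10
        assert sorted(len(c.overlapped_snvs) for c in cnvs) == [1, 1, 1, 2, 2, 3]
        for s in snvs:
            if s.overlap:
                cnv = next(c for c in cnvs if c.id == s.overlap[0])
                assert cnv.chrom == s.chrom and cnv.start <= s.pos <= cnv.end

    def test_empty_spec_changes_nothing(self, phylo_and_params, rng):
        phylo, params = phylo_and_params
        cnvs = simulate_cnvs(phylo, params, 6, rng)
        snvs = place_snvs(phylo, cnvs, 20, rng)
        before = [(s.chrom, s.pos, s.clone) for s in snvs]
        snvs, _ = configure_overlap(snvs, cnvs, [], phylo, rng)
        assert [(s.chrom, s.pos, s.clone) for s in snvs] == before

    def test_parallel_on_linear_phylogeny_is_infeasible(self, phylo_and_params, rng):
        phylo, params = phylo_and_params
        cnvs = simulate_cnvs(phylo, params, 6, rng)
        snvs = place_snvs(phylo, cnvs, 20, rng)
        with pytest.raises(ScenarioInfeasibleError, match="scenario infeasible"):
            configure_overlap(snvs, cnvs, [(cnvs[0].id, 1, "parallel")], phylo, rng)

    def test_scenario_relation_holds_in_phylogeny(self, rng):
        params = SimulationParams(model="branched_dependent", n_variants=26,
                                  cnv_types=("LOH",), seed=13)
        phylo = simulate_phylogeny(params)
        for scenario in ("cnv_first", "snv_first_affected", "parallel"):
            for cnv_clone in phylo.clones:
                for snv_clone in scenario_compatible_clones(phylo, cnv_clone, scenario):
                    if scenario == "cnv_first":
                        assert snv_clone == cnv_clone or phylo.is_ancestor(cnv_clone, snv_clone)
                    elif scenario == "snv_first_affected":
                        assert snv_clone == cnv_clone or phylo.is_ancestor(snv_clone, cnv_clone)
                    else:
                        assert not phylo.is_ancestor(snv_clone, cnv_clone)
                        assert not phylo.is_ancestor(cnv_clone, snv_clone)
                        assert snv_clone != cnv_clone


class TestReadSimulation:
    @pytest.fixture
    def snvs_with_vafs(self, rng):
        params = SimulationParams(n_variants=20, seed=8)
        phylo = simulate_phylogeny(params)
        snvs = place_snvs(phylo, [], 20, rng)
        compute_expected_vafs(snvs, [], phylo, params.purity)
        return snvs, params

    def test_depth_distribution_parameters_recovered(self, rng):
        """Median depth ~ mean_coverage (= e^mu for a log-normal) and the
        SD of log-depth ~ |ln 0.7|, both within 3% at n=10,000."""
        params = SimulationParams(n_variants=20, mean_coverage=300, seed=8)
        phylo = simulate_phylogeny(params)
        snvs = place_snvs(phylo, [], 20, rng)
        compute_expected_vafs(snvs, [], phylo, params.purity)
        # draw 10,000 depths by repeated read simulation
        collected = []
        for _ in range(10_000 // (20 * params.n_timepoints) + 1):
            simulate_reads(snvs, params, rng)
            collected += [s.depth.copy() for s in snvs]
        depths = np.concatenate(collected)[:10_000]
        assert np.median(depths) == pytest.approx(300, rel=0.03)
        assert np.std(np.log(depths)) == pytest.approx(READ_DEPTH_SIGMA, rel=0.03)

    def test_observed_vaf_tracks_expected_vaf(self, snvs_with_vafs, rng):
        """Mean observed alt fraction converges to the expected VAF within
        two standard errors of the N(0,1) percent noise."""
        snvs, params = snvs_with_vafs
        n = 400
        obs = {s.id: [] for s in snvs}
        for _ in range(n):
            simulate_reads(snvs, params, rng)
            for s in snvs:
                obs[s.id].append(s.alt_reads / s.depth * 100)
        for s in snvs:
            mean_obs = np.mean(obs[s.id], axis=0)
            for t in range(params.n_timepoints):
                se = 1.0 / np.sqrt(n)
                # clamping biases loci with expected VAF near 0 upward
                slack = 2 * se + (0.5 if s.expected_vaf[t] < 2 else 0.0)
                assert abs(mean_obs[t] - s.expected_vaf[t]) < slack + 0.3

    def test_vaf_bounds_and_alt_read_consistency(self, snvs_with_vafs, rng):
        snvs, params = snvs_with_vafs
        simulate_reads(snvs, params, rng)
        for s in snvs:
            assert np.all(s.vaf >= 0) and np.all(s.vaf <= 100)
            assert np.all(s.alt_reads >= 0) and np.all(s.alt_reads <= s.depth)
            assert np.array_equal(s.alt_reads,
                                  np.round(s.depth * s.vaf / 100).astype(int))

    def test_eradicated_clone_yields_near_zero_vaf(self, rng):
        params = SimulationParams(n_clones=1, n_variants=1, seed=77)
        phylo = simulate_phylogeny(params)
        phylo.ccf[0] = [10.0, 0.0, 0.0]
        snvs = place_snvs(phylo, [], 1, rng)
        compute_expected_vafs(snvs, [], phylo, 1.0)
        simulate_reads(snvs, params, rng)
        assert snvs[0].expected_vaf[1] == 0.0
        assert snvs[0].vaf[1] <= 3.0  # clamped N(0,1) noise only
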
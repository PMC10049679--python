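"""The 88-configuration benchmark corpus (10 patients per configuration).

The corpus varies, one axis at a time around a baseline of 3 time
points, 5 clones, 20 SNVs and 300x coverage:

* sim01-sim10: linear evolution, 1-10 time points
* sim11-sim20: linear evolution, 1-10 clones
* sim21-sim30: linear evolution, 5-50 SNVs (step 5)
* sim31-sim40: linear evolution, coverage 10x-2000x
* sim41-sim52: 20 SNVs plus 6 overlapping CNVs (deletions,
  duplications, LOH x the four overlap scenarios); 3 CNVs overlap
  1 SNV each, 2 CNVs overlap 2 SNVs each, 1 CNV overlaps 3 SNVs,
  so 10 of the 20 SNVs are affected
* sim53-sim70: branched dependent evolution (1-10 time points; 3-10 clones)
* sim71-sim88: branched independent evolution (1-10 time points; 3-10 clones)

The three datasets using the ``parallel`` overlap scenario (sim44,
sim48, sim52) are simulated under branched dependent evolution: a
parallel SNV/CNV pair needs two clones in sibling branches, which a
strictly linear phylogeny cannot provide.

Each patient directory contains the simulation bundle plus ground-truth
files for scoring reconstruction tools: ``truth_clusters.tsv`` (variant
id -> clone) and ``truth_tree.tsv`` (parent -> child edge list,
germline = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_export import SimulationBundle, export_bundle
from .params import SimulationParams
from .simulate import OverlapPlan, simulate_patient

PATIENTS_PER_DATASET = 10
OVERLAP_MULTIPLICITIES = (1, 1, 1, 2, 2, 3)

_BASELINE = dict(n_timepoints=3, n_clones=5, n_snvs=20, mean_coverage=300.0)

_SCENARIO_ORDER = ("cnv_first", "snv_first_affected", "snv_first_unaffected",
                   "parallel")
_COVERAGE_LADDER = (10, 20, 50, 100, 200, 300, 500, 1000, 1500, 2000)

#: patient re-simulation attempts (fresh sub-seed) before recording a failure
MAX_PATIENT_RETRIES = 20


@dataclass(frozen=True)
class BenchmarkConfig:
    dataset_id: str
    model: str
    n_timepoints: int
    n_clones: int
    n_snvs: int
    mean_coverage: float
    n_cnvs: int = 0
    cnv_type: str | None = None
    overlap_scenario: str | None = None
    overlap_multiplicities: tuple[int, ...] = ()
    n_patients: int = PATIENTS_PER_DATASET

    def params(self, seed: int | None = None) -> SimulationParams:
        return SimulationParams(
            model=self.model,
            n_timepoints=self.n_timepoints,
            n_clones=self.n_clones,
            n_variants=self.n_snvs + self.n_cnvs,
            mean_coverage=self.mean_coverage,
            cnv_types=(self.cnv_type,) if self.cnv_type else (),
            seed=seed,
        )

    def overlap_plan(self) -> OverlapPlan | None:
        if not self.n_cnvs:
            return None
        return OverlapPlan(multiplicities=self.overlap_multiplicities,
                           scenario=self.overlap_scenario)


def build_benchmark_configs() -> list[BenchmarkConfig]:
    """Enumerate the 88 benchmark configurations."""
    configs: list[BenchmarkConfig] = []

    def add(model, **over):
        fields = {**_BASELINE, **over}
        configs.append(BenchmarkConfig(
            dataset_id=f"sim{len(configs) + 1:02d}", model=model, **fields))

    for ntp in range(1, 11):
        add("linear", n_timepoints=ntp)
    for nc in range(1, 11):
        add("linear", n_clones=nc)
    for nv in range(5, 51, 5):
        add("linear", n_snvs=nv)
    for cov in _COVERAGE_LADDER:
        add("linear", mean_coverage=float(cov))
    for cnv_type in ("deletion", "duplication", "LOH"):
        for scenario in _SCENARIO_ORDER:
            # parallel overlaps need sibling branches; see module docstring
            model = "branched_dependent" if scenario == "parallel" else "linear"
            add(model, n_cnvs=6, cnv_type=cnv_type, overlap_scenario=scenario,
                overlap_multiplicities=OVERLAP_MULTIPLICITIES)
    for model in ("branched_dependent", "branched_independent"):
        for ntp in range(1, 11):
            add(model, n_timepoints=ntp)
        for nc in range(3, 11):
            add(model, n_clones=nc)
    assert len(configs) == 88
    return configs


@dataclass
class PatientFailure:
    dataset_id: str
    patient: int
    error: str


@dataclass
class BenchmarkReport:
    out_dir: Path
    patient_dirs: list[Path] = field(default_factory=list)
    failures: list[PatientFailure] = field(default_factory=list)


def patient_seed(base_seed: int, dataset_index: int, patient: int,
                 retry: int = 0) -> int:
    """Independent, reproducible per-patient seed (31-bit), recorded in the
    exported ``params.yaml`` so any single patient can be re-simulated."""
    ss = np.random.SeedSequence(entropy=base_seed,
                                spawn_key=(dataset_index, patient, retry))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_benchmark_patient(config: BenchmarkConfig, base_seed: int,
                               dataset_index: int, patient: int) -> SimulationBundle:
    """Simulate one benchmark patient, retrying with fresh sub-seeds when a
    random phylogeny happens to leave an overlap plan unsatisfiable."""
    last: Exception | None = None
    for retry in range(MAX_PATIENT_RETRIES):
        seed = patient_seed(base_seed, dataset_index, patient, retry)
        try:
            return simulate_patient(config.params(seed), n_cnvs=config.n_cnvs,
                                    overlap=config.overlap_plan())
        except Exception as exc:  # retried: rare infeasible draws
            last = exc
    raise RuntimeError(
        f"{config.dataset_id} patient {patient}: simulation failed after "
        f"{MAX_PATIENT_RETRIES} attempts: {last}") from last


def _write_truth(bundle: SimulationBundle, directory: Path) -> None:
    lines = ["variant_id\tcluster"]
    lines += [f"{vid}\t{clone}" for vid, clone
              in sorted(bundle.truth_clustering().items())]
    (directory / "truth_clusters.tsv").write_text("\n".join(lines) + "\n")
    lines = ["parent\tchild"]
    lines += [f"{p}\t{c}" for c, p in sorted(bundle.phylogeny.parents.items())]
    (directory / "truth_tree.tsv").write_text("\n".join(lines) + "\n")


def run_benchmark(
    configs: list[BenchmarkConfig],
    base_seed: int,
    out_dir: str | Path,
    progress: bool = False,
) -> BenchmarkReport:
    """Simulate every configuration x patient into ``out_dir``.

    Layout: ``out_dir/simXX/patientYY/{ccf_matrix.tsv, variants.tsv,
    params.yaml, truth_clusters.tsv, truth_tree.tsv}``. Deterministic
    given ``base_seed``. Per-patient failures are recorded in the report
    (with dataset and patient ids) and the run continues.
    """
    out_dir = Path(out_dir)
    all_ids = {c.dataset_id: i for i, c in enumerate(build_benchmark_configs())}
    report = BenchmarkReport(out_dir=out_dir)
    for config in configs:
        dataset_index = all_ids.get(config.dataset_id, 0)
        for patient in range(1, config.n_patients + 1):
            pdir = out_dir / config.dataset_id / f"patient{patient:02d}"
            try:
                bundle = simulate_benchmark_patient(
                    config, base_seed, dataset_index, patient)
                export_bundle(bundle, pdir)
                _write_truth(bundle, pdir)
                report.patient_dirs.append(pdir)
            except Exception as exc:
                report.failures.append(PatientFailure(
                    dataset_id=config.dataset_id, patient=patient, error=str(exc)))
            if progress:  # pragma: no cover
                print(f"{config.dataset_id} patient {patient:02d} done")
    return report
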
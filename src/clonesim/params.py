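"""Simulation parameters and their validity ranges.

A single :class:`SimulationParams` object carries every user-facing knob:
the model of evolution, the number of samples (time points), clones and
variants, the detection threshold ``minth`` and the minimum clonal distance
``mindist`` (both on the percent-CCF scale), the mean sequencing coverage,
the sample purity, and the set of CNV types to simulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MODELS = ("linear", "branched_dependent", "branched_independent")
CNV_TYPES = ("deletion", "duplication", "LOH")


class ParameterError(ValueError):
    """A simulation parameter is outside its allowed range."""


@dataclass(frozen=True)
class SimulationParams:
    """User inputs for one simulated patient.

    Attributes
    ----------
    model:
        ``linear``, ``branched_dependent`` or ``branched_independent``.
    n_timepoints:
        Number of samples collected over the course of disease (1-50).
    n_clones:
        Number of tumor-cell populations / ground-truth clusters (1-50).
    n_variants:
        Total number of variants (SNVs plus CNVs) split across the
        clones (1-200, at least ``n_clones``).
    detection_threshold:
        ``minth`` - minimum CCF (percent) at which a clone is still
        detectable; every clone must reach it at >=1 time point.
    min_clonal_distance:
        ``mindist`` - minimum CCF difference (percent) separating any two
        clones at >=1 time point.
    mean_coverage:
        Mean sequencing depth; read depths are log-normal around it.
    purity:
        Fraction of sampled cells that are tumor cells; normal cells
        dilute the observed VAFs.
    cnv_types:
        Subset of {deletion, duplication, LOH} to simulate. Empty means
        SNVs only.
    seed:
        RNG seed; simulations are reproducible bit-for-bit given
        identical parameters and seed.
    """

    model: str = "linear"
    n_timepoints: int = 3
    n_clones: int = 5
    n_variants: int = 20
    detection_threshold: float = 2.0
    min_clonal_distance: float = 4.0
    mean_coverage: float = 300.0
    purity: float = 1.0
    cnv_types: tuple[str, ...] = field(default=())
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ParameterError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not 1 <= self.n_timepoints <= 50:
            raise ParameterError(f"n_timepoints={self.n_timepoints} outside [1, 50]")
        if not 1 <= self.n_clones <= 50:
            raise ParameterError(f"n_clones={self.n_clones} outside [1, 50]")
        if not 1 <= self.n_variants <= 200:
            raise ParameterError(f"n_variants={self.n_variants} outside [1, 200]")
        if self.n_variants < self.n_clones:
            raise ParameterError(
                f"n_variants={self.n_variants} < n_clones={self.n_clones}: "
                "every clone needs at least one variant"
            )
        if not 0 <= self.detection_threshold <= 50:
            raise ParameterError(f"detection_threshold={self.detection_threshold} outside [0, 50]")
        if not 0 <= self.min_clonal_distance <= 50:
            raise ParameterError(f"min_clonal_distance={self.min_clonal_distance} outside [0, 50]")
        if self.mean_coverage <= 0:
            raise ParameterError(f"mean_coverage={self.mean_coverage} must be positive")
        if not 0 < self.purity <= 1:
            raise ParameterError(f"purity={self.purity} outside (0, 1]")
        object.__setattr__(self, "cnv_types", tuple(self.cnv_types))
        for t in self.cnv_types:
            if t not in CNV_TYPES:
                raise ParameterError(f"unknown CNV type {t!r}; expected one of {CNV_TYPES}")

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)
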
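"""Lossless export/import of complete simulations.

A simulation bundle (parameters, phylogeny + CCF matrix, CNV and SNV
calls) is serialized to three plain-text files in a directory:

``ccf_matrix.tsv``
    One row per clone (germline omitted): ``clone``, ``parent``,
    ``n_variants``, then one ``CCF_t<k>`` column per time point
    (percent, 1 decimal).
``variants.tsv``
    One row per variant: ``id``, ``kind`` (SNV/CNV), ``chrom``,
    ``start``, ``end``, ``ref``, ``alt``, ``cnv_type``, ``clone``,
    ``overlap_cnv_id``, ``scenario``, then ``depth_t<k>``, ``alt_t<k>``,
    ``VAF_t<k>`` per time point (SNVs only; VAF percent, 1 decimal).
``params.yaml``
    The simulation parameters, including the seed.

Re-importing an exported bundle reproduces identical in-memory objects,
and re-exporting yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import SimulationParams
from .phylogeny import Phylogeny, validate_phylogeny
from .variants import CNVCall, SNVCall

CCF_FILE = "ccf_matrix.tsv"
VARIANTS_FILE = "variants.tsv"
PARAMS_FILE = "params.yaml"

_PARAM_ORDER = (
    "model", "n_timepoints", "n_clones", "n_variants",
    "detection_threshold", "min_clonal_distance",
    "mean_coverage", "purity", "cnv_types", "seed",
)


class BundleError(ValueError):
    """Schema or consistency problem in an exported simulation."""


@dataclass
class SimulationBundle:
    """One simulated patient: parameters, phylogeny, variant calls."""

    params: SimulationParams
    phylogeny: Phylogeny
    cnvs: list[CNVCall] = field(default_factory=list)
    snvs: list[SNVCall] = field(default_factory=list)

    @property
    def n_timepoints(self) -> int:
        return self.phylogeny.n_timepoints

    def truth_clustering(self) -> dict[str, int]:
        """Ground-truth variant clustering: variant id -> clone id."""
        out = {s.id: s.clone for s in self.snvs}
        out.update({c.id: c.clone for c in self.cnvs})
        return out


def _fmt(x: float) -> str:
    return f"{x:.1f}"


def export_bundle(bundle: SimulationBundle, directory: str | Path) -> list[Path]:
    """Write the three bundle files; returns the written paths.

    Field order and number formatting are deterministic so that repeated
    exports of equal bundles are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ntp = bundle.n_timepoints
    phylo = bundle.phylogeny

    lines = ["\t".join(["clone", "parent", "n_variants"]
                       + [f"CCF_t{k + 1}" for k in range(ntp)])]
    for c in phylo.clones:
        row = [str(c), str(phylo.parents[c]), str(phylo.variants_per_clone[c])]
        row += [_fmt(v) for v in phylo.clone_ccf(c)]
        lines.append("\t".join(row))
    ccf_path = directory / CCF_FILE
    ccf_path.write_text("\n".join(lines) + "\n")

    per_tp = [col for k in range(ntp)
              for col in (f"depth_t{k + 1}", f"alt_t{k + 1}", f"VAF_t{k + 1}")]
    header = ["id", "kind", "chrom", "start", "end", "ref", "alt", "cnv_type",
              "clone", "overlap_cnv_id", "scenario"] + per_tp
    rows = [("\t".join(header))]
    for s in bundle.snvs:
        cnv_id, scenario = s.overlap if s.overlap else ("", "")
        row = [s.id, "SNV", str(s.chrom), str(s.pos), str(s.pos), s.ref, s.alt,
               "", str(s.clone), cnv_id, scenario]
        for k in range(ntp):
            row += [str(int(s.depth[k])), str(int(s.alt_reads[k])), _fmt(s.vaf[k])]
        rows.append("\t".join(row))
    for c in bundle.cnvs:
        row = [c.id, "CNV", str(c.chrom), str(c.start), str(c.end), "", "",
               c.cnv_type, str(c.clone), "", ""]
        row += ["", "", ""] * ntp
        rows.append("\t".join(row))
    var_path = directory / VARIANTS_FILE
    var_path.write_text("\n".join(rows) + "\n")

    p = bundle.params
    payload = {k: getattr(p, k) for k in _PARAM_ORDER}
    payload["cnv_types"] = list(p.cnv_types)
    params_path = directory / PARAMS_FILE
    params_path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return [ccf_path, var_path, params_path]


def _read_params(path: Path) -> SimulationParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise BundleError(f"{path}: expected a mapping of parameters")
    unknown = set(raw) - set(_PARAM_ORDER)
    if unknown:
        raise BundleError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    raw["cnv_types"] = tuple(raw.get("cnv_types") or ())
    return SimulationParams(**raw)


def import_bundle(directory: str | Path) -> SimulationBundle:
    """Read a bundle directory back into memory.

    Raises :class:`BundleError` on missing files or schema problems, and
    surfaces phylogeny-constraint violations (e.g. a hand-edited CCF
    matrix where a child exceeds its parent) with their standard names.
    """
    directory = Path(directory)
    for name in (CCF_FILE, VARIANTS_FILE, PARAMS_FILE):
        if not (directory / name).exists():
            raise BundleError(f"missing file: {directory / name}")
    params = _read_params(directory / PARAMS_FILE)

    ccf = pd.read_csv(directory / CCF_FILE, sep="\t")
    required = {"clone", "parent", "n_variants"}
    if not required.issubset(ccf.columns):
        raise BundleError(f"{CCF_FILE}: missing columns {required - set(ccf.columns)}")
    tp_cols = [c for c in ccf.columns if c.startswith("CCF_t")]
    if not tp_cols:
        raise BundleError(f"{CCF_FILE}: no CCF_t<k> columns")
    ccf = ccf.sort_values("clone")
    phylo = Phylogeny(
        parents={int(r.clone): int(r.parent) for r in ccf.itertuples()},
        ccf=ccf[tp_cols].to_numpy(dtype=float),
        variants_per_clone={int(r.clone): int(r.n_variants) for r in ccf.itertuples()},
    )
    violations = validate_phylogeny(phylo, params)
    if violations:
        raise BundleError(
            f"{CCF_FILE}: imported phylogeny violates constraints: "
            + "; ".join(str(v) for v in violations))

    var = pd.read_csv(directory / VARIANTS_FILE, sep="\t", dtype={"id": str})
    ntp = len(tp_cols)
    snvs: list[SNVCall] = []
    cnvs: list[CNVCall] = []
    for r in var.itertuples():
        if r.kind == "SNV":
            overlap = None
            if isinstance(r.overlap_cnv_id, str) and r.overlap_cnv_id:
                overlap = (r.overlap_cnv_id, r.scenario)
            snvs.append(SNVCall(
                id=r.id, chrom=int(r.chrom), pos=int(r.start),
                ref=str(r.ref), alt=str(r.alt), clone=int(r.clone),
                overlap=overlap,
                depth=np.array([int(getattr(r, f"depth_t{k + 1}")) for k in range(ntp)]),
                alt_reads=np.array([int(getattr(r, f"alt_t{k + 1}")) for k in range(ntp)]),
                vaf=np.array([float(getattr(r, f"VAF_t{k + 1}")) for k in range(ntp)]),
            ))
        elif r.kind == "CNV":
            cnvs.append(CNVCall(
                id=r.id, chrom=int(r.chrom), start=int(r.start), end=int(r.end),
                cnv_type=str(r.cnv_type), clone=int(r.clone)))
        else:
            raise BundleError(f"{VARIANTS_FILE}: unknown variant kind {r.kind!r}")
    for s in snvs:
        if s.overlap:
            cnv = next((c for c in cnvs if c.id == s.overlap[0]), None)
            if cnv is None:
                raise BundleError(f"{VARIANTS_FILE}: SNV {s.id} references unknown CNV {s.overlap[0]}")
            cnv.overlapped_snvs.append((s.id, s.overlap[1]))
            if not (cnv.chrom == s.chrom and cnv.start <= s.pos <= cnv.end):
                raise BundleError(
                    f"{VARIANTS_FILE}: SNV {s.id} marked overlapping CNV {cnv.id} "
                    "but lies outside its interval")
    return SimulationBundle(params=params, phylogeny=phylo, cnvs=cnvs, snvs=snvs)


def export_vcf(bundle: SimulationBundle, path: str | Path) -> Path:
    """Write the SNVs as a minimal multi-sample VCF 4.2 (one sample per
    time point, GT unphased heterozygous, AD = ref,alt depths, DP)."""
    path = Path(path)
    ntp = bundle.n_timepoints
    samples = [f"t{k + 1}" for k in range(ntp)]
    lines = [
        "##fileformat=VCFv4.2",
        "##source=clonesim",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom in sorted({s.chrom for s in bundle.snvs}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for s in sorted(bundle.snvs, key=lambda s: (s.chrom, s.pos)):
        fields = [str(s.chrom), str(s.pos), s.id, s.ref, s.alt, ".", "PASS", ".",
                  "GT:AD:DP"]
        for k in range(ntp):
            dp = int(s.depth[k])
            alt = int(s.alt_reads[k])
            fields.append(f"0/1:{dp - alt},{alt}:{dp}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path
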
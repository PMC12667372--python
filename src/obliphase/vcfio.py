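"""VCF and genetic-map I/O plus run configuration.

Reference panels arrive as phased VCF (all GT fields ``a|b``); targets as
unphased VCF whose dosages are taken from GT with missing sites dropped.
Sites are matched across files by the exact tuple (chrom, pos, ref, alt);
anything else (allele swaps, strand flips, multiallelic records) is an error
rather than a silent repair.  VCF positions stay 1-based in files; all
internal indices are 0-based half-open.  Output is written as minimal
VCF v4.2 text with deterministic bytes for fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import yaml

from .engine import PhaseConfig
from .panel import HaplotypePanel

logger = logging.getLogger("obliphase")

__all__ = [
    "RunConfig",
    "read_panel_vcf",
    "read_target_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "intersect_sites",
    "load_config",
]


@dataclass
class RunConfig(PhaseConfig):
    """Phasing parameters plus paths and debug flags (YAML-configurable)."""

    panel: str = ""
    target: str = ""
    out: str = ""
    genetic_map: str = ""
    threads: int = 1
    audit_traces: bool = False
    float_shadow: bool = False
    debug_dir: str = ""


def load_config(path: str | None, **overrides) -> RunConfig:
    """YAML config with unknown keys rejected; overrides win."""
    data = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "schedule" in data and not isinstance(data["schedule"], tuple):
        data["schedule"] = tuple(data["schedule"])
    return RunConfig(**data)


def _require_cyvcf2():
    try:
        from cyvcf2 import VCF  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc
    return VCF


def read_panel_vcf(path: str) -> HaplotypePanel:
    """Phased panel VCF -> haplotype matrix (two rows per sample).

    Column order is file sample order with the first (left-of-``|``) allele
    before the second.  Unphased, multiallelic or missing records are
    rejected with the offending site and sample named.
    """
    VCF = _require_cyvcf2()
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, site_ids, positions = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic site {var.CHROM}:{var.POS} not supported")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for si, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], bool(gt[2])
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing allele at {var.CHROM}:{var.POS} "
                    f"sample {samples[si]}")
            if not phased:
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS} "
                    f"sample {samples[si]}")
            col[2 * si], col[2 * si + 1] = a0, a1
        rows.append(col)
        site_ids.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        positions.append(var.POS)
    if not rows:
        raise ValueError("empty panel VCF")
    return HaplotypePanel(np.stack(rows, axis=1), site_ids,
                          np.asarray(positions))


def read_target_vcf(path: str):
    """Unphased target VCF -> per-sample dosage vectors over kept sites.

    Returns ``(sample_names, dosage matrix (n_samples, n_kept), site_ids)``.
    Sites with any missing allele are dropped (count logged).
    """
    VCF = _require_cyvcf2()
    vcf = VCF(path)
    samples = list(vcf.samples)
    dosages, site_ids = [], []
    n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic site {var.CHROM}:{var.POS} not supported")
        row = np.empty(len(samples), dtype=np.int8)
        missing = False
        for si, gt in enumerate(var.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                missing = True
                break
            row[si] = a0 + a1
        if missing:
            n_missing += 1
            continue
        dosages.append(row)
        site_ids.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_missing:
        logger.info("dropped %d sites with missing genotypes", n_missing)
    if not dosages:
        raise ValueError("no usable sites in target VCF")
    return samples, np.stack(dosages, axis=1), site_ids


def intersect_sites(panel: HaplotypePanel, target_sites: list,
                    dosages: np.ndarray):
    """Restrict panel and target to shared (chrom, pos, ref, alt) sites."""
    panel_index = {sid: i for i, sid in enumerate(panel.site_ids)}
    keep_t, keep_p = [], []
    for j, sid in enumerate(target_sites):
        i = panel_index.get(tuple(sid))
        if i is not None:
            keep_t.append(j)
            keep_p.append(i)
    dropped_t = dosages.shape[1] - len(keep_t)
    dropped_p = panel.n_sites - len(keep_p)
    if dropped_t or dropped_p:
        logger.info("site intersection: dropped %d target / %d panel sites",
                    dropped_t, dropped_p)
    if not keep_t:
        raise ValueError("zero shared sites between target and panel")
    keep_p = np.asarray(keep_p)
    sub_panel = HaplotypePanel(
        panel.alleles[:, keep_p],
        [panel.site_ids[i] for i in keep_p],
        panel.positions[keep_p],
    )
    return sub_panel, dosages[:, keep_t]


def write_phased_vcf(path: str, estimates: dict, site_ids: list) -> None:
    """Write phased GT fields (``a|b``); deterministic bytes for fixed input.

    ``estimates`` maps sample name -> :class:`PhaseEstimate`.
    """
    samples = list(estimates)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##source=obliphase",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for i, (chrom, pos, ref, alt) in enumerate(site_ids):
        gts = []
        for name in samples:
            est = estimates[name]
            gts.append(f"{int(est.hap_a[i])}|{int(est.hap_b[i])}")
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_panel_vcf(path: str, panel: HaplotypePanel) -> None:
    """Write a haplotype panel as phased VCF (two haplotypes per sample).

    Requires an even haplotype count; rows 2i and 2i+1 become sample i.
    """
    if panel.n_hap % 2:
        raise ValueError("panel VCF needs an even number of haplotypes")
    n_samp = panel.n_hap // 2
    samples = [f"REF{i}" for i in range(n_samp)]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##source=obliphase",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for i, (chrom, pos, ref, alt) in enumerate(panel.site_ids):
        gts = [
            f"{int(panel.alleles[2 * s, i])}|{int(panel.alleles[2 * s + 1, i])}"
            for s in range(n_samp)
        ]
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_target_vcf(path: str, dosages: np.ndarray, site_ids: list,
                     sample: str = "TARGET") -> None:
    """Write unphased dosages as a single-sample VCF (``0/0``, ``0/1``,
    ``1/1``)."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##source=obliphase",
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for i, (chrom, pos, ref, alt) in enumerate(site_ids):
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     f"{gt_of[int(dosages[i])]}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genetic_map(path: str, positions: np.ndarray) -> np.ndarray:
    """Interpolate cM at physical positions from a two-column TSV (pos, cM).

    Returns per-interval cM distances (length ``len(positions) - 1``);
    non-monotone maps are rejected.  Positions outside the map range take
    the boundary cM value (flat extrapolation).
    """
    table = np.loadtxt(path, dtype=float, ndmin=2)
    pos, cm = table[:, 0], table[:, 1]
    if np.any(np.diff(pos) <= 0) or np.any(np.diff(cm) < 0):
        raise ValueError("genetic map must be strictly increasing in position"
                         " and non-decreasing in cM")
    interp = np.interp(np.asarray(positions, dtype=float), pos, cm)
    return np.diff(interp)
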
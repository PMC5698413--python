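"""Post-calling filter cascade for chrY variant matrices.

The cascade mirrors the standard whole-Y resequencing workflow: restrict
to unique, high-quality regions; keep only sites supported by enough
reads (the callable region, >=5 reads by default); convert heterozygous
calls — impossible on the haploid Y and hence artefacts — to missing;
and finally drop samples with too much missingness (>=5%) or too little
mean coverage (<10X).  Upstream read mapping and genotype calling are
out of scope: the cascade starts from a VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (ANCESTRAL, DERIVED, HETEROZYGOUS, MISSING,
                         RegionMask, VariantMatrix)

DEFAULT_MIN_READS = 5
DEFAULT_MAX_MISSING = 0.05
DEFAULT_MIN_MEAN_DEPTH = 10.0


@dataclass
class SampleQCReport:
    sample: str
    missing_fraction: float
    mean_depth: float
    passed: bool


@dataclass
class CascadeReport:
    """Per-stage site/sample accounting for a filter run."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, vm: VariantMatrix, **extra) -> None:
        self.stages.append({"stage": stage, "n_sites": vm.n_sites,
                            "n_samples": vm.n_samples, **extra})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def apply_callable_filter(vm: VariantMatrix,
                          min_reads: int = DEFAULT_MIN_READS) -> VariantMatrix:
    """Mask genotypes below the read-support threshold.

    Genotypes with depth < ``min_reads`` become missing (never ancestral:
    coercing low-coverage calls to the reference state would bias every
    downstream mutation count).  Sites left missing in all samples are
    dropped.
    """
    if vm.depth is None:
        raise ValueError("callable filter requires per-sample depth (no DP field?)")
    geno = vm.genotypes.copy()
    geno[np.asarray(vm.depth) < min_reads] = MISSING
    keep = ~np.all(geno == MISSING, axis=0)
    out = VariantMatrix(positions=vm.positions, samples=vm.samples,
                        genotypes=geno, depth=vm.depth, ids=vm.ids)
    return out.take_sites(np.flatnonzero(keep))


def apply_region_mask(vm: VariantMatrix, mask: RegionMask) -> VariantMatrix:
    """Keep only sites inside the mask's keep-intervals."""
    inside = mask.contains(vm.positions)
    return vm.take_sites(np.flatnonzero(inside))


def remove_heterozygous_calls(vm: VariantMatrix) -> tuple[VariantMatrix, int]:
    """Convert heterozygous calls to missing; returns the conversion count."""
    geno = vm.genotypes.copy()
    het = geno == HETEROZYGOUS
    geno[het] = MISSING
    out = VariantMatrix(positions=vm.positions, samples=vm.samples,
                        genotypes=geno, depth=vm.depth, ids=vm.ids)
    return out, int(het.sum())


def sample_qc(vm: VariantMatrix,
              max_missing: float = DEFAULT_MAX_MISSING,
              min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH,
              ) -> tuple[VariantMatrix, list[SampleQCReport]]:
    """Drop samples with >= ``max_missing`` missing calls or mean depth
    below ``min_mean_depth`` (mean taken over the currently retained
    sites).  The boundary is exclusive-fail: exactly 5% missing fails."""
    missing = vm.missing_fraction()
    depth = vm.mean_depth() if vm.depth is not None else np.full(vm.n_samples, np.nan)
    reports = []
    keep = []
    for i, s in enumerate(vm.samples):
        ok = (missing[i] < max_missing) and (
            np.isnan(depth[i]) or depth[i] >= min_mean_depth)
        reports.append(SampleQCReport(sample=s, missing_fraction=float(missing[i]),
                                      mean_depth=float(depth[i]), passed=bool(ok)))
        if ok:
            keep.append(i)
    if not keep:
        raise ValueError("sample QC removed every sample")
    return vm.take_samples(np.asarray(keep)), reports


def drop_invariant_sites(vm: VariantMatrix) -> VariantMatrix:
    """Drop sites with no derived call among retained samples."""
    variable = np.any(vm.genotypes == DERIVED, axis=0)
    return vm.take_sites(np.flatnonzero(variable))


def run_filter_cascade(vm_or_vcf, mask: RegionMask | str | None = None,
                       min_reads: int = DEFAULT_MIN_READS,
                       max_missing: float = DEFAULT_MAX_MISSING,
                       min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH,
                       ) -> tuple[VariantMatrix, CascadeReport]:
    """Run mask -> callable -> heterozygote removal -> sample QC, in order.

    Accepts either a VariantMatrix or a VCF path; ``mask`` may be a
    RegionMask, a BED path, or None (no region restriction).  After
    sample QC, sites left invariant by sample removal are dropped so the
    result contains variable sites only.  The report records counts per
    stage; upstream caller-side filtering (e.g. GATK hard filters) is
    labelled external and not re-applied here.
    """
    from . import io as yio

    if isinstance(vm_or_vcf, VariantMatrix):
        vm = vm_or_vcf
    else:
        vm = yio.read_vcf(vm_or_vcf)
    if isinstance(mask, (str,)) or hasattr(mask, "__fspath__"):
        mask = yio.read_bed_mask(mask)

    report = CascadeReport()
    report.record("input (external upstream filters not re-applied)", vm)
    if mask is not None:
        vm = apply_region_mask(vm, mask)
        report.record("region_mask", vm, kept_length_bp=mask.kept_length)
    vm = apply_callable_filter(vm, min_reads=min_reads)
    report.record("callable_filter", vm, min_reads=min_reads)
    vm, n_het = remove_heterozygous_calls(vm)
    report.record("heterozygote_removal", vm, converted=n_het)
    vm, qc = sample_qc(vm, max_missing=max_missing, min_mean_depth=min_mean_depth)
    vm = drop_invariant_sites(vm)
    report.record("sample_qc", vm,
                  removed=[r.sample for r in qc if not r.passed],
                  max_missing=max_missing, min_mean_depth=min_mean_depth)
    return vm, report
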
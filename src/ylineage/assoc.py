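"""Allele-subclade association summaries and haplotype sharing reports.

These are descriptive statistics, not formal tests: per-allele repeat
frequencies inside a target subclade versus the remaining clade members
(the way a single STR allele can tag a subclade, e.g. DYS458*17), and
lists of identical multi-locus haplotypes that span two or more
subclades (the signature of a rapid radiation, where STRs have not yet
diverged between branches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import STRHaplotypeTable
from .phylo import round_half_up


@dataclass
class AlleleFrequencySplit:
    locus: str
    allele: int
    target: str
    freq_in_target: float
    freq_in_complement: float
    n_target: int
    n_complement: int

    @property
    def pct_in_target(self) -> int:
        return int(round_half_up(100.0 * self.freq_in_target, 0))

    @property
    def pct_in_complement(self) -> int:
        return int(round_half_up(100.0 * self.freq_in_complement, 0))


def _aligned_labels(table: STRHaplotypeTable, assignments) -> np.ndarray:
    if isinstance(assignments, dict):
        return np.asarray([assignments[s] for s in table.samples])
    labels = np.asarray(list(assignments))
    if len(labels) != table.n_samples:
        raise ValueError("assignments length does not match the STR table")
    return labels


def allele_split(table: STRHaplotypeTable, assignments, locus: str,
                 target_clade: str,
                 within: set[str] | None = None) -> list[AlleleFrequencySplit]:
    """Per-allele frequency of a locus inside vs outside a target clade.

    ``assignments`` maps samples to haplogroup labels (dict or aligned
    sequence).  ``within`` optionally restricts the comparison to a set
    of labels (e.g. all E-M183 subclades) so the complement means "other
    clade members", not "everything else".  Frequencies within each
    group sum to 1 across alleles.
    """
    if locus not in table.loci:
        raise ValueError(f"locus {locus!r} not in the STR table")
    labels = _aligned_labels(table, assignments)
    in_scope = np.ones(len(labels), dtype=bool)
    if within is not None:
        in_scope = np.isin(labels, sorted(within))
    target_mask = in_scope & (labels == target_clade)
    other_mask = in_scope & (labels != target_clade)
    if not target_mask.any() or not other_mask.any():
        raise ValueError("both the target clade and its complement must be non-empty")
    values = table.data[locus].to_numpy()
    out = []
    for allele in sorted(set(values[in_scope])):
        ft = float(np.mean(values[target_mask] == allele))
        fc = float(np.mean(values[other_mask] == allele))
        out.append(AlleleFrequencySplit(
            locus=locus, allele=int(allele), target=target_clade,
            freq_in_target=ft, freq_in_complement=fc,
            n_target=int(target_mask.sum()), n_complement=int(other_mask.sum())))
    return out


def allele_split_frame(splits: list[AlleleFrequencySplit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": s.locus, "allele": s.allele, "target": s.target,
        "freq_in_target": s.freq_in_target,
        "freq_in_complement": s.freq_in_complement,
        "pct_in_target": s.pct_in_target,
        "pct_in_complement": s.pct_in_complement,
        "n_target": s.n_target, "n_complement": s.n_complement,
    } for s in splits])


def shared_haplotypes(table: STRHaplotypeTable, assignments) -> pd.DataFrame:
    """Identical multi-locus haplotypes observed in two or more subclades.

    Returns one row per shared haplotype with the sorted clade list and
    per-clade counts; symmetric in clade order by construction.
    """
    labels = _aligned_labels(table, assignments)
    haps = table.haplotype_tuples()
    groups: dict[tuple, dict[str, int]] = {}
    for h, lab in zip(haps, labels):
        groups.setdefault(h, {}).setdefault(str(lab), 0)
        groups[h][str(lab)] += 1
    rows = []
    for h, counts in groups.items():
        if len(counts) >= 2:
            rows.append({
                "haplotype": ",".join(map(str, h)),
                "clades": ";".join(sorted(counts)),
                "counts": ";".join(f"{c}:{counts[c]}" for c in sorted(counts)),
                "n_clades": len(counts),
                "n_samples": sum(counts.values()),
            })
    rows.sort(key=lambda r: r["haplotype"])
    return pd.DataFrame(rows, columns=["haplotype", "clades", "counts",
                                       "n_clades", "n_samples"])
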
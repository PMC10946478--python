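"""Reading, filtering and thinning biallelic SNP tables.

The in-memory container is a site x individual genotype matrix in
derived-allele-copy coding (0/1/2, MISSING = -1) with per-genotype read
depth, RAD locus identifiers, and a population map. Filters mirror common
vcftools-style exports: drop sites missing in more than a given fraction of
individuals or with low mean depth, then keep a single randomly chosen SNP
per locus so downstream composite likelihoods can treat sites as unlinked.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "VariantTable",
    "ConfigurationError",
    "VCFParseError",
    "read_vcf",
    "filter_variants",
    "thin_one_snp_per_locus",
    "write_vcf",
    "site_report",
]

MISSING: int = -1

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Inputs are inconsistent with each other (e.g. sample not in pop map)."""


class VCFParseError(ValueError):
    """The VCF could not be parsed."""


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for a set of diploid individuals.

    ``genotypes``: (sites, individuals) int array of derived-allele copies
    (0, 1, 2) or MISSING. ``depths``: matching per-genotype read depth
    (negative where unavailable). ``locus_ids`` groups SNPs into RAD loci.
    """

    genotypes: np.ndarray
    depths: np.ndarray
    locus_ids: List[str]
    positions: np.ndarray
    individuals: List[str]
    pop_map: Dict[str, str]
    has_depth: bool = True

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        s, n = self.genotypes.shape
        if self.depths.shape != (s, n):
            raise ValueError("depths shape must match genotypes shape")
        if len(self.locus_ids) != s or len(self.positions) != s:
            raise ValueError("locus_ids/positions length must match site count")
        if len(self.individuals) != n:
            raise ValueError("individuals length must match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes must be 0, 1, 2 or MISSING")
        absent = [ind for ind in self.individuals if ind not in self.pop_map]
        if absent:
            raise ConfigurationError(f"individuals missing from pop_map: {absent}")
        if any(not lid for lid in self.locus_ids):
            raise ValueError("locus ids must be non-empty")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def populations(self) -> List[str]:
        """Distinct population labels, in first-appearance order over individuals."""
        seen: List[str] = []
        for ind in self.individuals:
            p = self.pop_map[ind]
            if p not in seen:
                seen.append(p)
        return seen

    def individual_indices(self, pop: str) -> np.ndarray:
        return np.array(
            [i for i, ind in enumerate(self.individuals) if self.pop_map[ind] == pop],
            dtype=int,
        )

    def take_sites(self, idx: Sequence[int]) -> "VariantTable":
        idx = np.asarray(idx, dtype=int)
        return VariantTable(
            self.genotypes[idx],
            self.depths[idx],
            [self.locus_ids[i] for i in idx],
            self.positions[idx],
            list(self.individuals),
            dict(self.pop_map),
            self.has_depth,
        )


def read_vcf(
    path,
    pop_map: Mapping[str, str],
    locus_from: str = "chrom",
    skip_multiallelic: bool = True,
) -> VariantTable:
    """Read biallelic SNPs from a VCF into a VariantTable.

    ``locus_from`` selects where the RAD locus identifier lives: "chrom"
    (de-novo catalogues put one locus per contig) or "id" (the VCF ID
    column). Multiallelic or non-SNP records are skipped when
    ``skip_multiallelic`` is true, otherwise they raise.
    """
    from cyvcf2 import VCF

    if locus_from not in ("chrom", "id"):
        raise ValueError("locus_from must be 'chrom' or 'id'")
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib reports its own diagnostics
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_map]
    if absent:
        raise ConfigurationError(f"VCF samples not in pop_map: {absent}")
    gts: List[np.ndarray] = []
    dps: List[np.ndarray] = []
    loci: List[str] = []
    pos: List[int] = []
    has_depth = True
    for rec_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or not v.is_snp:
            if skip_multiallelic:
                log.debug("skipping non-biallelic-SNP record %d", rec_no)
                continue
            raise VCFParseError(f"record {rec_no} ({v.CHROM}:{v.POS}) is not a biallelic SNP")
        row = np.empty(len(samples), dtype=np.int8)
        for k, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            row[k] = MISSING if (a < 0 or b < 0) else a + b
        gts.append(row)
        dp = v.format("DP")
        if dp is None:
            has_depth = False
            dps.append(np.full(len(samples), -1, dtype=np.int32))
        else:
            dps.append(np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32))
        lid = v.CHROM if locus_from == "chrom" else (v.ID or "")
        if not lid:
            raise VCFParseError(f"record {rec_no}: empty locus id (locus_from={locus_from})")
        loci.append(lid)
        pos.append(v.POS)
    if not gts:
        gts_arr = np.zeros((0, len(samples)), dtype=np.int8)
        dps_arr = np.zeros((0, len(samples)), dtype=np.int32)
    else:
        gts_arr = np.stack(gts)
        dps_arr = np.stack(dps)
    return VariantTable(
        gts_arr, dps_arr, loci, np.array(pos, dtype=np.int64), samples, dict(pop_map), has_depth
    )


def filter_variants(
    vt: VariantTable,
    max_missing: float = 0.5,
    min_mean_depth: float = 5.0,
    min_presence: Optional[float] = None,
) -> VariantTable:
    """Apply per-site missingness and mean-depth filters.

    A site is retained iff its fraction of MISSING genotypes is <=
    ``max_missing`` and its mean depth over called genotypes is >=
    ``min_mean_depth``. Missing genotypes carry no depth signal, so the mean
    is taken over called genotypes only. ``min_presence`` optionally requires
    the site to be called in at least that fraction of individuals (off by
    default). Site order is preserved; the filter is idempotent.
    """
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must lie in [0, 1]")
    if min_mean_depth < 0:
        raise ValueError("min_mean_depth must be >= 0")
    if vt.n_sites == 0:
        log.warning("filter_variants: empty variant table")
        return vt
    called = vt.genotypes != MISSING
    miss_frac = 1.0 - called.mean(axis=1)
    keep = miss_frac <= max_missing
    if min_presence is not None:
        keep &= called.mean(axis=1) >= min_presence
    if vt.has_depth:
        n_called = called.sum(axis=1)
        depth_sum = np.where(called & (vt.depths >= 0), vt.depths, 0).sum(axis=1)
        mean_depth = np.divide(
            depth_sum, n_called, out=np.zeros(vt.n_sites, dtype=float), where=n_called > 0
        )
        keep &= mean_depth >= min_mean_depth
    elif min_mean_depth > 0:
        warnings.warn("no DP field in table; skipping mean-depth filter", stacklevel=2)
    return vt.take_sites(np.nonzero(keep)[0])


def thin_one_snp_per_locus(vt: VariantTable, seed: int) -> VariantTable:
    """Keep one uniformly chosen SNP per locus (reproducible under ``seed``)."""
    rng = np.random.default_rng(seed)
    groups: Dict[str, List[int]] = {}
    order: List[str] = []
    for i, lid in enumerate(vt.locus_ids):
        if lid not in groups:
            groups[lid] = []
            order.append(lid)
        groups[lid].append(i)
    chosen = sorted(int(rng.choice(groups[lid])) for lid in order)
    return vt.take_sites(chosen)


def write_vcf(vt: VariantTable, path) -> None:
    """Write the table back out as a minimal VCF 4.2 with GT:DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for lid in dict.fromkeys(vt.locus_ids):
            fh.write(f"##contig=<ID={lid}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.individuals)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for s in range(vt.n_sites):
            cells = []
            for k in range(vt.n_individuals):
                dp = vt.depths[s, k]
                cells.append(f"{gt_str[int(vt.genotypes[s, k])]}:{dp if dp >= 0 else '.'}")
            fh.write(
                f"{vt.locus_ids[s]}\t{vt.positions[s]}\t.\tA\tT\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def site_report(vt: VariantTable):
    """Per-site summary (missingness, mean depth) as a DataFrame."""
    import pandas as pd

    called = vt.genotypes != MISSING
    n_called = called.sum(axis=1)
    depth_sum = np.where(called & (vt.depths >= 0), vt.depths, 0).sum(axis=1)
    return pd.DataFrame(
        {
            "locus": vt.locus_ids,
            "pos": vt.positions,
            "missing_fraction": 1.0 - called.mean(axis=1) if vt.n_sites else [],
            "mean_depth": np.divide(
                depth_sum, n_called, out=np.zeros(vt.n_sites, dtype=float), where=n_called > 0
            )
            if vt.n_sites
            else [],
        }
    )


def read_pop_map(path) -> Dict[str, str]:
    """Read a two-column (individual TAB population) map file."""
    pop_map: Dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ConfigurationError(f"pop map line {line_no}: need individual and population")
            pop_map[parts[0]] = parts[1]
    return pop_map
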
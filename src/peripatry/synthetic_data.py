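"""Synthetic RAD-style data with the statistical structure the pipeline assumes.

Generates (a) folded jSFS count matrices by Poisson-sampling the
engine-computed expected spectrum at a given theta, and (b) toy VCFs of L
unlinked loci with one biallelic SNP each, per-genotype missingness and
negative-binomial read depth, whose per-site allele configurations are drawn
from the model-expected folded spectrum. Every artifact carries a truth
sidecar so round-trip and recovery tests can check each pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .engine import ExpectedSpectrum, expected_jsfs, fold_expected
from .models import get_model
from .sfs import JointSFS, mask_fixed
from .variant_io import MISSING, VariantTable, write_vcf

__all__ = ["SimConfig", "expected_folded", "simulate_jsfs", "simulate_vcf"]


@dataclass
class SimConfig:
    """Generating scenario for synthetic spectra and VCFs.

    ``theta`` (composite scale 4*N_ref*mu*L) sets expected SNP counts;
    alternatively ``n_sites`` fixes the number of simulated loci exactly.
    ``samples`` are diploid individuals per population. Depth is negative
    binomial with the given mean and dispersion (variance = mean +
    mean^2/dispersion).
    """

    model_name: str
    params: Mapping[str, float]
    theta: Optional[float] = None
    n_sites: Optional[int] = None
    samples: Tuple[int, int] = (8, 8)
    missingness: float = 0.0
    depth_mean: float = 20.0
    depth_dispersion: float = 10.0
    seed: int = 0
    engine_replicates: int = 200_000
    pop_labels: Tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        get_model(self.model_name).validate(self.params)
        if self.theta is None and self.n_sites is None:
            raise ValueError("provide theta or n_sites")
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.n_sites is not None and self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0 <= self.missingness < 1):
            raise ValueError("missingness must lie in [0, 1)")
        if min(self.samples) < 1:
            raise ValueError("need at least one diploid per population")

    @property
    def haploid_sizes(self) -> Tuple[int, int]:
        return 2 * self.samples[0], 2 * self.samples[1]


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def expected_folded(cfg: SimConfig, n1: Optional[int] = None, n2: Optional[int] = None) -> ExpectedSpectrum:
    """Folded theta-free expected spectrum for the configured scenario."""
    h1, h2 = cfg.haploid_sizes
    n1 = h1 if n1 is None else n1
    n2 = h2 if n2 is None else n2
    dem = get_model(cfg.model_name).build(cfg.params)
    engine_seed = int(_rng(cfg, 0xE5).integers(2**31))
    return fold_expected(expected_jsfs(dem, n1, n2, cfg.engine_replicates, engine_seed))


def simulate_jsfs(cfg: SimConfig) -> JointSFS:
    """Poisson-sampled folded jSFS at the configured theta.

    Cell means are theta/2 times the expected branch-length spectrum (so a
    single equilibrium population would have mean theta/i at frequency i).
    """
    if cfg.theta is None:
        raise ValueError("simulate_jsfs requires theta")
    es = expected_folded(cfg)
    mu = 0.5 * cfg.theta * es.values
    counts = np.zeros_like(mu)
    rng = _rng(cfg, 0x5F)
    unmasked = ~es.mask
    counts[unmasked] = rng.poisson(mu[unmasked])
    return JointSFS(counts, folded=True, mask=es.mask.copy(), pop_labels=cfg.pop_labels)


def simulate_vcf(cfg: SimConfig, path) -> Tuple[VariantTable, dict]:
    """Write a toy VCF of unlinked one-SNP loci drawn from the model spectrum.

    Per-site minor-allele configurations (i, j) are drawn from the folded
    expected spectrum at the full haploid sample sizes; allele copies are
    assigned to chromosomes by random assortment; genotypes are masked
    MISSING at the configured rate; DP is negative-binomial. Truth (model,
    parameters, per-site configurations) goes to ``<path>.truth.json``.
    Returns the pre-missingness VariantTable is not exposed; the returned
    table is exactly what was written.
    """
    n1, n2 = cfg.haploid_sizes
    es = expected_folded(cfg)
    rng = _rng(cfg, 0x7C)
    unmasked = np.nonzero(~es.mask)
    probs = es.values[unmasked]
    total = probs.sum()
    if total <= 0:
        raise ValueError("expected spectrum has no segregating mass")
    probs = probs / total
    if cfg.n_sites is not None:
        n_sites = int(cfg.n_sites)
    else:
        n_sites = int(rng.poisson(0.5 * cfg.theta * total))
    cells = rng.choice(len(probs), size=n_sites, p=probs)
    configs = [(int(unmasked[0][c]), int(unmasked[1][c])) for c in cells]

    d1, d2 = cfg.samples
    individuals = [f"{cfg.pop_labels[0]}_{k}" for k in range(d1)] + [
        f"{cfg.pop_labels[1]}_{k}" for k in range(d2)
    ]
    pop_map = {ind: cfg.pop_labels[0] if k < d1 else cfg.pop_labels[1] for k, ind in enumerate(individuals)}
    genotypes = np.zeros((n_sites, d1 + d2), dtype=np.int8)
    for s, (i, j) in enumerate(configs):
        chrom1 = np.zeros(n1, dtype=np.int8)
        chrom1[rng.choice(n1, size=i, replace=False)] = 1
        chrom2 = np.zeros(n2, dtype=np.int8)
        chrom2[rng.choice(n2, size=j, replace=False)] = 1
        genotypes[s, :d1] = chrom1.reshape(d1, 2).sum(axis=1)
        genotypes[s, d1:] = chrom2.reshape(d2, 2).sum(axis=1)
    k = cfg.depth_dispersion
    depths = rng.negative_binomial(k, k / (k + cfg.depth_mean), size=genotypes.shape).astype(
        np.int32
    )
    if cfg.missingness > 0:
        miss = rng.random(genotypes.shape) < cfg.missingness
        genotypes[miss] = MISSING
        depths[miss] = 0
    vt = VariantTable(
        genotypes,
        depths,
        [f"locus_{s}" for s in range(n_sites)],
        np.arange(1, n_sites + 1),
        individuals,
        pop_map,
    )
    write_vcf(vt, path)
    truth = {
        "model_name": cfg.model_name,
        "params": dict(cfg.params),
        "theta": cfg.theta,
        "n_sites": n_sites,
        "samples": list(cfg.samples),
        "missingness": cfg.missingness,
        "seed": cfg.seed,
        "site_configs": configs,
    }
    with open(f"{path}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return vt, truth
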
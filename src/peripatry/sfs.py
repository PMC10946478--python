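"""Joint site-frequency spectra: construction, projection, folding, masking.

The joint SFS (jSFS) for two populations with n1 and n2 sampled haploid
genomes is an (n1+1) x (n2+1) matrix whose (i, j) entry counts SNPs with i
copies of the non-reference allele in population 1 and j copies in
population 2. Missing genotypes are absorbed by hypergeometric
downprojection: every site is averaged over all subsamples of the target
size, so a site with c called haploid copies contributes fractional weight
to the target-size grid rather than being dropped. Without ancestral-state
information the spectrum is folded: each cell is merged with its
allele-relabelled complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Tuple

import numpy as np
from scipy.stats import hypergeom

from .variant_io import MISSING, VariantTable

__all__ = [
    "JointSFS",
    "project_site",
    "build_jsfs",
    "fold",
    "mask_fixed",
    "segregating_sites",
    "choose_projection",
    "write_sfs",
    "read_sfs",
]

log = logging.getLogger(__name__)


@dataclass
class JointSFS:
    """A two-population site-frequency spectrum.

    ``counts[i, j]``: (expected or observed) number of SNPs with allele
    configuration (i, j). ``mask`` marks excluded cells (True = excluded),
    at minimum the two non-segregating corners.
    """

    counts: np.ndarray
    folded: bool = False
    mask: np.ndarray = None  # type: ignore[assignment]
    pop_labels: Tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("jSFS counts must be a 2-D matrix")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("jSFS counts must be finite and non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts shape")

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    def unmasked_sum(self) -> float:
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.counts.copy(), self.folded, self.mask.copy(), self.pop_labels)


def project_site(derived: int, total: int, target: int) -> np.ndarray:
    """Hypergeometric projection weights for one site.

    weight[j] is the probability that a uniform subsample of ``target`` of
    the ``total`` called haploid copies contains j derived copies:
    C(derived, j) * C(total-derived, target-j) / C(total, target).
    """
    if not (0 <= derived <= total):
        raise ValueError("need 0 <= derived <= total")
    if not (1 <= target <= total):
        raise ValueError("need 1 <= target <= total")
    j = np.arange(target + 1)
    w = hypergeom.pmf(j, total, derived, target)
    return w / w.sum()  # renormalize away pmf round-off


def _site_pop_counts(vt: VariantTable) -> tuple:
    """Per-site (derived, called-haploid) counts for each of the two populations."""
    pops = vt.populations()
    if len(pops) != 2:
        raise ValueError(f"need exactly 2 populations, got {pops}")
    out = []
    for pop in pops:
        idx = vt.individual_indices(pop)
        g = vt.genotypes[:, idx]
        called = g != MISSING
        derived = np.where(called, g, 0).sum(axis=1)
        out.append((derived, 2 * called.sum(axis=1)))
    return pops, out


def build_jsfs(vt: VariantTable, target_sizes: Tuple[int, int]) -> JointSFS:
    """Project every site onto the target haploid sample sizes and tabulate.

    Sites with fewer called haploid copies than the target in either
    population contribute nothing. The result is unfolded, with the fixed
    corners (0,0) and (n1,n2) masked.
    """
    t1, t2 = int(target_sizes[0]), int(target_sizes[1])
    if t1 < 1 or t2 < 1:
        raise ValueError("target sizes must be >= 1")
    pops, ((d1, c1), (d2, c2)) = _site_pop_counts(vt)
    counts = np.zeros((t1 + 1, t2 + 1))
    usable = (c1 >= t1) & (c2 >= t2)
    for s in np.nonzero(usable)[0]:
        w1 = project_site(int(d1[s]), int(c1[s]), t1)
        w2 = project_site(int(d2[s]), int(c2[s]), t2)
        counts += np.outer(w1, w2)
    out = JointSFS(counts, folded=False, pop_labels=(pops[0], pops[1]))
    return mask_fixed(out)


def choose_projection(vt: VariantTable, min_fraction: float = 0.8) -> Tuple[int, int]:
    """Pick downprojection sizes maximizing n1+n2 while keeping sites.

    Among (even) target pairs that retain at least ``min_fraction`` of the
    sites, return the one with the largest total haploid sample size (ties:
    larger n1).
    """
    _, ((_, c1), (_, c2)) = _site_pop_counts(vt)
    n_sites = len(c1)
    if n_sites == 0:
        raise ValueError("no sites to project")
    best = None
    for t1 in range(2, int(c1.max()) + 1, 2):
        for t2 in range(2, int(c2.max()) + 1, 2):
            kept = int(((c1 >= t1) & (c2 >= t2)).sum())
            if kept >= min_fraction * n_sites:
                key = (t1 + t2, t1)
                if best is None or key > best[0]:
                    best = (key, (t1, t2))
    if best is None:
        raise ValueError("no projection retains the requested fraction of sites")
    return best[1]


def fold_matrix(values: np.ndarray, mask: np.ndarray) -> tuple:
    """Fold an unfolded jSFS matrix (and its mask) over allele relabelling.

    Cell (i, j) merges with its complement (n1-i, n2-j). Kept cells are those
    with i+j below half the total sample size; on the tie line the
    lexicographically smaller member of each pair is kept. Masked cells
    contribute no mass. Returns (folded_values, folded_mask).
    """
    n1 = values.shape[0] - 1
    n2 = values.shape[1] - 1
    half = (n1 + n2) / 2.0
    out = np.zeros_like(values, dtype=float)
    out_mask = np.ones_like(mask, dtype=bool)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            ci, cj = n1 - i, n2 - j
            tot = i + j
            if tot > half:
                continue
            if tot == half and (i, j) > (ci, cj):
                continue
            v = 0.0 if mask[i, j] else values[i, j]
            if (i, j) != (ci, cj) and not mask[ci, cj]:
                v += values[ci, cj]
            out[i, j] = v
            out_mask[i, j] = mask[i, j] and mask[ci, cj]
    return out, out_mask


def fold(jsfs: JointSFS) -> JointSFS:
    """Fold the spectrum; total unmasked mass is conserved."""
    if jsfs.folded:
        raise ValueError("spectrum is already folded")
    counts, mask = fold_matrix(jsfs.counts, jsfs.mask)
    return JointSFS(counts, folded=True, mask=mask, pop_labels=jsfs.pop_labels)


def mask_fixed(jsfs: JointSFS) -> JointSFS:
    """Mask the non-segregating corner cells (idempotent)."""
    out = jsfs.copy()
    out.mask[0, 0] = True
    out.mask[out.n1, out.n2] = True
    out.counts[0, 0] = 0.0
    out.counts[out.n1, out.n2] = 0.0
    return out


def segregating_sites(jsfs: JointSFS) -> float:
    """Total (possibly fractional) count of segregating sites."""
    return jsfs.unmasked_sum()


# --- plain-text serialization (dadi-style) ---------------------------------

def write_sfs(jsfs: JointSFS, path) -> None:
    """Write a spectrum in the dadi plain-text convention.

    Line 1: "<n1+1> <n2+1> <folded|unfolded>"; line 2: row-major counts;
    line 3: row-major mask as 0/1 (1 = masked).
    """
    with open(path, "w") as fh:
        fh.write(f"{jsfs.n1 + 1} {jsfs.n2 + 1} {'folded' if jsfs.folded else 'unfolded'}\n")
        fh.write(" ".join(f"{v:.10g}" for v in jsfs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in jsfs.mask.ravel()) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3 or header[2] not in ("folded", "unfolded"):
            raise ValueError(f"malformed SFS header in {path}")
        shape = (int(header[0]), int(header[1]))
        counts = np.fromstring(fh.readline(), sep=" ").reshape(shape)
        mask_line = fh.readline().split()
        if mask_line:
            mask = np.array([c == "1" for c in mask_line], dtype=bool).reshape(shape)
        else:
            mask = np.zeros(shape, dtype=bool)
    return JointSFS(counts, folded=header[2] == "folded", mask=mask)


def to_dataframe(jsfs: JointSFS):
    """Long-format TSV-ready view (one row per unmasked cell)."""
    import pandas as pd

    i, j = np.nonzero(~jsfs.mask)
    return pd.DataFrame({"i": i, "j": j, "count": jsfs.counts[i, j]})
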
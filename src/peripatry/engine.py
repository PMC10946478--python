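"""Expected joint SFS under a piecewise demography, by Monte-Carlo coalescent.

For an unlinked biallelic site under the infinite-sites model, the expected
number of SNPs with allele configuration (i, j) is proportional to the
expected total length of genealogy branches subtending exactly i of the n1
leaves sampled in population 1 and j of the n2 leaves in population 2. This
module estimates that branch-length spectrum by simulating structured
coalescent genealogies backward in time through the demography's epochs:

* within a deme of (time-varying) relative size nu(t), each pair of lineages
  coalesces at rate 1/nu(t) (time in units of 2*N_ref generations);
* a lineage in deme a jumps to deme b at rate equal to the 2*N_ref-scaled
  forward migration rate from b into a;
* exponential size trajectories are handled exactly by inverting the
  integrated coalescence rate (no Euler stepping);
* before the split, all lineages coalesce in the root population.

The returned spectrum is theta-free: absolute scale enters only through the
likelihood's analytic theta step. With theta = 4*N_ref*mu*L, expected SNP
counts are theta/2 times these branch lengths, so a single equilibrium
population yields the classical E[xi_i] = theta / i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from numba import njit

from .models import Demography
from .sfs import JointSFS, fold_matrix

__all__ = ["ExpectedSpectrum", "expected_jsfs", "fold_expected", "MAX_LINEAGES"]

# desk-scale guard: genealogy cost grows with sample size and larger grids
# need far more replicates per cell anyway
MAX_LINEAGES = 60

_R_TINY = 1e-12


@dataclass
class ExpectedSpectrum:
    """Monte-Carlo estimate of the relative expected jSFS.

    ``values[i, j]`` is the mean branch length (2*N_ref-generation units)
    subtending i pop-1 and j pop-2 leaves; ``mc_se`` the per-cell standard
    error of that mean.
    """

    values: np.ndarray
    mc_se: np.ndarray
    n_replicates: int
    seed: int
    folded: bool = False
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
            self.mask[0, 0] = True
            self.mask[-1, -1] = True
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("expected spectrum must be finite and non-negative")

    @property
    def n1(self) -> int:
        return self.values.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.values.shape[1] - 1

    def unmasked_sum(self) -> float:
        return float(self.values[~self.mask].sum())

    def as_jsfs(self, pop_labels=("pop1", "pop2")) -> JointSFS:
        return JointSFS(self.values, folded=self.folded, mask=self.mask, pop_labels=pop_labels)


@njit(cache=True)
def _lam(u, A, B0, r0, B1, r1):
    tot = A * u
    if B0 > 0.0:
        tot += B0 * ((np.exp(r0 * u) - 1.0) / r0 if abs(r0) > _R_TINY else u)
    if B1 > 0.0:
        tot += B1 * ((np.exp(r1 * u) - 1.0) / r1 if abs(r1) > _R_TINY else u)
    return tot


@njit(cache=True)
def _lam_prime(u, A, B0, r0, B1, r1):
    tot = A
    if B0 > 0.0:
        tot += B0 * np.exp(r0 * u)
    if B1 > 0.0:
        tot += B1 * np.exp(r1 * u)
    return tot


@njit(cache=True)
def _solve_wait(E, rem, A, B0, r0, B1, r1):
    """Smallest u with integrated hazard Lambda(u) = E, or -1 if > rem."""
    lam_rem = _lam(rem, A, B0, r0, B1, r1)
    if lam_rem < E:
        return -1.0
    if abs(r0) <= _R_TINY and abs(r1) <= _R_TINY:
        return E / (A + B0 + B1)
    # safeguarded Newton on a monotone function, bracket [lo, hi]
    lo = 0.0
    hi = rem
    u = min(rem, E / _lam_prime(0.0, A, B0, r0, B1, r1))
    for _ in range(100):
        f = _lam(u, A, B0, r0, B1, r1) - E
        if abs(f) <= 1e-10 * (1.0 + E):
            break
        if f > 0.0:
            hi = u
        else:
            lo = u
        step = f / _lam_prime(u, A, B0, r0, B1, r1)
        u_new = u - step
        if u_new <= lo or u_new >= hi:
            u_new = 0.5 * (lo + hi)
        u = u_new
    return u


@njit(cache=True)
def _pick_in_deme(deme, nact, a, rank):
    """Index of the rank-th active lineage currently in deme a."""
    c = 0
    for i in range(nact):
        if deme[i] == a:
            if c == rank:
                return i
            c += 1
    return -1  # unreachable when rank < deme count


@njit(cache=True)
def _simulate_branch_spectrum(
    n1, n2, reps, seed, durs, nu_recent, nu_old, mig_back, root_size
):
    """Accumulate per-class branch lengths over `reps` genealogies.

    Epoch arrays are in backward order (index 0 = most recent epoch). A
    lineage's descendant-count class is fixed over its lifetime, so each
    lineage's full branch length is charged to its class once, when it
    coalesces. Returns (mean, standard error) matrices of shape
    (n1+1, n2+1).
    """
    np.random.seed(seed)
    n_epochs = durs.shape[0]
    n = n1 + n2
    acc = np.zeros((n1 + 1, n2 + 1))
    acc2 = np.zeros((n1 + 1, n2 + 1))
    rep = np.zeros((n1 + 1, n2 + 1))
    deme = np.empty(n, np.int64)
    d1 = np.empty(n, np.int64)
    d2 = np.empty(n, np.int64)
    birth = np.empty(n, np.float64)
    for _ in range(reps):
        rep[:, :] = 0.0
        for i in range(n1):
            deme[i] = 0
            d1[i] = 1
            d2[i] = 0
            birth[i] = 0.0
        for i in range(n1, n):
            deme[i] = 1
            d1[i] = 0
            d2[i] = 1
            birth[i] = 0.0
        nact = n
        k0 = n1
        e = 0
        t_in = 0.0
        t_abs = 0.0  # cumulative backward time
        while nact > 1:
            if e >= n_epochs:
                # root population: constant size, single deme
                haz = 0.5 * nact * (nact - 1) / root_size
                u = np.random.exponential(1.0) / haz
                t_abs += u
                i1 = int(np.random.random() * nact)
                i2 = int(np.random.random() * (nact - 1))
                if i2 >= i1:
                    i2 += 1
                rep[d1[i1], d2[i1]] += t_abs - birth[i1]
                rep[d1[i2], d2[i2]] += t_abs - birth[i2]
                d1[i1] += d1[i2]
                d2[i1] += d2[i2]
                birth[i1] = t_abs
                nact -= 1
                deme[i2] = deme[nact]
                d1[i2] = d1[nact]
                d2[i2] = d2[nact]
                birth[i2] = birth[nact]
                continue
            k1 = nact - k0
            dur = durs[e]
            # per-deme coalescence hazard B*exp(r*u) at offset u from t_in
            B0 = 0.0
            r0 = 0.0
            if k0 > 1:
                r0 = np.log(nu_recent[e, 0] / nu_old[e, 0]) / dur
                B0 = 0.5 * k0 * (k0 - 1) / nu_recent[e, 0] * np.exp(r0 * t_in)
            B1 = 0.0
            r1 = 0.0
            if k1 > 1:
                r1 = np.log(nu_recent[e, 1] / nu_old[e, 1]) / dur
                B1 = 0.5 * k1 * (k1 - 1) / nu_recent[e, 1] * np.exp(r1 * t_in)
            m01 = k0 * mig_back[e, 0, 1]
            m10 = k1 * mig_back[e, 1, 0]
            A = m01 + m10
            rem = dur - t_in
            u = _solve_wait(np.random.exponential(1.0), rem, A, B0, r0, B1, r1)
            if u < 0.0:
                # no event before the epoch boundary
                t_abs += rem
                e += 1
                t_in = 0.0
                continue
            t_abs += u
            t_in += u
            wc0 = B0 * np.exp(r0 * u) if B0 > 0.0 else 0.0
            wc1 = B1 * np.exp(r1 * u) if B1 > 0.0 else 0.0
            x = np.random.random() * (wc0 + wc1 + m01 + m10)
            if x < wc0 + wc1:
                a = 0 if x < wc0 else 1
                ka = k0 if a == 0 else k1
                i1 = _pick_in_deme(deme, nact, a, int(np.random.random() * ka))
                rank2 = int(np.random.random() * (ka - 1))
                i2 = -1
                c = 0
                for i in range(nact):
                    if deme[i] == a and i != i1:
                        if c == rank2:
                            i2 = i
                            break
                        c += 1
                rep[d1[i1], d2[i1]] += t_abs - birth[i1]
                rep[d1[i2], d2[i2]] += t_abs - birth[i2]
                d1[i1] += d1[i2]
                d2[i1] += d2[i2]
                birth[i1] = t_abs
                nact -= 1
                deme[i2] = deme[nact]
                d1[i2] = d1[nact]
                d2[i2] = d2[nact]
                birth[i2] = birth[nact]
                if a == 0:
                    k0 -= 1
            elif x < wc0 + wc1 + m01:
                i1 = _pick_in_deme(deme, nact, 0, int(np.random.random() * k0))
                deme[i1] = 1
                k0 -= 1
            else:
                i1 = _pick_in_deme(deme, nact, 1, int(np.random.random() * k1))
                deme[i1] = 0
                k0 += 1
        acc += rep
        acc2 += rep * rep
    mean = acc / reps
    var = acc2 / reps - mean * mean
    var = np.maximum(var, 0.0)
    se = np.sqrt(var / reps)
    return mean, se


def _demography_arrays(dem: Demography):
    epochs = list(reversed(dem.epochs))  # backward order: most recent first
    n_e = len(epochs)
    durs = np.empty(n_e)
    nu_recent = np.empty((n_e, 2))
    nu_old = np.empty((n_e, 2))
    mig_back = np.zeros((n_e, 2, 2))
    for k, ep in enumerate(epochs):
        durs[k] = ep.duration
        nu_recent[k, 0], nu_recent[k, 1] = ep.end_sizes
        nu_old[k, 0], nu_old[k, 1] = ep.start_sizes
        # backward: a lineage in deme a jumps to b at the forward rate b -> a
        mig_back[k, 0, 1] = ep.migration[1][0]
        mig_back[k, 1, 0] = ep.migration[0][1]
    return durs, nu_recent, nu_old, mig_back


def expected_jsfs(
    dem: Demography,
    n1: int,
    n2: int,
    n_replicates: int = 20_000,
    seed: int = 0,
    allow_large: bool = False,
) -> ExpectedSpectrum:
    """Estimate the relative expected jSFS for n1 + n2 sampled haploids.

    ``n2 = 0`` gives a single-population spectrum (shape (n1+1, 1)). The
    result is unfolded, with the fixed corners masked. Identical seeds give
    identical output.
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 0 or (n2 == 0 and n1 < 2):
        raise ValueError("need n1 >= 2 and n2 >= 0")
    if n1 + n2 > MAX_LINEAGES and not allow_large:
        raise ValueError(
            f"n1+n2 = {n1 + n2} exceeds the desk-scale cap {MAX_LINEAGES}; "
            "pass allow_large=True to override"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    durs, nu_recent, nu_old, mig_back = _demography_arrays(dem)
    values, se = _simulate_branch_spectrum(
        n1, n2, int(n_replicates), int(seed) & 0x7FFFFFFF,
        durs, nu_recent, nu_old, mig_back, dem.root_size,
    )
    return ExpectedSpectrum(values, se, int(n_replicates), int(seed))


def write_expected(es: ExpectedSpectrum, path) -> None:
    """Write the spectrum in the shared SFS text format plus an MC-error sidecar."""
    from .sfs import write_sfs

    write_sfs(es.as_jsfs(), path)
    with open(f"{path}.mcse", "w") as fh:
        fh.write(f"{es.n1 + 1} {es.n2 + 1} replicates={es.n_replicates} seed={es.seed}\n")
        fh.write(" ".join(f"{v:.6g}" for v in es.mc_se.ravel()) + "\n")


def fold_expected(es: ExpectedSpectrum) -> ExpectedSpectrum:
    """Fold the expected spectrum with the same rule as data folding."""
    if es.folded:
        raise ValueError("expected spectrum is already folded")
    values, mask = fold_matrix(es.values, es.mask)
    # variances add under the complement merge
    se2, _ = fold_matrix(es.mc_se**2, es.mask)
    return ExpectedSpectrum(
        values, np.sqrt(se2), es.n_replicates, es.seed, folded=True, mask=mask
    )
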
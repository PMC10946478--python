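"""Correctness of the Monte-Carlo coalescent spectrum estimator."""

import numpy as np
import pytest

from peripatry.engine import expected_jsfs, fold_expected
from peripatry.models import Demography, Epoch, build_demography
from peripatry.sfs import JointSFS, fold


def equilibrium_single_pop(n, reps=40_000, seed=1):
    dem = Demography(1.0, (Epoch(40.0, (1.0, 1.0), (1.0, 1.0)),))
    return expected_jsfs(dem, n, 0, reps, seed)


class TestNeutralEquilibrium:
    def test_one_over_i_law(self):
        """E[xi_i] is proportional to 1/i for a constant-size population."""
        n = 8
        es = equilibrium_single_pop(n)
        i = np.arange(1, n)
        vals = es.values[1:n, 0]
        se = es.mc_se[1:n, 0]
        np.testing.assert_array_less(np.abs(vals - 2.0 / i), 3 * se + 1e-12)

    def test_high_migration_approaches_panmixia(self):
        """Two demes glued by strong migration behave as one population."""
        dem = Demography(
            1.0, (Epoch(40.0, (0.5, 0.5), (0.5, 0.5), ((0.0, 50.0), (50.0, 0.0))),)
        )
        n1 = n2 = 4
        es = expected_jsfs(dem, n1, n2, 60_000, 3)
        collapsed = np.zeros(n1 + n2 + 1)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                collapsed[i + j] += es.values[i, j]
        k = np.arange(1, n1 + n2)
        np.testing.assert_allclose(collapsed[1:-1] * k, 2.0, rtol=0.06)


class TestStructure:
    def test_symmetric_demography_transpose_symmetric(self):
        dem = build_demography("sym_mig", dict(nu1=1.0, nu2=1.0, m=1.0, T1=0.5))
        es = expected_jsfs(dem, 5, 5, 60_000, 4)
        err = 3 * (es.mc_se + es.mc_se.T) + 1e-3
        assert np.all(np.abs(es.values - es.values.T) <= err)

    def test_determinism_under_seed(self):
        dem = build_demography("asym_mig", dict(nu1=0.5, nu2=2.0, m12=1.0, m21=0.2, T1=0.7))
        a = expected_jsfs(dem, 6, 6, 5_000, 11)
        b = expected_jsfs(dem, 6, 6, 5_000, 11)
        np.testing.assert_array_equal(a.values, b.values)
        c = expected_jsfs(dem, 6, 6, 5_000, 12)
        assert not np.array_equal(a.values, c.values)

    def test_fixed_cells_masked_and_zero(self):
        dem = build_demography("no_mig", dict(nu1=1.0, nu2=1.0, T1=0.5))
        es = expected_jsfs(dem, 4, 4, 2_000, 5)
        assert es.mask[0, 0] and es.mask[4, 4]
        assert es.values[0, 0] == 0.0

    def test_desk_scale_guard(self):
        dem = build_demography("no_mig", dict(nu1=1.0, nu2=1.0, T1=0.5))
        with pytest.raises(ValueError, match="desk-scale"):
            expected_jsfs(dem, 40, 40, 10, 1)

    def test_mc_error_shrinks_with_replicates(self):
        dem = build_demography("sym_mig", dict(nu1=1.0, nu2=1.0, m=0.5, T1=1.0))
        lo = expected_jsfs(dem, 4, 4, 4_000, 21)
        hi = expected_jsfs(dem, 4, 4, 16_000, 22)
        keep = ~lo.mask
        ratio = np.median(lo.mc_se[keep] / np.maximum(hi.mc_se[keep], 1e-12))
        assert 1.6 < ratio < 2.5  # 4x replicates -> ~2x smaller SE


class TestFoldExpected:
    def test_fold_agrees_with_data_folding_rule(self):
        dem = build_demography("asym_mig", dict(nu1=0.5, nu2=2.0, m12=0.8, m21=0.1, T1=0.6))
        es = expected_jsfs(dem, 5, 3, 10_000, 6)
        via_engine = fold_expected(es)
        via_sfs = fold(JointSFS(es.values, mask=es.mask))
        np.testing.assert_allclose(via_engine.values, via_sfs.counts, atol=1e-12)
        np.testing.assert_array_equal(via_engine.mask, via_sfs.mask)

    def test_fold_conserves_unmasked_mass(self):
        dem = build_demography("sym_mig", dict(nu1=2.0, nu2=0.5, m=0.3, T1=0.8))
        es = expected_jsfs(dem, 6, 4, 10_000, 7)
        assert fold_expected(es).unmasked_sum() == pytest.approx(es.unmasked_sum())

    def test_double_fold_rejected(self):
        dem = build_demography("no_mig", dict(nu1=1.0, nu2=1.0, T1=0.5))
        folded = fold_expected(expected_jsfs(dem, 4, 4, 1_000, 8))
        with pytest.raises(ValueError):
            fold_expected(folded)


class TestAgainstMsprime:
    """Independent cross-validation with an external coalescent simulator."""

    @staticmethod
    def to_msprime(dem):
        import msprime

        d = msprime.Demography()
        backs = list(reversed(dem.epochs))

        def gr(ep, pop):
            nr, no = ep.end_sizes[pop], ep.start_sizes[pop]
            return np.log(nr / no) / ep.duration if nr != no else 0.0

        d.add_population(name="p0", initial_size=backs[0].end_sizes[0], growth_rate=gr(backs[0], 0))
        d.add_population(name="p1", initial_size=backs[0].end_sizes[1], growth_rate=gr(backs[0], 1))
        d.add_population(name="anc", initial_size=dem.root_size)
        d.set_migration_rate("p0", "p1", backs[0].migration[1][0])
        d.set_migration_rate("p1", "p0", backs[0].migration[0][1])
        t = backs[0].duration
        for ep in backs[1:]:
            for pop, name in ((0, "p0"), (1, "p1")):
                d.add_population_parameters_change(
                    time=t, population=name, initial_size=ep.end_sizes[pop], growth_rate=gr(ep, pop)
                )
            d.add_migration_rate_change(time=t, source="p0", dest="p1", rate=ep.migration[1][0])
            d.add_migration_rate_change(time=t, source="p1", dest="p0", rate=ep.migration[0][1])
            t += ep.duration
        d.add_population_split(time=t, derived=["p0", "p1"], ancestral="anc")
        d.sort_events()
        return d

    def test_branch_spectrum_matches_msprime(self):
        import msprime

        params = dict(
            nuA=0.683, nu1=0.431, nu2=6.017, m12=1.664, m21=0.547, T1=0.092, T2=0.647, s=0.113
        )
        dem = build_demography("founder_sec_contact_asym_two_epoch", params)
        n1 = n2 = 5
        mine = expected_jsfs(dem, n1, n2, 60_000, 31)
        acc = np.zeros((n1 + 1, n2 + 1))
        reps = 6_000
        s0, s1 = np.arange(n1), np.arange(n1, n1 + n2)
        for ts in msprime.sim_ancestry(
            samples={"p0": n1, "p1": n2},
            demography=self.to_msprime(dem),
            ploidy=1,
            num_replicates=reps,
            random_seed=32,
        ):
            acc += ts.allele_frequency_spectrum(
                sample_sets=[s0, s1], mode="branch", polarised=True, span_normalise=True
            )
        acc /= reps
        keep = ~mine.mask
        a, b = mine.values[keep], acc[keep]
        cosine = a @ b / np.sqrt((a @ a) * (b @ b))
        assert cosine > 0.999
        assert mine.unmasked_sum() == pytest.approx(acc[keep].sum(), rel=0.05)
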
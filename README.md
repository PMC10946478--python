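# peripatry

Demographic model selection for two-population ("mainland–island")
diversification histories from the folded joint site-frequency spectrum
(jSFS), built for RAD-style SNP data. The package implements the full
inference chain used to test peripatric-speciation hypotheses — as in the
*Plagiolepis pyrenaica* / *P. taurica* ant system, where a small peripheral
isolate diverged from a widespread ancestor with later gene flow:

1. **variant_io** — read biallelic SNPs from VCF, apply missingness
   (`--max-missing 0.5`) and mean-depth (`--min-meanDP 5`) filters, thin to
   one random SNP per RAD locus;
2. **sfs** — build the jSFS with per-site hypergeometric downprojection
   (easySFS convention) to absorb missing genotypes, fold, mask fixed cells;
3. **models** — a registry of 16 named diversification models (vicariance,
   founder, old founder, secondary contact) over piecewise two-population
   demographies in coalescent units;
4. **engine** — the θ-free expected jSFS under any registry demography, by
   Monte-Carlo structured-coalescent simulation (numba-accelerated,
   cross-validated against msprime);
5. **fit** — composite Poisson likelihood with analytic θ̂, four-round
   randomized-restart Nelder-Mead optimization in log-parameter space
   (replicate schedule 60/70/70/80), AIC and Akaike weights
   ω_i = exp(−ΔAIC_i/2)/Σ exp(−ΔAIC_j/2);
6. **harness** — ranked multi-model comparisons and the hierarchical
   three-pair design (species pair with the founder/vicariance set, then
   island vs each mainland subgroup with the secondary-contact set);
7. **synthetic_data** — RAD-style toy VCFs and Poisson-sampled spectra with
   known generating truth, so every stage is testable without downloads.

The model at the core: for unlinked sites, the expected number of SNPs with
i derived copies in population 1 and j in population 2 is
(θ/2)·E[L_ij], where L_ij is the total genealogy branch length subtending
(i, j) sampled haploids and θ = 4·N_ref·μ·L. Each jSFS cell is treated as
an independent Poisson count; θ is profiled out analytically and models are
ranked by AIC. See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

Simulate a RAD-style dataset under the published species-pair scenario — a
founder event (founding fraction s = 0.113) with later asymmetric secondary
contact — then recover the spectrum and refit:

```python
import peripatry as pp
from peripatry.presets import PUBLISHED_FITS
from peripatry.synthetic_data import SimConfig, simulate_vcf
from peripatry.variant_io import read_vcf, filter_variants, thin_one_snp_per_locus
from peripatry.sfs import build_jsfs, fold

sc = PUBLISHED_FITS["species_pair"]
cfg = SimConfig(sc.model_name, sc.params, theta=sc.theta, samples=(6, 6),
                missingness=0.1, seed=11)
vt, truth = simulate_vcf(cfg, "sim.vcf")

table = read_vcf("sim.vcf", vt.pop_map)
table = thin_one_snp_per_locus(filter_variants(table), seed=11)
data = fold(build_jsfs(table, (10, 10)))
print(f"{truth['n_sites']} simulated SNPs, {data.unmasked_sum():.1f} in the folded jSFS")

fit = pp.optimize_model(sc.model_name, data,
                        rounds=(10, 10, 10, 20), perturb_folds=(3, 2, 2, 1),
                        seed=1, engine_config=pp.EngineConfig(
                            search_replicates=2000, refit_replicates=25_000,
                            max_evals=120))
print(f"s_hat = {fit.params_hat['s']:.3f}  (generating s = {sc.params['s']})")
print(f"m12_hat/m21_hat = {fit.params_hat['m12'] / fit.params_hat['m21']:.2f}  "
      f"(generating ratio = {sc.params['m12'] / sc.params['m21']:.2f})")
print(f"loglik = {fit.loglik:.1f}, theta_hat = {fit.theta_hat:.1f}, AIC = {fit.aic:.1f}")
```

Output (3 or so minutes on one CPU):

```
1277 simulated SNPs, 903.8 in the folded jSFS
s_hat = 0.404  (generating s = 0.113)
m12_hat/m21_hat = 5.26  (generating ratio = 3.04)
loglik = 2924.9, theta_hat = 41.6, AIC = -5833.8
```

The direction of the migration asymmetry (island→mainland excess,
three-fold in the published fit) is recovered. The fitted founding
fraction illustrates a real property of this scenario: s rides a wide,
upward-biased likelihood ridge at ~10^3 SNPs — point estimates scatter
roughly two-fold around the generating value across seeds (see
`docs/methods.md` on identifiability). A model comparison over a candidate
set is one call:

```python
from peripatry.harness import run_comparison, SelectionConfig
report = run_comparison(data, ["founder_sec_contact_asym_two_epoch",
                               "vic_no_mig", "sym_mig", "sec_contact_asym_mig"],
                        SelectionConfig(rounds=(10, 10, 10, 20), seed=7))
print(report.winner, report.weight_of(report.winner))
```

Shell equivalents: `peripatry filter --vcf sim.vcf --popmap popmap.tsv
--max-missing 0.5 --min-mean-dp 5 --thin-seed 11 --out filtered.vcf` and
`peripatry select --sfs data.fs --models founder_set --seed 7 --out report.json`.

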
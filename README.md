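# ylineage

Analysis toolkit for dating and structuring Y-chromosome haplogroups from
whole-Y resequencing SNPs and Y-STR haplotype panels — the workflow used
to characterise recently radiating paternal lineages such as the North
African clade E-M183 (E-M81).

The package covers the full post-calling pipeline:

- **Filtering** — the standard whole-Y filter cascade: restrict a VCF to
  unique high-quality regions (BED mask, ~4.88 Mb of the Y), keep sites
  supported by ≥ 5 reads ("callable region"), convert heterozygous calls
  (artefacts on the haploid Y) to missing, and drop samples with ≥ 5%
  missingness or mean depth < 10X.
- **Phylogeny & haplogroups** — perfect-phylogeny construction of the SNP
  tree (Y-SNPs are effectively homoplasy-free; four-gamete conflicts are
  a hard error, not silently resolved), assignment of samples against a
  defining-SNP hierarchy (e.g. M183 → SM001 → {Z5009, CTS12227,
  PF6794 → PF6789}), and population frequency tables with starred
  paragroup columns (M183\*, SM001\*, …).
- **Dating** — the rho statistic. For a clade with `l_b` mutations on
  branch *b* carrying `n_b` of *n* tips,

  ```
  ρ  = Σ_b (n_b / n) · l_b          (mean mutations lineage → ancestor)
  σ² = Σ_b (n_b / n)² · l_b         (Saillard estimator)
  T  = ρ / μ                        (rate constancy)
  ```

  with μ = substitution rate × callable length for SNPs (fast
  10⁻⁹/site/year and slow 6.17 × 10⁻¹⁰/site/year presets) or one STR
  mutation per haplotype per 858 years for the YFiler panel.
- **Diversity** — Nei gene diversity with sampling SD, mean pairwise
  differences, per-locus heterozygosity and allele-size variance, and
  Spearman correlations with longitude using exact permutation P-values
  for small population sets.
- **AMOVA** — hierarchical analysis of molecular variance (Excoffier
  variance components, Φ_ST/Φ_SC/Φ_CT, per-component permutation tests)
  for population, group (e.g. coastal vs inland), and subclade designs.
- **Networks** — median-joining networks (minimum spanning network plus
  cost-reducing Steiner medians) with a star-likeness index that
  quantifies the one-step halo of a rapid radiation.
- **Simulation** — a coalescent generator of SNP+STR panels with known
  TMRCA: star, constant-size and growth genealogies; infinite-sites
  Poisson SNP mutations over the callable region; symmetric single-step
  STR mutations. Every estimator above can therefore be validated
  against truth without any external download.

## Worked example

```python
from ylineage import (GenealogyModel, MutationRateSpec, PopulationSpec,
                      drop_snp_mutations, generate_population_panel,
                      simulate_genealogy)
from ylineage.amova import AmovaDesign, amova_with_pvalues
from ylineage.dating import rho_snp, rho_str, tmrca_from_rho
from ylineage.filtering import run_filter_cascade
from ylineage.phylo import build_perfect_phylogeny

rates = MutationRateSpec()   # fast SNP rate over 4.88 Mb; STR rate 1/858 per year

# SNP dating of a simulated 50-tip radiation with true TMRCA 2000 years
tree = simulate_genealogy(GenealogyModel(50, 2000, "star", seed=42))
vm = drop_snp_mutations(tree, rates, seed=43)
vm, cascade = run_filter_cascade(vm, None)
est = tmrca_from_rho(rho_snp(build_perfect_phylogeny(vm)), rates)
print(f"rho = {est.rho:.2f} ± {est.sigma_rho:.2f}  "
      f"TMRCA = {est.tmrca:.0f} y  95% CI [{est.ci_low:.0f}, {est.ci_high:.0f}]")

# STR dating and AMOVA on a two-population panel
pops = [PopulationSpec("West", 25, 2000, longitude=-10.0),
        PopulationSpec("East", 25, 2000, longitude=10.0)]
panel = generate_population_panel(pops, rates, seed=7)
est = tmrca_from_rho(rho_str(panel.strs), rates, mode="str")
print(f"STR rho = {est.rho:.3f}  TMRCA = {est.tmrca:.0f} y "
      f"[{est.ci_low:.0f}, {est.ci_high:.0f}]")
design = AmovaDesign(populations=dict(zip(panel.strs.samples,
                                          panel.strs.populations)))
res = amova_with_pvalues(panel.strs, design, n_perm=999, seed=1)
print(f"AMOVA among-population: {res.percent_variation['among_populations']:.1f}% "
      f"(Phi_ST = {res.phi_statistics['phi_st']:.3f}, P = {res.p_values['phi_st']:.3f})")
```

prints

```
rho = 9.40 ± 0.43  TMRCA = 1926 y  95% CI [1752, 2100]
STR rho = 2.340  TMRCA = 2008 y [1644, 2372]
AMOVA among-population: 33.1% (Phi_ST = 0.331, P = 0.001)
```

The SNP rho (9.40) is the mean number of mutations separating each
sampled chromosome from the common ancestor; dividing by
10⁻⁹ × 4.88 × 10⁶ converts it to years, and the interval covers the
simulated truth of 2000. The STR estimate multiplies rho by 858. The
AMOVA percentage is large here because the two simulated populations
have fully disjoint genealogies; with a shared genealogy it centres on
zero.

A command-line interface mirrors the library
(`ylineage simulate|filter|assign|date|diversity|amova|network|assoc|run`);
`ylineage run --config cfg.yaml` executes the whole pipeline from one
YAML file with a deterministic master seed.

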
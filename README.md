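# mitolineage

Matrilineal analysis of complete human mitochondrial genomes, packaged as a
tested, reusable pipeline. It covers the classical toolchain of mtDNA
population studies — for population geneticists and phylogeographers who
score complete mitogenomes against the rCRS coordinate frame and want every
step scriptable and reproducible:

- **Variant scoring** — reference-anchored global alignment (affine gaps,
  leftmost-normalized) and variant calling in standard mtDNA nomenclature
  (`73`, `16318T`, `249del`, `8281-8289del`, `315.1C`), with IUPAC
  heteroplasmies treated as missing data and the conventional hotspot /
  poly-C masking (`16182`, `16183`, `16519`; nps 303–315 and 16184–16194).
- **Haplogroup classification** against a Phylotree-style motif hierarchy
  (back mutations marked `!`), plus haplogroup and continental-component
  frequency tables.
- **Median-joining networks** of haplotype classes and rooted
  most-parsimonious genealogies (exact minimum Steiner trees on small
  instances via Dreyfus–Wagner over the median closure).
- **ρ-statistic dating** — for a clade genealogy rooted at its founder
  haplotype, ρ is the multiplicity-weighted mean number of mutations from
  each sampled lineage to the root, with the heuristic standard error

      σ² = Σ_edges (n_e / n)² · m_e

  (n_e sampled lineages below edge e, m_e mutations on it). A linear clock
  converts ρ to years; the default complete-genome clock is 1.665×10⁻⁸
  substitutions/site/year over 16,569 sites, and a synonymous clock can be
  driven by the built-in functional annotation of each edge mutation.
- **Diversity statistics** — segregating sites S, haplotype diversity Hd,
  nucleotide diversity π, mean pairwise differences k, and Tajima's
  D = (k − S/a₁) / √(e₁S + e₂S(S−1)), with significance classes from
  neutral coalescent simulation conditioned on S.
- **Population structure** — distance-based AMOVA (2- and 3-level
  variance components, Φ_ST/Φ_SC/Φ_CT with permutation p-values), pairwise
  Φ_ST matrices, and Kruskal nonmetric MDS of the Φ_ST matrix.
- **Coalescent simulator** — Kingman genealogies under constant,
  exponential-growth and two-epoch demographies, mutational hotspots, and a
  finite island model with known equilibrium F_ST ≈ 1/(1+2Nm); every
  dataset ships with a truth table (genealogy, per-branch mutation events,
  clade TMRCAs) so each pipeline stage can be validated against ground
  truth.

The packaged reference sequence is a synthetic stand-in for the rCRS with
the correct length and coordinate anchors (see `docs/methods.md`); analyses
of real mitogenomes should supply the genuine reference, while all internal
logic, tests and simulations are reference-agnostic.

## Worked example: dating a simulated clade

```python
from mitolineage import rho_clock, simulate

model = simulate.DemographicModel(kind="constant", size=320.0)
genealogy = simulate.simulate_genealogy(model, n=30, seed=42)
sequences, truth = simulate.drop_mutations(genealogy, rate=1.665e-8, seed=43)

clade = simulate.truth_to_genealogy(truth)
rho = rho_clock.compute_rho(clade)
sigma = rho_clock.compute_sigma(clade)
est = rho_clock.rho_to_time(rho, sigma, rho_clock.COMPLETE_GENOME_CLOCK,
                            two_sigma=True)
print(f"true TMRCA : {truth.tmrca_years:8.0f} years")
print(f"rho        : {rho:8.3f} mutations")
print(f"sigma      : {sigma:8.3f}")
print(f"estimate   : {est.tmrca_years:8.0f} years "
      f"(2-sigma interval {est.ci_years[0]:.0f} - {est.ci_years[1]:.0f})")
```

prints

```
true TMRCA :    13485 years
rho        :    4.500 mutations
sigma      :    1.457
estimate   :    16312 years (2-sigma interval 5748 - 26876)
```

i.e. the 30 sampled lineages carry on average 4.5 mutations back to the
clade root; at ~1 substitution per 3,624 years genome-wide that converts to
a point estimate of ~16.3 kya, and the 2σ interval brackets the true
simulated age of ~13.5 kya.

## Command line

A thin CLI wraps the library: `mitolineage simulate` writes a synthetic
island-model dataset (FASTA + metadata + truth JSON), and
`mitolineage run-all --config config.yaml` runs the configured stages
(profile → classify → network → date → diversity → structure) into a report
bundle of TSV tables, each stamped with the config hash and seed; reruns
are byte-identical. `mitolineage validate --config ...` reports config
problems (missing files, unmapped samples, singleton populations) without
running anything.

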
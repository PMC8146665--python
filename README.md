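# hapsignal

Haplotype-level selection-signal analysis for phased variation data, built
around the question that arises at candidate insecticide-resistance loci in
*Anopheles* mosquitoes (the motivating case is the cytochrome P450 gene
*Cyp6m2* on chromosome arm 3R): **are the missense alleles segregating at a
gene under recent positive selection, or does their haplotype structure just
reflect demography?**

The package implements the full analysis chain on phased diploid haplotypes:

1. **Effect annotation** — a minimal strand-aware annotator maps biallelic
   SNPs onto a single-transcript gene model, translates reference and
   alternate codons, and emits labels such as `I359V`.
2. **Frequency filtering** — per-(population × species) alt-allele
   frequencies; variants kept when they strictly exceed 5 % in at least one
   cohort.
3. **Haplotype clustering** — pairwise Hamming distances in SNP units over a
   region, hierarchical clustering cut at 7 SNPs; clusters ≥ 1 % named
   C1…Ck by descending size, remainder wild type (`wt`).
4. **Linkage disequilibrium** — signed Lewontin's *D′* ∈ [−1, 1] between all
   variant pairs, pooled and per population (monomorphic cohorts are flagged
   undefined, never silently 0).
5. **Median-joining networks** — Bandelt–Forster–Röhl networks over the
   haplotype sequences; connected components after dropping edges heavier
   than 2 SNPs; concordance of the components with the hierarchical
   clusters.
6. **EHH decay** — extended haplotype homozygosity
   `EHH(x) = Σ_s C(e_s,2) / C(c,2)` around a core region (canonically the
   1689 bp interval 3R:6928858–6930547, half-open), out to 200 kb per side,
   per population, with trapezoidal decay areas for sweep-vs-wild-type
   contrasts.

A bundled forward-time Wright–Fisher simulator (recombination, mutation,
selection on a focal allele, bottleneck epochs) generates phased VCF + sample
panel + truth labels, so the whole chain is testable end to end without any
external data. Sweeps and bottlenecks both slow EHH decay; separating the
two — the selection signal from the demographic confound — is exactly what
the per-population analysis is for.

## Worked example

Run the full pipeline on a simulated selective sweep (two demes are not
needed; one deme, 200 haplotypes):

```bash
hapsignal run --config docs/example_config.toml --seed 3 --out sweep_out
```

which prints

```
wrote sweep_out/manifest.json (14 artefacts)
```

and leaves, among others, `sweep_out/clusters.tsv` (haplotype → cluster),
`sweep_out/dprime.tsv`, `sweep_out/network.graphml` and `sweep_out/ehh.tsv`.
The manifest's report block for this run reads:

```json
{
  "carrier_ehh_area": 27257.675299359507,
  "carrier_group_slowest_decay": true,
  "clusters": {"C1": 190, "C2": 5, "C3": 4},
  "mjn_concordance": 1.0,
  "n_haplotypes": 200,
  "n_high_frequency_variants": 5,
  "n_sites": 300,
  "wt_ehh_area": 17959.73333333333
}
```

Reading: five missense variants pass the 5 % frequency filter; the swept
haplotypes form one dominant cluster (C1, 190 of 200 haplotypes) carrying
the focal allele; the median-joining network components agree with the
hierarchical clusters in full (concordance 1.0); and the focal-allele
carriers' EHH decay area (≈ 27.3 kb·EHH summed over both flanks) exceeds the
wild-type background (≈ 18.0 kb·EHH) — the long-haplotype signature of the
planted sweep. Rerunning with the same seed reproduces every output file
bit-identically (the manifest lists SHA-256 hashes).

The same subcommands work on real inputs: `hapsignal cluster|ld|mjn|ehh
--vcf ... --panel ...` accept any phased VCF and a
`sample_id<TAB>population<TAB>species` panel.

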
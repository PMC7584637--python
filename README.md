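# gnselect

Selection scans for physically clustered genes, built around three analyses
and the seeded simulators that exercise them end to end:

* **Neighborhood LD enrichment** (`gnselect.ld_neighborhood`): squared
  allele-frequency correlation (r²) between biallelic SNPs, focal-gene
  genomic neighborhoods (gene body ± flank, tandem genes merged), counts of
  LD pairs above a threshold per neighborhood, a pooled-variance t-test
  between clustered and non-clustered neighborhood groups, and a tricube
  LOESS curve of LD decay with distance.
* **Pairwise dN/dS** (`gnselect.dnds`): Nei–Gojobori (NG86) counting with
  Jukes–Cantor correction, and a Goldman–Yang single-ω codon model fit by
  maximum likelihood with a χ²(1) likelihood-ratio test against ω = 1.
* **McDonald–Kreitman tests** (`gnselect.mk_tests`): standard MKT with α and
  the neutrality index, the FWW low-frequency cutoff, and the extended MKT
  that estimates and removes weakly deleterious rare polymorphism.
* **Simulators** (`gnselect.synthetic_data`): a forward Wright–Fisher SNP
  panel simulator with an optional selective sweep at a focal position
  (post-fixation or mid-sweep sampling), a codon-pair simulator under the
  same GY94 model as the likelihood code, and a Poisson
  polymorphism/divergence table simulator with a specified adaptive
  fraction. All simulators are pure functions of (config, seed).

SNP panels are haploid-coded biallelic matrices for inbred accessions
(`gnselect.snp_matrix`), read from VCF or a plain sites-by-samples TSV;
loci come from 4–5 column BED (the 13-gene Col-0 oxidosqualene-cyclase
inventory ships with the package, `osc_locus_inventory()`).

## CLI

```sh
# neighborhood LD scan (per-GN pair tables, counts, group t-test, decay)
gnselect ldscan --panel panel.tsv --loci loci.bed --out outdir \
    --flank-bp 50000 --r2-threshold 0.1 --maf-min 0.05

# pairwise dN/dS batch: manifest is "gene<TAB>fasta" (2 CDS records each)
gnselect dnds --manifest genes.tsv --out dnds.tsv

# MK tests (standard + FWW + extended rows)
gnselect mktest --poly poly.tsv --dn 20 --ds 30 --cutoff 0.05 --out mkt.tsv

# simulators
gnselect simulate panel  --config sweep.cfg --seed 1 --out simdir
gnselect simulate codons --n-codons 1000 --t 0.3 --kappa 2 --omega 0.2 \
    --seed 1 --out simdir
gnselect simulate mktable --seed 1 --out simdir
```

Simulator configs are plain `key = value` text files mirroring the
`SweepSimConfig` / `MkSimConfig` fields.

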
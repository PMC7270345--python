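# vdmap — mapping-by-sequencing of pooled mutants

`vdmap` identifies the genomic region, and ultimately the candidate
protein-coding variants, responsible for a recessive phenotype from
whole-genome sequencing of a **pool of homozygous mutants** out of a
forward-genetic cross (e.g. an ENU-mutagenized line outcrossed to a
polymorphic mapping strain, phenotypic F2 offspring pooled and sequenced).
It is aimed at researchers doing variant-discovery mapping (VDM) in model
organisms such as zebrafish, where the raw product of the experiment is a
VCF of pooled variant calls with allele depths.

## The method

Near the causal locus every pooled chromosome carries the
mutagenized-strain haplotype, so variant sites there read out as
homozygous (alt fraction ≈ 1), while strain polymorphisms elsewhere still
segregate (alt fraction ≈ 0.5). The pipeline:

1. **Classifies zygosity** per site from allele depths
   (`f = ad_alt/(ad_ref+ad_alt)`; hom at f ≥ 0.9, het in [0.2, 0.8],
   depth ≥ 10, all configurable).
2. **Maps** each chromosome with Gaussian kernel densities of the hom and
   het SNP positions (bandwidth 1 Mb) and the count-scaled score
   `n_hom·f_hom(x) − n_het·f_het(x)`, whose peak marks the locus; the
   candidate interval is the contiguous region with score ≥ ½ its maximum.
3. **Subtracts background** strain polymorphisms by exact
   (chrom, pos, ref, alt) match against any number of catalogues.
4. **Annotates consequences** against GFF3 transcript models + genome
   FASTA, with HGVS-style `c.` / `p.` notation (e.g. `c.500T>C`,
   `p.L167P`, `c.4_5delCT`, `p.L2fs`).
5. **Triages candidates**: mapped-interval (and optional prior-interval)
   intersection, protein-changing filter, and curated expression /
   conservation flags, with an exactly reconciling audit trail.

A bundled simulator (`vdmap simulate`) generates a synthetic pooled F2
incross — Haldane-linked marker segregation, Poisson coverage, binomial
read sampling with sequencing error, an incomplete background catalogue and
a toy annotated genome — so the whole pipeline can be exercised and
validated without any external data. See `docs/methods.md` for the model
and its assumptions.

## Worked example

Simulate a default cross (5 chromosomes × 50 Mb, causal missense implanted
at chr3:20,000,000 in the toy gene `simB`, 50 pooled mutants, 30×) and run
the full pipeline:

```sh
vdmap simulate --seed 2 --outdir sim
cat > run.yaml <<EOF
vcf: sim/pool.vcf
chrom_lengths: sim/genome.fa.fai   # or a chrom<TAB>length TSV
outdir: out
background:
  - sim/background.tsv
gff3: sim/annotation.gff3
fasta: sim/genome.fa
EOF
samtools faidx sim/genome.fa
vdmap run --config run.yaml
python -m json.tool out/summary.json
```

Key numbers from `out/summary.json` for this run:

```
"mapping":      top_chromosome chr3, interval chr3:13,700,000–29,200,000
"subtraction":  437 hom-alt candidates in, 137 kept, 300 removed
"triage":       137 -> 81 (interval) -> 1 (protein-changing) -> 1 candidate
top candidate:  chr3:20000000  gene simB  missense  c.500T>C  p.L167P
```

Reading: the homozygosity score ranks chr3 first and calls a ~15.5 Mb
interval containing the true locus; background subtraction removes the
catalogued strain SNPs; inside the interval exactly one surviving variant
changes a protein — the implanted Leu→Pro missense, reported with its
coding-DNA and protein notation. `out/density.tsv` holds the raw hom/het
densities and score per 100 kb grid point (plot with `--plot` on
`vdmap map`, or any plotting tool).

Each stage is also available separately (`vdmap classify / map / subtract /
annotate / triage`) and as library functions (`vdmap.partition`,
`vdmap.build_tracks`, `vdmap.subtract`, `vdmap.annotate_all`,
`vdmap.run_triage`, ...).

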
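# Methods

`vdmap` implements variant-discovery mapping (VDM): locating a recessive,
chemically induced mutation from whole-genome sequencing of a single pool of
phenotypic F2 mutants, then narrowing the mapped region to candidate
protein-coding variants. This note records the model, the parameter choices,
the numerical decisions, and what the bundled simulator does and does not
emulate.

## The mapping model

The experiment behind the method: a mutation is induced on one strain
(e.g. by ENU), carriers are outcrossed to a genetically distant mapping
strain, and F2 offspring showing the recessive phenotype are pooled and
sequenced. Every chromosome in the pool was selected to carry the mutant
allele at the causal locus, so markers near the locus are homozygous for the
mutagenized-strain haplotype, while markers elsewhere still segregate ~1:1.

**Zygosity classification.** Each variant's pooled alternate-allele read
fraction `f = ad_alt / (ad_alt + ad_ref)` is thresholded:

| call        | rule (defaults)                   |
|-------------|-----------------------------------|
| ambiguous   | depth < `min_depth` (10)          |
| hom_alt     | `f >= hom_alt_min_fraction` (0.9) |
| het         | `het_low <= f <= het_high` ([0.2, 0.8]) |
| hom_ref     | ref fraction `>= hom_alt_min_fraction`  |
| ambiguous   | anything in the gaps              |

The thresholds are conventional mapping-by-sequencing values, fully
configurable. Fractions in the gap bands (0.1–0.2, 0.8–0.9 by default) are
deliberately left ambiguous rather than forced into a class; this keeps the
two density inputs clean at the cost of discarding a few markers. Band
edges are inclusive. The hom_ref test is written on the reference fraction
(not `f <= 1 - 0.9`) so that swapping the two depths maps hom_alt to
hom_ref exactly, including in floating point.

**Density mapping.** For each chromosome, the positions of hom_alt SNVs and
of het SNVs are smoothed with a plain Gaussian KDE,
`f(x) = (1/(n h)) Σ_i φ((x − p_i)/h)`, evaluated on a regular grid spanning
[0, chromosome length]. Defaults: bandwidth `h` = 1 Mb, grid step = 100 kb —
the megabase scale on which linkage disequilibrium with the causal locus
decays in an F2 cross. The per-chromosome mapping signal is the
count-scaled difference

    score(x) = n_hom · f_hom(x) − n_het · f_het(x)

(units: SNPs/bp). Count scaling matters: each KDE integrates to 1, so a
chromosome with a single stray hom_alt call would otherwise produce the
tallest "density" genome-wide. Multiplying by the contributing counts makes
the score an (unnormalized) local excess of homozygous over heterozygous
markers, which is the VDM signature: high hom density co-located with a het
depletion. Chromosomes are ranked by maximum score (ties: name order); the
candidate interval is the maximal contiguous grid run around the peak with
`score >= 0.5 · max` (fraction configurable), reported half-open in bp. A
signal that is nowhere positive yields an explicit no-interval status.

No boundary correction is applied to the KDE; densities near chromosome
ends are attenuated by the kernel mass falling outside the data range. A
causal locus within ~2–3 bandwidths of a telomere will therefore have a
slightly displaced peak. Both raw densities are always written to the
density TSV so any other combination can be recomputed downstream. Indels
are excluded from the density input (the statistic is defined over SNPs)
but retained for annotation.

**Background subtraction.** Known strain polymorphisms (sequencing of the
mapping strain, published catalogues) are removed by exact
(chrom, pos, ref, alt) match — never by position alone, so a causal allele
that coincides with a known polymorphic position survives. Any number of
catalogue files (VCF or 4-column TSV) is accepted; removals are attributed
per source file.

**Consequence annotation.** Surviving variants are annotated against
transcript models (GFF3 + FASTA). c. numbering starts at the A of the start
codon and counts spliced coding bases, strand-aware. SNVs in the CDS are
translated per codon (missense/nonsense/stop_loss/synonymous); CDS indels
are frameshift iff their length is not a multiple of 3; variants touching
the two intronic bases flanking an exon are splice_site; other transcript
positions are noncoding, everything else intergenic. Only the notation
subset the workflow needs is emitted: `c.NX>Y`, `c.N_MdelXY`, `c.N_MinsXY`,
`p.XNY`, `p.XN*`, `p.XNfs`, `p.XN=`. The genome's reference base at every
annotated site must equal the variant's ref allele; a mismatch is fatal by
design, because it almost always indicates a coordinate-convention bug.
Severity order for per-variant summaries: frameshift = nonsense > stop_loss
> missense > splice_site > inframe_indel > synonymous > noncoding >
intergenic (stop_loss has no conventional slot in this shortlist; it is
placed just below nonsense).

**Triage.** Candidates (the hom_alt stream — a recessive causal mutation is
homozygous in the pool) are intersected with the called mapping interval
(and an optional prior genetic interval, e.g. from coarse marker mapping,
supplied as BED), filtered to protein-changing consequences
(missense, nonsense, stop_loss, frameshift, inframe_indel, splice_site —
splice_site included because a splice disruption is protein-changing in
effect), then screened against curated gene flags: *expressed during early
development* and *site in a conserved region*, each true/false/unknown.
A `false` eliminates; `unknown` never eliminates, it only ranks the
candidate lower. Conservation may be flagged per gene or per site
(per-site overrides). Every stage is audited; the pipeline refuses to
write a summary whose counts do not reconcile exactly.

Interval membership compares a variant's 1-based position against the
half-open `[start, end)` pair, so the end coordinate is always exclusive.

## The simulator

`simulate_pool` emulates the pooled F2 design at the VCF level (no reads):

- Strain markers are placed by a Poisson process (mean spacing 50 kb).
- On the causal chromosome, each of the `2 n_mutants` pooled chromosomes
  carries the mutagenized-strain allele at a marker independently with
  probability `1 − r(d)`, where `d = |pos − causal_pos| · cM_per_Mb / 100`
  Morgans and `r` is the Haldane map function `r(d) = (1 − e^{−2d})/2`
  (no crossover interference; a single uniform 1.25 cM/Mb map rate).
  Off-causal chromosomes use probability 0.5.
- Site depth ~ Poisson(30); alternate reads ~ Binomial(depth,
  q(1−ε) + (1−q)ε) with q the realized haplotype fraction and ε = 0.005
  the per-read error rate. The causal site is emitted at q = 1.
- 70% of markers (never the causal site) are listed in the emitted
  background catalogue, mimicking an incomplete strain SNP list.
- A toy annotation is written around the causal site: three single-exon
  genes (one on the minus strand), the middle one harboring the causal base
  at phase 1 of a CTG codon so the implanted change is a Leu→Pro missense.

Defaults (5 × 50 Mb chromosomes, causal at 20 Mb, 50 pooled mutants, 30×)
are genre-typical for a zebrafish-style cross and are the conditions under
which the acceptance checks run.

Determinism: chromosomes are processed in name order with independent child
RNG streams for (a) reference sequence and (b) markers; within the marker
stream, all inter-marker spacings are drawn first, then per site in
coordinate order the haplotype count, depth, alternate reads and background
flag. Identical configs give byte-identical files, and skipping the
FASTA/GFF3 (`write_genome=False`) perturbs nothing else.

What the simulator does *not* emulate: read mapping artifacts (mismapping,
indel realignment, allele bias), non-uniform recombination maps,
interference, copy-number variation, pool-construction unevenness, or
caller-specific filtering. Passing tests therefore demonstrate the
statistical machinery under the idealized segregation/sampling model, not
robustness to alignment noise in real data.

## Numerical and design choices

- KDE evaluation is vectorized in grid chunks; it equals the brute-force
  double loop to ~1e-15 relative (tests enforce 1e-9).
- `haldane_r` clamps to `nextafter(0.5, 0)` so the strict bound r < 0.5
  survives the underflow of `e^{−2d}` at double precision (d ≳ 19 Morgans).
- Peak ties take the lowest genomic coordinate (first argmax); chromosome
  ties rank by name.
- The survivor/removed VCFs are minimal reconstructions from the variant
  fields (fixed header, sorted records, no timestamps) so pipeline reruns
  are byte-identical.
- Multi-allelic records are split into per-alt variants sharing the
  reference depth; records without parseable allele depths are skipped and
  counted.
- Problem sizes in the test-suite: the 20-seed recovery checks run the
  default 5 × 50 Mb cross through classification and mapping (the stages
  the statistic depends on); full end-to-end runs including annotation and
  triage use 3-chromosome genomes of 4–6 Mb over a handful of seeds, which
  exercises every stage at identical per-base parameters.

## Known limitations

- No likelihood or Bayesian interval: the peak interval is a
  fraction-of-maximum cut, adequate for triage but without coverage
  guarantees.
- The annotation subset is not a full HGVS implementation (no
  normalization/3'-shifting of indels, no delins beyond the equal-length
  case, no multi-transcript phased effects).
- Triage flags are consumed as curated inputs; the package computes neither
  expression nor conservation.
- c. coordinates follow HGVS CDS numbering (c.1 = A of ATG). Published
  reports sometimes number from the transcript start instead; such
  coordinates will disagree with this package's output by the 5' UTR
  length.
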
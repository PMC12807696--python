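# haploprot

Haplotype-resolved proteoform reconstruction and fitness scoring from phased
cohort genotypes.

Most variant-effect tools score one variant at a time, but variants on the
same chromosome copy are inherited — and translated — together. `haploprot`
reconstructs, for every protein-coding transcript, the *haplotypes* a phased
diploid cohort actually carries (the specific combinations of alternative
alleles across the variant sites in the coding sequence), generates the
corresponding protein sequences including indel-, truncation- and
readthrough-derived forms, computes global and per-population haplotype
frequencies, and scores every proteoform with pseudo-log-likelihood-based
fitness metrics through a pluggable scorer interface. It is aimed at
population and medical geneticists who want haplotype-level (rather than
variant-level) functional impact tables from a phased VCF.

## The metrics

For a protein sequence *x* of length *L*, a scorer provides a
pseudo-log-likelihood

```
PLL(x) = Σ_{i=1..L} log p(x_i | x)
```

The impact of a mutant proteoform x^mt is measured relative to two
references from the same transcript:

```
PLLR_wt(x^mt) = PLL(x^mt) − PLL(x^wt)      (wild type)
PLLR_mf(x^mt) = PLL(x^mt) − PLL(x^mf)      (most frequent haplotype)
```

with lower values meaning greater predicted impairment, and each transcript
*t* is summarised by the spread over its retained haplotype set H_t:

```
PLL_delta(t) = max_{h∈H_t} PLL(h) − min_{h∈H_t} PLL(h)
```

External per-variant pathogenicity probabilities s̃ (AlphaMissense-style)
are mapped to log-odds, `s = ln(s̃/(1−s̃))`, and aggregated per haplotype as
the mean and the sum of the variant logits.

Haplotypes with global frequency ≥ 0.5% are retained for scoring (the wild
type always is), and proteoforms shorter than 10 or longer than 4000 amino
acids are excluded by QC. Translation applies explicit edge rules: start-loss
rescued at the next in-frame ATG, premature stops truncating, frameshifts
reading through in the shifted frame until the first stop (extending into
the 3′UTR when available).

Heavy protein language models (ESM-2-style masked marginals, autoregressive
family models, structure-conditioned models) are *plugins*: anything with a
`name` and a `score(protein) -> float` satisfies the scorer contract and can
be registered. Two deterministic unigram scorers ship with the package.

## Worked example

```bash
haploprot simulate --out sim --seed 3 --n-per-pop 20 --n-transcripts 2
haploprot build --vcf sim/cohort.vcf --gtf sim/annotation.gtf \
    --fasta sim/genome.fa --popmap sim/popmap.tsv --out build.tsv
haploprot score --build build.tsv \
    --scorer unigram-uniform,unigram-natural --out scored.tsv
```

`build` logs its stage counts to stderr:

```
#STAT variants_read=14
#STAT transcripts=2
#STAT haplotypes_observed=18
#STAT haplotypes_retained=18
#STAT proteoforms_qc_pass=18
```

meaning: 14 biallelic sites fell in the two transcripts' CDS; across 40
samples (80 chromosomes per transcript) 18 distinct haplotypes were
observed (9 per transcript, wild type included), all at ≥ 0.5% global
frequency, and all translated into proteins passing the 10–4000 aa QC
window. `scored.tsv` then carries one row per
(transcript, haplotype) with its frequencies and per-model scores; for
example the designed stop-gain haplotype of transcript T1 shows

```
haplotype_key=40:C>T  consequences=stop_gained  freq_global=0.05
unigram-natural_pll=-38.993  unigram-natural_pllr_wt=133.161
```

a protein truncated from 59 to 13 residues (the large *positive* PLLR under
a unigram model reflects the shorter sequence — direction is
model-dependent, which is exactly why the scorer interface is pluggable),
and `scored.tsv.pll_delta.tsv` reports each transcript's PLL_delta
(`T1 unigram-natural 135.654 n_haplotypes=9`). Finally,

```bash
haploprot analyze --scored scored.tsv --variant-set my_ids.txt \
    --scorer unigram-natural --seed 7 --out-prefix an
```

annotates haplotypes by a variant-id list, runs a 100-replicate bootstrap of
the median PLLR_wt per group, and writes the replicate table plus a JSON
summary with each group's median-of-medians and the fraction of replicate
pairs ordered in-set < out-set.

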
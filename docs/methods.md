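# Methods

## Pipeline model

`haploprot` treats a phased diploid VCF as 2N observed chromosome copies.
For each protein-coding transcript it restricts attention to the biallelic
variants whose full REF span lies inside the CDS intervals, re-expresses
them in transcript coordinates (reverse-complementing alleles on
minus-strand transcripts), and reads each chromosome's haplotype directly
off the phase of the genotype pairs. A haplotype is the set of alternative
alleles one chromosome carries across those sites; its canonical key sorts
the constituent variants by CDS position and joins `tpos:tref>talt` with
semicolons, with `WT` for the empty set. The wild-type haplotype is always
emitted, even at count 0, so every transcript has its reference row.

Frequencies are plain chromosome fractions, computed globally and within
each population of the sample→population map. Denominators count only
*included* chromosomes: a chromosome is dropped for a transcript when any
of the transcript's sites has a missing allele, an unphased heterozygous
genotype (phase unknown; unphased homozygotes are unambiguous and kept), or
two carried variants overlapping on the CDS (a contradictory phasing).
Dropping affects numerator and denominator symmetrically, so per-population
frequencies still sum to 1 whenever the population has at least one
included chromosome; a population with none reports undefined (`NA`), never
zero. The retention filter keeps haplotypes at global frequency ≥ 0.5%
(`--min-freq`, default 0.005) plus the wild type, and deliberately does not
renormalise: reported values stay cohort frequencies. Ploidy is fixed at
two; hemizygous sex-chromosome calls are taken as the VCF presents them.

## Sequence editing and translation

Edits are applied to the wild-type CDS in 5′→3′ order with a cumulative
shift tracker: each variant's position refers to the unedited CDS and is
relocated by the summed length changes of the edits before it. The
reference allele is validated twice — once against the reference-derived
CDS at mapping time and again at the shifted position at edit time — and a
mismatch raises rather than producing a silent chimera. This left-to-right
scheme is provably equivalent to applying edits in descending coordinate
order with no tracking, which is the independent oracle the tests use.

Translation walks codons under the standard genetic code (table 1 only;
selenocysteine recoding is unsupported) with these rules:

* **start-loss** — if the edited CDS no longer begins `ATG`, scan offsets
  0, 3, 6, … of the *annotated* frame for the next `ATG` and translate from
  there (`start_rescued`). Out-of-frame ATGs are ignored: "in frame" is
  only meaningful relative to the annotated frame. If no in-frame ATG
  exists the proteoform is emitted with `qc=fail:no_start` rather than
  dropped, so counts stay auditable.
* **premature stop** — a stop codon before the last complete codon of the
  edited CDS truncates the protein (`truncated_premature_stop`). The
  terminal stop is never included in the protein.
* **frameshift / stop-loss readthrough** — when no stop occurs inside the
  edited CDS, translation continues into the transcript's exonic 3′
  sequence when one is available (`extended_readthrough`), else ends at the
  last complete codon (`no_stop_reached`). Frameshifts (net length change
  ≢ 0 mod 3) need no special frame bookkeeping: the shifted frame arises
  from the edit itself. Stop-loss uses the same machinery, as no separate
  rule is defensible for it.

Consequence labels (Sequence Ontology terms: synonymous, missense,
stop_gained, stop_lost, start_lost, inframe_insertion/deletion, frameshift)
are computed internally by applying each variant *alone* to the wild-type
CDS and diffing the translations — no external annotator is invoked.
QC passes proteins of 10–4000 aa inclusive; the bounds are scorer-driven
(very short peptides and very long proteins are outside the reliable range
of current protein language models) and are exposed as `--min-len/--max-len`.

GTF `stop_codon` features are merged into the CDS at read time (GENCODE
GTFs exclude the stop from CDS), so a complete wild-type annotation
translates cleanly end-to-end with no flags.

## Scoring

The scorer contract is a `name` plus `score(protein) -> float`; anything
deterministic and finite over the 20 standard residues qualifies, and heavy
protein language models are expected to be wrapped as such plugins. The two
bundled unigram scorers (`unigram-uniform`, `unigram-natural`, the latter
using a Swiss-Prot-like background composition) realise the additive PLL
structure exactly and make score identities testable in closed form. Each
distinct protein sequence is scored once per model (a sequence-keyed cache;
caching is output-transparent). PLLR_wt and PLLR_mf are plain differences
against the wild-type and most-frequent haplotype PLLs; the most-frequent
tie-break is highest global frequency, then wild type, then smallest
haplotype key, making the choice deterministic. PLL_delta is max−min PLL
over the *retained, QC-passing* haplotypes of a transcript, wild type
included. Scores are kept at double precision internally and written with 6
significant digits.

Logit aggregation of external pathogenicity probabilities uses
`s = ln(s̃/(1−s̃))`, defined on the open interval (0,1) (probabilities are
clipped away from {0,1} by the data generator, and rejected with a domain
error by the function); per-haplotype summaries are the mean and the sum of
the variant logits. Class labels (benign/ambiguous/pathogenic) are carried
through, never recomputed.

## Group statistics

The variant-set comparison annotates each haplotype `in_set` iff it carries
at least one identifier from a user-supplied list (the wild type is always
`out_set`), then bootstraps the median of each group's scores: 100
replicates by default, each the median of a same-size resample with
replacement (classical bootstrap; even-length medians are the mean of the
two central order statistics). Groups resample from seed-offset streams
(`seed+0`, `seed+1`) so they are independent by default, while equal
offsets reproduce coupled draws when a paired construction is wanted. The
summary reports each group's median of replicate medians and the fraction
of replicate pairs ordered a < b — the replicate distributions themselves
are written out rather than a named test, since the comparison is
descriptive. Pearson correlations (scipy, t-transform p-value, listwise
missing-data deletion, NaN marker on zero variance) summarise inter-model
agreement of PLLR_wt and PLL_delta.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline is built for:
multi-exon plus- and minus-strand transcripts with canonical GT–AG introns
on a random genome, a designed variant per consequence class (synonymous,
missense, stop-gain, start-loss, in-frame insertion and deletion,
frameshift) at reserved, non-overlapping codon slots, and designed
haplotypes (wild type, one singleton per variant, one cis substitution
pair) assigned to chromosomes by categorical sampling. Sampling whole
haplotypes — not per-site genotypes — makes the designed frequencies exact
targets up to binomial noise, at the price of not modelling recombination,
mutation-rate heterogeneity or demography; per-site LD is implied, not
simulated. The default cohort is 500 samples in five populations of 100
(1000 chromosomes), the size at which a designed frequency p is recovered
within 3·√(p(1−p)/2n) with comfortable margin; the default haplotype
distribution gives the wild type 0.6 and splits 0.4 equally among the
designed alternatives so that every designed haplotype clears the retention
threshold. The 3′UTR embeds a short block containing stop codons in all
three frames so frameshift readthrough terminates deterministically inside
the annotation. AlphaMissense-style probabilities for designed missense
variants are Beta-distributed (concentration 20) around means drawn once
per variant.

Ground truth is produced by *independent* machinery: descending-coordinate
edit application (no shift tracker) and a separate codon walker over
Biopython's translation table. Passing the ground-truth check therefore
shows the pipeline agrees with a second implementation of the stated rules
on exactly the designed conditions; it does not validate behaviour on real
annotation pathologies (partial CDS, non-canonical splice structures,
overlapping genes), which the readers reject or flag rather than model.

## Numerical and design notes

* Coordinates: external formats keep native 1-based inclusive conventions;
  conversion to internal arithmetic happens once, at the I/O boundary.
* Multi-allelic records are decomposed at read time; downstream haplotype
  keys assume biallelic sites. Unphased heterozygotes are treated as
  missing rather than pseudo-phased, which would silently corrupt
  frequencies.
* All randomness (simulation, bootstrap) flows through
  `numpy.random.default_rng` seeds; with deterministic scorers the whole
  pipeline is byte-reproducible, which the test suite asserts end-to-end.
* The acceptance script measures at the default cohort size (500 samples,
  two 60-codon transcripts, two unigram models) — sizes chosen so designed
  frequencies are estimable to a few tenths of a percent while the whole
  run completes in seconds.
* Known limitations: no splice-site or UTR-regulatory effects, no NMD
  prediction, no statistical phasing or imputation, no frequency confidence
  intervals, and no reproduction of database-scale cohort counts, which
  require full public-cohort downloads and GPU-scale model inference.
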
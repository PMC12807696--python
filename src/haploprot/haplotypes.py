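"""Transcript-space variant mapping, haplotype enumeration and frequencies.

A haplotype here is the set of alternative alleles one chromosome copy
carries across the variant sites inside one transcript's coding sequence.
Each diploid sample contributes two chromosomes; the phase of the VCF
genotypes decides which alleles travel together, so a compound heterozygote
in cis and in trans yield different haplotype multisets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import reverse_complement

from .io_formats import (
    MISSING,
    PhasedGenotypes,
    PopulationMap,
    TranscriptModel,
    Variant,
)

log = logging.getLogger(__name__)

WT_KEY = "WT"

#: global-frequency retention threshold: haplotypes at >=0.5% are scored,
#: the wild type always is.
DEFAULT_MIN_GLOBAL_FREQ = 0.005


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the reference-derived CDS."""


@dataclass(frozen=True)
class TranscriptVariant:
    """A genomic variant re-expressed in transcript (CDS) coordinates.

    ``tpos`` is the 1-based position of the first affected CDS base in 5'->3'
    transcript orientation; on minus-strand transcripts ``tref``/``talt`` are
    the reverse complements of the genomic alleles.
    """

    source: Variant
    tpos: int
    tref: str
    talt: str

    @property
    def tend(self) -> int:
        """1-based inclusive CDS position of the last tref base."""
        return self.tpos + len(self.tref) - 1

    @property
    def shift(self) -> int:
        return len(self.talt) - len(self.tref)

    @property
    def label(self) -> str:
        return f"{self.tpos}:{self.tref}>{self.talt}"


@dataclass
class Haplotype:
    """One observed combination of alternative alleles on a transcript."""

    transcript_id: str
    alt_set: tuple[TranscriptVariant, ...]
    key: str
    count: int = 0
    freq_global: Optional[float] = None
    freq_by_pop: dict[str, Optional[float]] = field(default_factory=dict)
    # (sample, chromosome index) provenance, used for population frequencies
    carriers: list[tuple[str, int]] = field(default_factory=list)

    @property
    def is_wildtype(self) -> bool:
        return not self.alt_set

    @property
    def variant_ids(self) -> list[str]:
        return [tv.source.id for tv in self.alt_set if tv.source.id]


def haplotype_key(alt_set: Sequence[TranscriptVariant]) -> str:
    """Canonical identifier: variants sorted by tpos, "tpos:tref>talt" joined."""
    if not alt_set:
        return WT_KEY
    return ";".join(tv.label for tv in sorted(alt_set, key=lambda t: t.tpos))


def cds_genomic_positions(model: TranscriptModel) -> list[int]:
    """Genomic positions (1-based) of CDS bases in transcript 5'->3' order."""
    positions: list[int] = []
    for s, e in model.cds:
        positions.extend(range(s, e + 1))
    if model.strand == "-":
        positions.reverse()
    return positions


def extract_cds(model: TranscriptModel, reference: Mapping[str, str]) -> str:
    """Wild-type CDS in transcript orientation from a genome sequence map."""
    if model.chrom not in reference:
        raise KeyError(f"reference lacks chromosome {model.chrom}")
    chrom = reference[model.chrom]
    parts = [chrom[s - 1 : e] for s, e in model.cds]
    seq = "".join(parts)
    return reverse_complement(seq) if model.strand == "-" else seq


def extract_downstream(
    model: TranscriptModel, reference: Mapping[str, str]
) -> str:
    """Exonic sequence 3' of the CDS in transcript orientation (the 3'UTR).

    Used to extend translation past the annotated stop for frameshift or
    stop-lost readthrough.
    """
    chrom = reference[model.chrom]
    exonic: list[int] = []
    for s, e in model.exons:
        exonic.extend(range(s, e + 1))
    if model.strand == "-":
        exonic.reverse()
    cds_set = {p for s, e in model.cds for p in range(s, e + 1)}
    # positions after the last CDS base in transcript order
    try:
        last_idx = max(i for i, p in enumerate(exonic) if p in cds_set)
    except ValueError:
        return ""
    tail = exonic[last_idx + 1 :]
    bases = [chrom[p - 1] for p in tail]
    if model.strand == "-":
        return "".join(reverse_complement(b) for b in bases)
    return "".join(bases)


def map_variants_to_transcript(
    variants: Sequence[Variant],
    model: TranscriptModel,
    reference: Mapping[str, str],
) -> list[TranscriptVariant]:
    """Project genomic variants onto a transcript's CDS coordinates.

    Only variants whose whole REF span lies inside the CDS intervals are
    returned (a span crossing a CDS boundary or an intron is dropped).
    Alleles are validated against the reference-derived CDS; a mismatch
    raises :class:`ReferenceMismatchError` naming the variant.
    """
    positions = cds_genomic_positions(model)
    offset_of = {g: i for i, g in enumerate(positions)}
    cds = extract_cds(model, reference)
    out: list[TranscriptVariant] = []
    for v in variants:
        if v.chrom != model.chrom:
            continue
        span = range(v.pos, v.end + 1)
        if not all(g in offset_of for g in span):
            continue
        if model.strand == "+":
            tpos = offset_of[v.pos] + 1
            tref, talt = v.ref, v.alt
        else:
            tpos = offset_of[v.end] + 1
            tref = reverse_complement(v.ref)
            talt = reverse_complement(v.alt)
        observed = cds[tpos - 1 : tpos - 1 + len(tref)]
        if observed != tref:
            raise ReferenceMismatchError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} "
                f"({model.transcript_id} tpos {tpos}): expected CDS allele "
                f"{tref!r}, found {observed!r}"
            )
        out.append(TranscriptVariant(source=v, tpos=tpos, tref=tref, talt=talt))
    out.sort(key=lambda tv: tv.tpos)
    return out


def _overlapping(alt_set: Sequence[TranscriptVariant]) -> bool:
    ordered = sorted(alt_set, key=lambda t: t.tpos)
    return any(
        b.tpos <= a.tend for a, b in zip(ordered, ordered[1:])
    )


def build_haplotypes(
    tvariants: Sequence[TranscriptVariant],
    genotypes: PhasedGenotypes,
    transcript_id: Optional[str] = None,
) -> list[Haplotype]:
    """Enumerate per-chromosome haplotypes from phased genotypes.

    Each sample contributes two chromosomes in VCF pair order. A chromosome
    is excluded entirely from counting when, at any of the transcript's
    sites, its allele is missing or the genotype is an unphased heterozygote
    (phase unknown); unphased homozygotes are unambiguous and kept. A
    chromosome carrying two CDS-overlapping variants is contradictory and is
    excluded with a warning. The wild-type haplotype is always present in
    the output, possibly with count 0.
    """
    tid = transcript_id or (
        tvariants[0].source.chrom if tvariants else "transcript"
    )
    site_idx = genotypes.site_index()
    rows = []
    for tv in tvariants:
        s = tv.source
        i = site_idx.get((s.chrom, s.pos, s.ref, s.alt))
        if i is None:
            raise KeyError(
                f"genotypes do not cover variant {s.chrom}:{s.pos} {s.ref}>{s.alt}"
            )
        rows.append(i)

    haps: dict[str, Haplotype] = {
        WT_KEY: Haplotype(transcript_id=tid, alt_set=(), key=WT_KEY)
    }
    for j, sample in enumerate(genotypes.samples):
        # decide chromosome-level usability first
        usable = [True, True]
        for i in rows:
            a, b = genotypes.alleles[i, j]
            phased = genotypes.phased[i, j]
            for k, allele in enumerate((a, b)):
                if allele == MISSING:
                    usable[k] = False
            if not phased and a != b:
                usable[0] = usable[1] = False  # unphased het: phase unknown
        for k in range(2):
            if not usable[k]:
                continue
            carried = tuple(
                tv
                for tv, i in zip(tvariants, rows)
                if genotypes.alleles[i, j, k] == 1
            )
            if _overlapping(carried):
                log.warning(
                    "sample %s chromosome %d carries overlapping variants on "
                    "%s; chromosome excluded",
                    sample,
                    k,
                    tid,
                )
                continue
            key = haplotype_key(carried)
            hap = haps.get(key)
            if hap is None:
                hap = Haplotype(transcript_id=tid, alt_set=carried, key=key)
                haps[key] = hap
            hap.count += 1
            hap.carriers.append((sample, k))
    # stable order: WT first, then by key
    out = [haps[WT_KEY]]
    out.extend(
        h for k, h in sorted(haps.items()) if k != WT_KEY
    )
    return out


def compute_frequencies(
    haplotypes: Sequence[Haplotype], popmap: Optional[PopulationMap] = None
) -> list[Haplotype]:
    """Fill global and per-population frequencies in place.

    Denominators are the included chromosomes (globally, and restricted to
    each population). A population with zero included chromosomes gets
    ``None`` (undefined), never 0.
    """
    total = sum(h.count for h in haplotypes)
    pops = popmap.labels() if popmap is not None else []
    pop_totals = {p: 0 for p in pops}
    if popmap is not None:
        for h in haplotypes:
            for sample, _k in h.carriers:
                p = popmap.get(sample)
                if p is not None:
                    pop_totals[p] += 1
    for h in haplotypes:
        h.freq_global = h.count / total if total else None
        h.freq_by_pop = {}
        for p in pops:
            if pop_totals[p] == 0:
                h.freq_by_pop[p] = None
            else:
                n_p = sum(
                    1
                    for sample, _k in h.carriers
                    if popmap.get(sample) == p
                )
                h.freq_by_pop[p] = n_p / pop_totals[p]
    return list(haplotypes)


def filter_haplotypes(
    haplotypes: Sequence[Haplotype],
    min_global_freq: float = DEFAULT_MIN_GLOBAL_FREQ,
) -> list[Haplotype]:
    """Retain haplotypes at or above the global-frequency threshold plus WT.

    Frequencies are not renormalized after filtering: the reported values
    stay cohort frequencies.
    """
    return [
        h
        for h in haplotypes
        if h.is_wildtype
        or (h.freq_global is not None and h.freq_global >= min_global_freq)
    ]
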
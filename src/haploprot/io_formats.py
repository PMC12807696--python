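"""Readers and writers for the external formats the pipeline touches.

External files keep their native coordinate conventions (VCF and GTF/GFF3 are
1-based inclusive); conversion to the 0-based half-open arithmetic used by the
haplotype/proteoform code happens in exactly one place, at these boundaries.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

_DNA = set("ACGT")

MISSING = -1  # allele index placeholder for "." in a GT field


class FormatError(ValueError):
    """Raised when an input file violates its declared contract."""


@dataclass(frozen=True)
class Variant:
    """One normalized biallelic substitution, insertion or deletion.

    ``pos`` is the 1-based genomic position of the first REF base (VCF
    convention: indels carry a shared anchor base). Multi-allelic sites must
    be decomposed before construction: exactly one ALT per Variant.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self) -> None:
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _DNA:
                raise ValueError(
                    f"{name} allele {allele!r} is not a non-empty A/C/G/T string"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")

    @property
    def end(self) -> int:
        """1-based inclusive genomic position of the last REF base."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's exon/CDS structure on the genome.

    Intervals are 1-based inclusive ``(start, end)`` tuples sorted by genomic
    start; every CDS interval is contained in some exon. ``tsl`` is the
    Ensembl transcript support level (1-5) or ``None`` when unknown.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    tsl: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.cds:
            raise ValueError("transcript has no CDS intervals")
        for iv in self.exons + self.cds:
            if iv[0] > iv[1]:
                raise ValueError(f"malformed interval {iv}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b[0] <= a[1]:
                raise ValueError("exons overlap or are unsorted")
        for c in self.cds:
            if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                raise ValueError(f"CDS interval {c} not contained in any exon")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class PhasedGenotypes:
    """Diploid genotypes for an ordered sample set at decomposed sites.

    ``alleles[i, j]`` is the ordered allele-index pair ``(hapA, hapB)`` of
    sample ``j`` at site ``i`` (0 = ref, 1 = alt, -1 = missing); pair order
    carries phase. ``phased[i, j]`` is the VCF phased flag.
    """

    samples: list[str]
    sites: list[Variant]
    alleles: np.ndarray  # (n_sites, n_samples, 2) int8
    phased: np.ndarray  # (n_sites, n_samples) bool

    def __post_init__(self) -> None:
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.alleles.shape != (n_sites, n_samples, 2):
            raise ValueError("alleles array shape mismatch")
        if self.phased.shape != (n_sites, n_samples):
            raise ValueError("phased array shape mismatch")

    def site_index(self) -> dict[tuple[str, int, str, str], int]:
        return {
            (v.chrom, v.pos, v.ref, v.alt): i for i, v in enumerate(self.sites)
        }


@dataclass(frozen=True)
class PopulationMap:
    """Sample name -> population label (e.g. the five continental groups)."""

    assignments: Mapping[str, str]

    def labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def get(self, sample: str) -> Optional[str]:
        return self.assignments.get(sample)


def read_phased_vcf(
    path: str, region: Optional[tuple[str, int, int]] = None
) -> PhasedGenotypes:
    """Read a multi-sample VCF into decomposed biallelic phased genotypes.

    Multi-allelic records are split into one biallelic :class:`Variant` per
    ALT; a sample's allele index for the decomposed record is 1 when it
    carries that ALT, 0 when it carries any other allele of the site, and -1
    (missing) for ".". ``region`` is an optional 1-based inclusive
    ``(chrom, start, end)`` filter applied to the POS field.
    """
    with pysam.VariantFile(path) as vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: no GT FORMAT field declared")
        samples = list(vf.header.samples)
        sites: list[Variant] = []
        allele_rows: list[np.ndarray] = []
        phased_rows: list[np.ndarray] = []
        for rec in vf:
            if region is not None:
                chrom, start, end = region
                if rec.chrom != chrom or not (start <= rec.pos <= end):
                    continue
            alts = rec.alts or ()
            gts = []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or len(gt) != 2:
                    raise FormatError(
                        f"{path}: sample {s} at {rec.chrom}:{rec.pos} has no "
                        "diploid GT"
                    )
                gts.append((gt, bool(call.phased)))
            for ai, alt in enumerate(alts, start=1):
                if alt is None or set(alt.upper()) - _DNA:
                    continue  # symbolic or spanning-deletion allele
                sites.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        id=rec.id or "",
                    )
                )
                pair = np.empty((len(samples), 2), dtype=np.int8)
                ph = np.empty(len(samples), dtype=bool)
                for j, (gt, phased) in enumerate(gts):
                    for k in (0, 1):
                        a = gt[k]
                        pair[j, k] = MISSING if a is None else int(a == ai)
                    ph[j] = phased
                allele_rows.append(pair)
                phased_rows.append(ph)
    alleles = (
        np.stack(allele_rows)
        if allele_rows
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    phased = (
        np.stack(phased_rows)
        if phased_rows
        else np.empty((0, len(samples)), dtype=bool)
    )
    return PhasedGenotypes(samples, sites, alleles, phased)


def _parse_tsl(raw: str) -> Optional[int]:
    # GENCODE writes e.g. "1", "5", "NA", or "1 (assigned to previous version)"
    tok = raw.strip().split()[0] if raw.strip() else ""
    return int(tok) if tok.isdigit() else None


def read_transcript_models(path: str) -> list[TranscriptModel]:
    """Parse GTF or GFF3 exon/CDS features into :class:`TranscriptModel`\\ s.

    Transcripts with no CDS feature are not emitted; transcripts whose CDS
    falls outside their exons are rejected with a logged
    "incomplete CDS annotation" warning. GTF ``stop_codon`` features are
    merged into the CDS so translated intervals include the stop.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def tx_key(feat) -> Optional[str]:
        if "transcript_id" in feat.attributes:
            return feat.attributes["transcript_id"][0]
        if "Parent" in feat.attributes:
            return feat.attributes["Parent"][0].split(":")[-1]
        return None

    def attr1(feat, *names: str) -> str:
        for n in names:
            if n in feat.attributes:
                return feat.attributes[n][0]
        return ""

    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        ft = feat.featuretype
        if ft not in {"exon", "CDS", "stop_codon"}:
            continue
        key = tx_key(feat)
        if key is None:
            continue
        d = per_tx.setdefault(
            key,
            {
                "exons": [],
                "cds": [],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "gene_id": "",
                "gene_symbol": "",
                "tsl": None,
            },
        )
        iv = (feat.start, feat.end)
        if ft == "exon":
            d["exons"].append(iv)
        else:
            d["cds"].append(iv)
        d["gene_id"] = d["gene_id"] or attr1(feat, "gene_id")
        d["gene_symbol"] = d["gene_symbol"] or attr1(
            feat, "gene_name", "gene_symbol", "Name"
        )
        if d["tsl"] is None and "transcript_support_level" in feat.attributes:
            d["tsl"] = _parse_tsl(feat.attributes["transcript_support_level"][0])

    models: list[TranscriptModel] = []
    for key, d in per_tx.items():
        if not d["cds"]:
            continue
        exons = tuple(sorted(set(d["exons"])))
        # merge adjoining CDS/stop_codon pieces into maximal intervals
        cds_sorted = sorted(set(d["cds"]))
        merged: list[list[int]] = []
        for s, e in cds_sorted:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        try:
            models.append(
                TranscriptModel(
                    transcript_id=key,
                    gene_id=d["gene_id"],
                    gene_symbol=d["gene_symbol"],
                    chrom=d["chrom"],
                    strand=d["strand"],
                    exons=exons,
                    cds=tuple((s, e) for s, e in merged),
                    tsl=d["tsl"],
                )
            )
        except ValueError as exc:
            log.warning(
                "transcript %s rejected: incomplete CDS annotation (%s)", key, exc
            )
    models.sort(key=lambda m: m.transcript_id)
    return models


def read_reference(path: str) -> dict[str, str]:
    """Read a FASTA into an uppercase name -> sequence map.

    Names are the first whitespace-delimited token of each header; duplicate
    names raise, non-ACGTN characters are retained with a warning.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            warnings.warn(
                f"{path}: sequence {rec.id} contains non-ACGTN characters "
                f"{sorted(bad)}; retained as-is"
            )
        seqs[rec.id] = seq
    return seqs


def read_population_map(path: str) -> PopulationMap:
    """Read a two-column sample/population TSV (header row optional)."""
    assignments: dict[str, str] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{ln}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            sample, pop = fields
            if ln == 1 and sample.lower() in {"sample", "sample_id", "name"}:
                continue
            if sample in assignments and assignments[sample] != pop:
                raise FormatError(
                    f"{path}: sample {sample} assigned to both "
                    f"{assignments[sample]} and {pop}"
                )
            assignments[sample] = pop
    return PopulationMap(assignments)


def write_haplotype_table(
    records: Sequence[Mapping[str, object]],
    path: str,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write scored haplotype rows as a (optionally gzipped) TSV.

    Rows are ordered by (transcript_id, haplotype_key) for cross-run
    identity; ``columns`` selects a subset of the record fields.
    """
    all_cols: list[str] = []
    for r in records:
        for c in r:
            if c not in all_cols:
                all_cols.append(c)
    if columns is not None:
        unknown = [c for c in columns if c not in all_cols]
        if unknown and records:
            raise ValueError(
                f"unknown columns {unknown}; valid names: {all_cols}"
            )
        all_cols = list(columns)
    df = pd.DataFrame(list(records), columns=all_cols, dtype=object)
    if {"transcript_id", "haplotype_key"} <= set(all_cols):
        df = df.sort_values(
            ["transcript_id", "haplotype_key"], kind="mergesort"
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, compression="infer")


def read_haplotype_table(path: str) -> pd.DataFrame:
    """Read back a written haplotype TSV with all fields as strings."""
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, compression="infer"
    )
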
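"""Self-contained synthetic cohorts with known ground truth.

Generates a toy diploid cohort — genome FASTA, GTF annotation, phased VCF,
population map and an AlphaMissense-style per-variant probability table —
over multi-exon plus/minus-strand transcripts, with designed variants
covering every retained consequence class (synonymous, missense, stop-gain,
start-loss, in-frame indel, frameshift) and controllable per-haplotype
population frequencies.

Haplotypes are assigned to chromosomes by categorical sampling from the
designed probabilities, so ground-truth frequencies are exact targets
(binomial sampling error only); per-site linkage structure is implied by the
haplotype draws, not modelled. Genome background is random with a fixed
seed; introns are canonical GT..AG so annotations look realistic, but
splicing is never computed.

The GroundTruth edited CDS is produced by descending-coordinate edit
application (no shift tracker) and its translation by an independent
codon walker over Biopython's translate, so the record can serve as an
oracle for the pipeline's 5'->3' shift-tracked engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq, reverse_complement

from .haplotypes import WT_KEY

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]
_NON_ATG = [c for c in SENSE_CODONS if c != "ATG"]

#: default consequence-class mix designed into every transcript
DEFAULT_VARIANT_MIX = {
    "synonymous": 1,
    "missense": 1,
    "stop_gained": 1,
    "start_lost": 1,
    "inframe_insertion": 1,
    "inframe_deletion": 1,
    "frameshift": 1,
}

#: five continental groups at 100 samples each: a 500-sample cohort
DEFAULT_POP_SIZES = {"AFR": 100, "AMR": 100, "EAS": 100, "EUR": 100, "SAS": 100}


@dataclass(frozen=True)
class TranscriptDesign:
    n_exons: int = 2
    n_codons: int = 60
    strand: str = "+"


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``haplotype_probs[t]`` is the categorical distribution over transcript
    ``t``'s designed haplotypes (wild type first, then one singleton per
    designed variant, then one cis pair when two or more substitutions
    exist); ``None`` gives the wild type 0.6 and splits the rest equally.
    """

    pop_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POP_SIZES)
    )
    transcripts: list[TranscriptDesign] = field(
        default_factory=lambda: [
            TranscriptDesign(n_exons=2, n_codons=60, strand="+"),
            TranscriptDesign(n_exons=2, n_codons=60, strand="-"),
        ]
    )
    variant_mix: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_MIX)
    )
    haplotype_probs: Optional[list[list[float]]] = None
    seed: int = 0


@dataclass
class DesignedVariant:
    vid: str
    consequence: str
    tpos: int  # 1-based CDS coordinate
    tref: str
    talt: str
    protein_change: Optional[str] = None  # "K3E" for missense designs


@dataclass
class DesignedHaplotype:
    key: str
    variant_ids: list[str]
    designed_freq: float
    edited_cds: str
    protein: str
    flags: list[str]
    consequences: list[str]


@dataclass
class TranscriptTruth:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds: str
    downstream: str
    haplotypes: list[DesignedHaplotype]


@dataclass
class GroundTruth:
    n_chromosomes: int
    transcripts: list[TranscriptTruth]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class CohortBundle:
    fasta: str
    gtf: str
    vcf: str
    popmap: str
    am_table: str
    ground_truth_json: str
    truth: GroundTruth
    spec: CohortSpec


def _apply_descending(cds: str, variants: Sequence[DesignedVariant]) -> str:
    """Descending-coordinate edit application: no shift tracking needed."""
    seq = cds
    for v in sorted(variants, key=lambda v: -v.tpos):
        start = v.tpos - 1
        assert seq[start : start + len(v.tref)] == v.tref
        seq = seq[:start] + v.talt + seq[start + len(v.tref) :]
    return seq


def _oracle_translate(
    dna: str, downstream: str, net_shift: int, is_wt: bool
) -> tuple[str, list[str]]:
    """Independent rule walker producing (protein, flags) for a truth record."""
    flags: set[str] = set()
    start = 0
    if not dna.startswith("ATG"):
        starts = [
            o for o in range(0, len(dna) - 2, 3) if dna[o : o + 3] == "ATG"
        ]
        if not starts:
            return "", ["no_start"]
        start = starts[0]
        flags.add("start_rescued")
    if net_shift % 3 != 0:
        flags.add("frameshift")
    body = dna[start:]
    seq = body + downstream
    protein = []
    stop_i = None
    for i in range(0, len(seq) - 2, 3):
        aa = str(Seq(seq[i : i + 3]).translate())
        if aa == "*":
            stop_i = i
            break
        protein.append(aa)
    if stop_i is None:
        flags.add("no_stop_reached")
    elif stop_i + 3 > len(body):
        flags.add("extended_readthrough")
    elif stop_i + 3 <= len(body) - 3:
        flags.add("truncated_premature_stop")
    if is_wt:
        flags -= {"no_stop_reached", "extended_readthrough"}
    return "".join(protein), sorted(flags)


def _design_cds(
    design: TranscriptDesign,
    mix: dict[str, int],
    rng: np.random.Generator,
    vid_prefix: str,
) -> tuple[str, list[DesignedVariant]]:
    """Lay out a CDS with reserved codon slots realising each variant class."""
    n = design.n_codons
    n_vars = sum(mix.values())
    rescue_codon = 4
    first_slot = 7
    need = first_slot + 3 * n_vars + 4
    if n < need:
        raise ValueError(
            f"CDS of {n} codons too short for {n_vars} designed variants "
            f"(need >= {need})"
        )
    codons = [_NON_ATG[i] for i in rng.integers(0, len(_NON_ATG), size=n)]
    codons[0] = "ATG"
    codons[rescue_codon] = "ATG"
    codons[-1] = "TAA"

    variants: list[DesignedVariant] = []
    slot = first_slot
    k = 0

    def vid() -> str:
        nonlocal k
        k += 1
        return f"{vid_prefix}{k:03d}"

    classes = [c for c in DEFAULT_VARIANT_MIX if mix.get(c, 0) > 0]
    extra = [c for c in mix if c not in DEFAULT_VARIANT_MIX and mix[c] > 0]
    for cls in classes + extra:
        for _ in range(mix[cls]):
            j = slot
            if cls == "synonymous":
                codons[j] = "GGA"
                variants.append(
                    DesignedVariant(vid(), cls, 3 * j + 3, "A", "T")
                )
            elif cls == "missense":
                codons[j] = "AAA"
                variants.append(
                    DesignedVariant(
                        vid(), cls, 3 * j + 1, "A", "G",
                        protein_change=f"K{j + 1}E",
                    )
                )
            elif cls == "stop_gained":
                codons[j] = "CAA"
                variants.append(
                    DesignedVariant(vid(), cls, 3 * j + 1, "C", "T")
                )
            elif cls == "start_lost":
                if any(v.tpos == 1 for v in variants):
                    raise ValueError("at most one start-loss design per CDS")
                variants.append(
                    DesignedVariant(vid(), cls, 1, "A", "T")
                )
                continue  # uses codon 0, not a slot
            elif cls == "inframe_insertion":
                anchor = codons[j][2]
                variants.append(
                    DesignedVariant(
                        vid(), cls, 3 * j + 3, anchor, anchor + "GCT"
                    )
                )
            elif cls == "inframe_deletion":
                ref = codons[j][2] + codons[j + 1]
                variants.append(
                    DesignedVariant(vid(), cls, 3 * j + 3, ref, ref[0])
                )
            elif cls == "frameshift":
                ref = codons[j][2] + codons[j + 1][0]
                variants.append(
                    DesignedVariant(vid(), cls, 3 * j + 3, ref, ref[0])
                )
            else:
                raise ValueError(f"unknown consequence class {cls!r}")
            slot += 3
    cds = "".join(codons)
    for v in variants:
        assert cds[v.tpos - 1 : v.tpos - 1 + len(v.tref)] == v.tref
    variants.sort(key=lambda v: v.tpos)
    return cds, variants


def _design_haplotypes(
    variants: Sequence[DesignedVariant],
    probs: Optional[Sequence[float]],
) -> list[tuple[list[DesignedVariant], float]]:
    """WT, one singleton per variant, and one cis pair of substitutions."""
    groups: list[list[DesignedVariant]] = [[]]
    groups.extend([v] for v in variants)
    subs = [
        v
        for v in variants
        if len(v.tref) == len(v.talt) == 1 and v.tpos > 3
    ]
    if len(subs) >= 2:
        groups.append([subs[0], subs[1]])
    if probs is None:
        rest = (1.0 - 0.6) / (len(groups) - 1) if len(groups) > 1 else 0.0
        probs = [0.6] + [rest] * (len(groups) - 1)
    if len(probs) != len(groups):
        raise ValueError(
            f"haplotype_probs has {len(probs)} entries for {len(groups)} "
            "designed haplotypes"
        )
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError("haplotype_probs must sum to 1")
    return [(g, float(p)) for g, p in zip(groups, probs)]


def _key(variants: Sequence[DesignedVariant]) -> str:
    if not variants:
        return WT_KEY
    return ";".join(
        f"{v.tpos}:{v.tref}>{v.talt}"
        for v in sorted(variants, key=lambda v: v.tpos)
    )


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def generate_cohort(spec: CohortSpec, outdir: str | Path) -> CohortBundle:
    """Write the full file bundle and return it with its ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    samples: list[tuple[str, str]] = []  # (name, population)
    for pop in sorted(spec.pop_sizes):
        for i in range(spec.pop_sizes[pop]):
            samples.append((f"{pop}{i:04d}", pop))
    n_chrom = 2 * len(samples)

    fasta_recs: list[tuple[str, str]] = []
    gtf_lines: list[str] = []
    vcf_records: list[tuple[str, int, str, str, str, list[str]]] = []
    am_rows: list[dict] = []
    truths: list[TranscriptTruth] = []

    for t_idx, design in enumerate(spec.transcripts):
        tid = f"T{t_idx + 1}"
        gid = f"G{t_idx + 1}"
        chrom = f"chr{t_idx + 1}"
        mix = dict(spec.variant_mix)
        cds, variants = _design_cds(design, mix, rng, f"rs{t_idx + 1}")
        utr5 = _rand_seq(rng, 21)
        utr3 = _rand_seq(rng, 9) + "TAAATAAATAAA" + _rand_seq(rng, 9)
        tx = utr5 + cds + utr3

        # exon split points: codon boundaries in the CDS tail, clear of the
        # designed variant spans
        last_span = max(v.tpos + len(v.tref) - 1 for v in variants)
        safe_from = len(utr5) + 3 * ((last_span + 2) // 3 + 2)
        safe_to = len(utr5) + len(cds) - 6
        n_exons = max(1, design.n_exons)
        cuts = [
            safe_from + 3 * round((safe_to - safe_from) / 3 * f / n_exons)
            for f in range(1, n_exons)
        ]
        pieces = []
        prev = 0
        for c in cuts:
            pieces.append((prev, c))
            prev = c
        pieces.append((prev, len(tx)))

        flank5, flank3 = _rand_seq(rng, 200), _rand_seq(rng, 200)
        sense_parts = [flank5]
        exon_sense: list[tuple[int, int]] = []  # 1-based inclusive, sense
        tmap: dict[int, int] = {}  # transcript offset -> sense pos (1-based)
        gpos = len(flank5)
        for pi, (a, b) in enumerate(pieces):
            if pi > 0:
                intron = "GT" + _rand_seq(rng, 40) + "AG"
                sense_parts.append(intron)
                gpos += len(intron)
            exon_sense.append((gpos + 1, gpos + (b - a)))
            for off in range(a, b):
                tmap[off] = gpos + 1 + (off - a)
            sense_parts.append(tx[a:b])
            gpos += b - a
        sense_parts.append(flank3)
        sense_seq = "".join(sense_parts)
        L = len(sense_seq)

        cds_t0, cds_t1 = len(utr5), len(utr5) + len(cds)  # half-open tx offsets

        def tx_range_to_sense(a: int, b: int) -> list[tuple[int, int]]:
            ivs: list[tuple[int, int]] = []
            for off in range(a, b):
                g = tmap[off]
                if ivs and g == ivs[-1][1] + 1:
                    ivs[-1] = (ivs[-1][0], g)
                else:
                    ivs.append((g, g))
            return ivs

        cds_sense = tx_range_to_sense(cds_t0, cds_t1)

        if design.strand == "-":
            chrom_seq = reverse_complement(sense_seq)
            flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
            exon_g = sorted(flip(iv) for iv in exon_sense)
            cds_g = sorted(flip(iv) for iv in cds_sense)
        else:
            chrom_seq = sense_seq
            exon_g = sorted(exon_sense)
            cds_g = sorted(cds_sense)
        fasta_recs.append((chrom, chrom_seq))

        attrs = (
            f'gene_id "{gid}"; transcript_id "{tid}"; '
            f'gene_name "{gid}X"; transcript_support_level "1";'
        )
        g_start = min(iv[0] for iv in exon_g)
        g_end = max(iv[1] for iv in exon_g)
        st = design.strand
        gtf_lines.append(
            f"{chrom}\tsynth\tgene\t{g_start}\t{g_end}\t.\t{st}\t.\t"
            f'gene_id "{gid}"; gene_name "{gid}X";'
        )
        gtf_lines.append(
            f"{chrom}\tsynth\ttranscript\t{g_start}\t{g_end}\t.\t{st}\t.\t{attrs}"
        )
        for s, e in exon_g:
            gtf_lines.append(
                f"{chrom}\tsynth\texon\t{s}\t{e}\t.\t{st}\t.\t{attrs}"
            )
        for s, e in cds_g:
            gtf_lines.append(
                f"{chrom}\tsynth\tCDS\t{s}\t{e}\t.\t{st}\t0\t{attrs}"
            )

        # designed haplotypes and chromosome assignment
        hap_probs = (
            spec.haplotype_probs[t_idx]
            if spec.haplotype_probs is not None
            else None
        )
        hap_designs = _design_haplotypes(variants, hap_probs)
        probs = np.array([p for _g, p in hap_designs])
        draws = rng.choice(len(hap_designs), size=(len(samples), 2), p=probs)

        # genomic VCF records for every designed variant
        for v in variants:
            t_off = cds_t0 + v.tpos - 1
            sense_first = tmap[t_off]
            sense_last = tmap[t_off + len(v.tref) - 1]
            assert sense_last - sense_first == len(v.tref) - 1, (
                "designed variant crosses an exon junction"
            )
            if design.strand == "-":
                pos = L - sense_last + 1
                ref = reverse_complement(v.tref)
                alt = reverse_complement(v.talt)
            else:
                pos = sense_first
                ref, alt = v.tref, v.talt
            assert chrom_seq[pos - 1 : pos - 1 + len(ref)] == ref
            carrier = np.array(
                [
                    any(dv.vid == v.vid for dv in g)
                    for g, _p in hap_designs
                ]
            )
            gts = [
                f"{int(carrier[draws[j, 0]])}|{int(carrier[draws[j, 1]])}"
                for j in range(len(samples))
            ]
            vcf_records.append((chrom, pos, v.vid, ref, alt, gts))
            if v.consequence == "missense":
                mean = float(rng.uniform(0.1, 0.9))
                conc = 20.0
                p = float(
                    np.clip(
                        rng.beta(mean * conc, (1 - mean) * conc), 1e-6, 1 - 1e-6
                    )
                )
                cls = (
                    "benign"
                    if p < 0.34
                    else ("pathogenic" if p > 0.564 else "ambiguous")
                )
                am_rows.append(
                    {
                        "transcript_id": tid,
                        "variant_id": v.vid,
                        "protein_change": v.protein_change,
                        "probability": f"{p:.6f}",
                        "class": cls,
                    }
                )

        # ground truth per designed haplotype
        hap_truths = []
        for g, p in hap_designs:
            edited = _apply_descending(cds, g)
            net = sum(len(v.talt) - len(v.tref) for v in g)
            protein, flags = _oracle_translate(edited, utr3, net, not g)
            hap_truths.append(
                DesignedHaplotype(
                    key=_key(g),
                    variant_ids=[v.vid for v in g],
                    designed_freq=p,
                    edited_cds=edited,
                    protein=protein,
                    flags=flags,
                    consequences=[v.consequence for v in g],
                )
            )
        truths.append(
            TranscriptTruth(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=design.strand,
                cds=cds,
                downstream=utr3,
                haplotypes=hap_truths,
            )
        )

    # ---- write the bundle ----
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in fasta_recs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")

    vcf = outdir / "cohort.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in fasta_recs:
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(name for name, _p in samples)
            + "\n"
        )
        for chrom, pos, vid, ref, alt, gts in sorted(
            vcf_records, key=lambda r: (r[0], r[1])
        ):
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )

    popmap = outdir / "popmap.tsv"
    with open(popmap, "w") as fh:
        fh.write("sample\tpopulation\n")
        for name, pop in samples:
            fh.write(f"{name}\t{pop}\n")

    am_table = outdir / "am_table.tsv"
    with open(am_table, "w") as fh:
        cols = ["transcript_id", "variant_id", "protein_change", "probability", "class"]
        fh.write("\t".join(cols) + "\n")
        for row in am_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    truth = GroundTruth(n_chromosomes=n_chrom, transcripts=truths)
    gt_json = outdir / "ground_truth.json"
    gt_json.write_text(truth.to_json())

    return CohortBundle(
        fasta=str(fasta),
        gtf=str(gtf),
        vcf=str(vcf),
        popmap=str(popmap),
        am_table=str(am_table),
        ground_truth_json=str(gt_json),
        truth=truth,
        spec=spec,
    )


def ground_truth_check(
    truth: GroundTruth,
    results: dict,
    se_multiplier: float = 3.0,
) -> list[str]:
    """Compare pipeline output against the designed truth.

    ``results`` maps transcript_id -> {haplotype_key -> {"protein", "flags",
    "freq_global"}} as produced by :func:`haploprot.pipeline.build_result_index`.
    Frequencies must fall within ``se_multiplier`` binomial standard errors
    of the designed probability. Returns a list of mismatch descriptions;
    empty means pass.
    """
    issues: list[str] = []
    n = truth.n_chromosomes
    for t in truth.transcripts:
        got = results.get(t.transcript_id)
        if got is None:
            issues.append(f"{t.transcript_id}: missing from results")
            continue
        designed_keys = {h.key for h in t.haplotypes}
        for key in got:
            if key not in designed_keys:
                issues.append(f"{t.transcript_id}: unexpected haplotype {key}")
        for h in t.haplotypes:
            obs = got.get(h.key)
            if obs is None:
                if h.designed_freq > 0:
                    issues.append(
                        f"{t.transcript_id}/{h.key}: designed haplotype absent"
                    )
                continue
            if obs.get("protein") != h.protein:
                issues.append(
                    f"{t.transcript_id}/{h.key}: protein mismatch "
                    f"({obs.get('protein')!r} != {h.protein!r})"
                )
            if sorted(obs.get("flags", [])) != h.flags:
                issues.append(
                    f"{t.transcript_id}/{h.key}: flags "
                    f"{sorted(obs.get('flags', []))} != {h.flags}"
                )
            f = obs.get("freq_global")
            p = h.designed_freq
            tol = se_multiplier * (p * (1 - p) / n) ** 0.5
            if f is None or abs(f - p) > max(tol, 1e-12):
                issues.append(
                    f"{t.transcript_id}/{h.key}: frequency {f} outside "
                    f"{p} +/- {tol:.4g}"
                )
    return issues
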
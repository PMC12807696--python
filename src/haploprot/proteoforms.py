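"""Edit a wild-type CDS with a haplotype's variants and translate it.

Edits are applied sequentially in 5'->3' order with a cumulative position
shift tracker so that insertions and deletions keep subsequent coordinates
correct. Translation uses the standard genetic code with explicit rules for
disruptive variants:

* start-loss: scan for the next in-frame ATG to define the N-terminus
  (``start_rescued``); if none exists the proteoform fails QC (``no_start``);
* premature stop codons truncate the protein (``truncated_premature_stop``);
* frameshifts translate on in the shifted frame until the first stop codon,
  extending into a caller-supplied 3' sequence when one is available
  (``extended_readthrough``) and flagging ``no_stop_reached`` otherwise;
  stop-lost variants reuse the same readthrough machinery.

Proteins shorter than 10 or longer than 4000 amino acids fail QC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .haplotypes import TranscriptVariant, WT_KEY

QC_PASS = "pass"

DEFAULT_MIN_PROTEIN_LEN = 10
DEFAULT_MAX_PROTEIN_LEN = 4000

_CODON = dict(standard_dna_table.forward_table)
_CODON.update({c: "*" for c in standard_dna_table.stop_codons})

# Sequence Ontology consequence labels
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"
INFRAME_INSERTION = "inframe_insertion"
INFRAME_DELETION = "inframe_deletion"
FRAMESHIFT = "frameshift"


class ReferenceMismatchError(ValueError):
    """An edit's expected reference bases were absent at the shifted position."""


@dataclass(frozen=True)
class Proteoform:
    """Edited CDS plus its translation and provenance flags for one haplotype."""

    transcript_id: str
    haplotype_key: str
    dna: str
    protein: str
    flags: frozenset[str]
    consequences: tuple[str, ...]
    qc: str = QC_PASS

    @property
    def qc_pass(self) -> bool:
        return self.qc == QC_PASS


def apply_variants(
    cds: str, tvariants: Sequence[TranscriptVariant]
) -> str:
    """Apply non-overlapping edits left-to-right with cumulative shift tracking.

    Each variant's tpos refers to the unedited CDS; the running shift
    (sum of preceding length changes) relocates it on the partially edited
    string. Reference bases are validated at the shifted position.
    """
    seq = cds
    shift = 0
    last_end = 0
    for tv in tvariants:
        if tv.tpos <= last_end:
            raise ValueError(
                f"overlapping edits at tpos {tv.tpos} (previous ends {last_end})"
            )
        last_end = tv.tend
        start = tv.tpos - 1 + shift
        observed = seq[start : start + len(tv.tref)]
        if observed != tv.tref:
            raise ReferenceMismatchError(
                f"edit {tv.label}: expected {tv.tref!r} at shifted position "
                f"{start + 1}, found {observed!r}"
            )
        seq = seq[:start] + tv.talt + seq[start + len(tv.tref) :]
        shift += tv.shift
    return seq


def rescue_start(dna: str) -> Optional[int]:
    """Offset of the next in-frame ATG (0, 3, 6, ...) or None when absent.

    Meaningful only for a start-lost CDS; offsets not divisible by 3 are
    ignored because "in frame" refers to the annotated reading frame.
    """
    for o in range(0, len(dna) - 2, 3):
        if dna[o : o + 3] == "ATG":
            return o
    return None


def translate_cds(
    dna: str, downstream: Optional[str] = None
) -> tuple[str, frozenset[str]]:
    """Translate an edited CDS codon-by-codon under the standard code.

    The terminal stop is not included in the protein. A stop before the
    last complete codon of ``dna`` flags ``truncated_premature_stop``. When
    no stop occurs inside ``dna``, translation continues into ``downstream``
    (if given) until the first stop, flagging ``extended_readthrough``;
    without one (or when the extension also lacks a stop) the protein ends at
    the last complete codon with ``no_stop_reached``. Trailing bases (<3)
    are ignored.
    """
    if not dna:
        raise ValueError("empty CDS")
    seq = dna + (downstream or "")
    protein: list[str] = []
    flags: set[str] = set()
    stop_at: Optional[int] = None
    i = 0
    while i + 3 <= len(seq):
        aa = _CODON.get(seq[i : i + 3])
        if aa is None:
            raise ValueError(f"non-ACGT codon {seq[i:i+3]!r} at position {i + 1}")
        if aa == "*":
            stop_at = i
            break
        protein.append(aa)
        i += 3
    if stop_at is None:
        flags.add("no_stop_reached")
        # residues translated from the extension still count as readthrough
        if downstream and i > len(dna) - 3:
            flags.add("extended_readthrough")
    elif stop_at + 3 > len(dna):
        flags.add("extended_readthrough")
    elif stop_at + 3 <= len(dna) - 3:
        flags.add("truncated_premature_stop")
    return "".join(protein), frozenset(flags)


def translate_frameshift(
    dna: str, downstream: Optional[str] = None
) -> tuple[str, frozenset[str]]:
    """Translate a frame-shifted CDS; the shifted frame arises from the edit
    itself, so this is plain codon-walking plus the ``frameshift`` flag."""
    protein, flags = translate_cds(dna, downstream)
    return protein, flags | {FRAMESHIFT}


def build_proteoform(
    cds: str,
    tvariants: Sequence[TranscriptVariant],
    transcript_id: str,
    haplotype_key: str = WT_KEY,
    downstream: Optional[str] = None,
    consequences: Sequence[str] = (),
) -> Proteoform:
    """Apply a haplotype's variants and translate under the edge-case rules."""
    dna = apply_variants(cds, tvariants)
    flags: set[str] = set()
    offset = 0
    if not dna.startswith("ATG"):
        if not tvariants:
            # annotation problem, not a variant effect
            return Proteoform(
                transcript_id=transcript_id,
                haplotype_key=haplotype_key,
                dna=dna,
                protein="",
                flags=frozenset(),
                consequences=tuple(consequences),
                qc="fail:incomplete_cds",
            )
        o = rescue_start(dna)
        if o is None:
            return Proteoform(
                transcript_id=transcript_id,
                haplotype_key=haplotype_key,
                dna=dna,
                protein="",
                flags=frozenset({"no_start"}),
                consequences=tuple(consequences),
                qc="fail:no_start",
            )
        flags.add("start_rescued")
        offset = o
    if sum(tv.shift for tv in tvariants) % 3 != 0:
        flags.add(FRAMESHIFT)
    protein, tflags = translate_cds(dna[offset:], downstream)
    flags |= tflags
    if not tvariants:
        # wild type: a complete annotation translates cleanly end-to-end
        flags.discard("no_stop_reached")
        flags.discard("extended_readthrough")
    return Proteoform(
        transcript_id=transcript_id,
        haplotype_key=haplotype_key,
        dna=dna,
        protein=protein,
        flags=frozenset(flags),
        consequences=tuple(consequences),
    )


def qc_filter(
    p: Proteoform,
    min_len: int = DEFAULT_MIN_PROTEIN_LEN,
    max_len: int = DEFAULT_MAX_PROTEIN_LEN,
) -> Proteoform:
    """Set the QC verdict from protein length bounds (closed interval)."""
    if p.qc != QC_PASS:
        return p
    if len(p.protein) < min_len:
        return replace(p, qc="fail:protein_too_short")
    if len(p.protein) > max_len:
        return replace(p, qc="fail:protein_too_long")
    return p


def classify_variant(
    cds: str,
    tv: TranscriptVariant,
    downstream: Optional[str] = None,
) -> str:
    """Consequence label for a single variant applied alone to the CDS."""
    if tv.shift % 3 != 0:
        return FRAMESHIFT
    edited = apply_variants(cds, [tv])
    if cds.startswith("ATG") and not edited.startswith("ATG"):
        return START_LOST
    if tv.shift > 0:
        return INFRAME_INSERTION
    if tv.shift < 0:
        return INFRAME_DELETION
    wt_protein, wt_flags = translate_cds(cds, downstream)
    mt_protein, mt_flags = translate_cds(edited, downstream)
    if mt_protein == wt_protein:
        return SYNONYMOUS
    new = mt_flags - wt_flags
    if "truncated_premature_stop" in new:
        return STOP_GAINED
    if new & {"no_stop_reached", "extended_readthrough"}:
        return STOP_LOST
    return MISSENSE


def classify_consequences(
    cds: str,
    tvariants: Sequence[TranscriptVariant],
    downstream: Optional[str] = None,
) -> tuple[str, ...]:
    """Per-variant labels, each from applying the variant alone and diffing."""
    return tuple(classify_variant(cds, tv, downstream) for tv in tvariants)


def protein_change_label(
    cds: str, tv: TranscriptVariant, downstream: Optional[str] = None
) -> Optional[str]:
    """Compact "K3E"-style label for a missense variant, else None.

    Used to join external per-variant pathogenicity tables keyed by amino
    acid change.
    """
    if classify_variant(cds, tv, downstream) != MISSENSE:
        return None
    wt_protein, _ = translate_cds(cds, downstream)
    mt_protein, _ = translate_cds(apply_variants(cds, [tv]), downstream)
    for i, (a, b) in enumerate(zip(wt_protein, mt_protein), start=1):
        if a != b:
            return f"{a}{i}{b}"
    return None


def proteoform_fasta_records(
    proteoforms: Sequence[Proteoform],
) -> list[tuple[str, str]]:
    """(header, protein) pairs for FASTA export, header "transcript|key"."""
    return [
        (f"{p.transcript_id}|{p.haplotype_key}", p.protein)
        for p in proteoforms
        if p.protein
    ]
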
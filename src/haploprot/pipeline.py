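"""End-to-end orchestration: inputs -> haplotypes -> proteoforms -> scores.

The stages mirror the construction of a haplotype-resolved proteoform score
table: read phased genotypes, annotation and reference; map variants into
each transcript's CDS; enumerate and filter haplotypes; edit and translate;
QC; score with the registered scorer plugins. Intermediate TSVs are the
contract between the CLI subcommands, so each stage can be rerun alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io_formats, proteoforms, scoring
from .haplotypes import (
    DEFAULT_MIN_GLOBAL_FREQ,
    Haplotype,
    WT_KEY,
    build_haplotypes,
    compute_frequencies,
    extract_cds,
    extract_downstream,
    filter_haplotypes,
    map_variants_to_transcript,
)
from .io_formats import PhasedGenotypes, PopulationMap, TranscriptModel
from .proteoforms import Proteoform, build_proteoform, classify_consequences, qc_filter
from .scoring import ScoreRecord, TranscriptScoreSummary

log = logging.getLogger(__name__)


def _fmt(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.6g}"


@dataclass
class TranscriptResult:
    model: TranscriptModel
    cds: str
    downstream: str
    haplotypes_all: list[Haplotype]
    haplotypes_retained: list[Haplotype]
    proteoforms: dict[str, Proteoform]  # keyed by haplotype key


@dataclass
class BuildResult:
    transcripts: list[TranscriptResult]
    populations: list[str]
    stats: dict[str, int] = field(default_factory=dict)

    def to_rows(self) -> list[dict[str, str]]:
        rows = []
        for tr in self.transcripts:
            for h in tr.haplotypes_retained:
                p = tr.proteoforms[h.key]
                row = {
                    "gene_id": tr.model.gene_id,
                    "gene_symbol": tr.model.gene_symbol,
                    "transcript_id": tr.model.transcript_id,
                    "haplotype_key": h.key,
                    "variant_ids": ",".join(h.variant_ids) or ".",
                    "nt_changes": ";".join(tv.label for tv in h.alt_set) or ".",
                    "consequences": ",".join(p.consequences) or ".",
                    "count": str(h.count),
                    "freq_global": _fmt(h.freq_global),
                }
                for pop in self.populations:
                    row[f"freq_{pop}"] = _fmt(h.freq_by_pop.get(pop))
                row["flags"] = ",".join(sorted(p.flags)) or "."
                row["qc"] = p.qc
                row["protein"] = p.protein or "."
                rows.append(row)
        return rows


def run_build(
    vcf: str,
    annotation: str,
    fasta: str,
    popmap: Optional[str] = None,
    min_global_freq: float = DEFAULT_MIN_GLOBAL_FREQ,
    min_len: int = proteoforms.DEFAULT_MIN_PROTEIN_LEN,
    max_len: int = proteoforms.DEFAULT_MAX_PROTEIN_LEN,
    region: Optional[tuple[str, int, int]] = None,
) -> BuildResult:
    """Run the construction pipeline over every annotated transcript."""
    genotypes = io_formats.read_phased_vcf(vcf, region=region)
    models = io_formats.read_transcript_models(annotation)
    reference = io_formats.read_reference(fasta)
    pmap = io_formats.read_population_map(popmap) if popmap else None
    pops = pmap.labels() if pmap else []

    stats = {
        "variants_read": len(genotypes.sites),
        "transcripts": len(models),
        "haplotypes_observed": 0,
        "haplotypes_retained": 0,
        "proteoforms_qc_pass": 0,
    }
    results: list[TranscriptResult] = []
    for model in models:
        if model.chrom not in reference:
            log.warning(
                "transcript %s skipped: chromosome %s absent from reference",
                model.transcript_id,
                model.chrom,
            )
            continue
        cds = extract_cds(model, reference)
        downstream = extract_downstream(model, reference)
        tvs = map_variants_to_transcript(genotypes.sites, model, reference)
        haps = build_haplotypes(tvs, genotypes, model.transcript_id)
        compute_frequencies(haps, pmap)
        retained = filter_haplotypes(haps, min_global_freq)
        stats["haplotypes_observed"] += len(haps)
        stats["haplotypes_retained"] += len(retained)
        pforms: dict[str, Proteoform] = {}
        for h in retained:
            cons = classify_consequences(cds, h.alt_set, downstream)
            p = build_proteoform(
                cds,
                h.alt_set,
                transcript_id=model.transcript_id,
                haplotype_key=h.key,
                downstream=downstream,
                consequences=cons,
            )
            p = qc_filter(p, min_len, max_len)
            pforms[h.key] = p
            stats["proteoforms_qc_pass"] += int(p.qc_pass)
        results.append(
            TranscriptResult(
                model=model,
                cds=cds,
                downstream=downstream,
                haplotypes_all=haps,
                haplotypes_retained=retained,
                proteoforms=pforms,
            )
        )
    return BuildResult(transcripts=results, populations=pops, stats=stats)


def build_result_index(build: BuildResult) -> dict:
    """transcript -> haplotype -> observables, for ground-truth comparison."""
    out: dict[str, dict] = {}
    for tr in build.transcripts:
        d: dict[str, dict] = {}
        for h in tr.haplotypes_all:
            entry: dict = {"freq_global": h.freq_global, "count": h.count}
            p = tr.proteoforms.get(h.key)
            if p is not None:
                entry["protein"] = p.protein
                entry["flags"] = sorted(p.flags)
            else:
                # not retained: compute on demand so the truth check can
                # still compare sequences
                cons = classify_consequences(tr.cds, h.alt_set, tr.downstream)
                p2 = build_proteoform(
                    tr.cds,
                    h.alt_set,
                    transcript_id=tr.model.transcript_id,
                    haplotype_key=h.key,
                    downstream=tr.downstream,
                    consequences=cons,
                )
                entry["protein"] = p2.protein
                entry["flags"] = sorted(p2.flags)
            d[h.key] = entry
        out[tr.model.transcript_id] = d
    return out


@dataclass
class ScoredResult:
    build: BuildResult
    records: list[ScoreRecord]
    summaries: list[TranscriptScoreSummary]
    unscored: list[tuple[str, str]] = field(default_factory=list)

    def to_rows(self) -> list[dict[str, str]]:
        rows = self.build.to_rows()
        by_key = {
            (r.transcript_id, r.haplotype_key, r.model): r for r in self.records
        }
        models = sorted({r.model for r in self.records})
        for row in rows:
            for m in models:
                r = by_key.get((row["transcript_id"], row["haplotype_key"], m))
                row[f"{m}_pll"] = _fmt(r.pll if r else None)
                row[f"{m}_pllr_wt"] = _fmt(r.pllr_wt if r else None)
                row[f"{m}_pllr_mf"] = _fmt(r.pllr_mf if r else None)
        return rows

    def summary_rows(self) -> list[dict[str, str]]:
        return [
            {
                "transcript_id": s.transcript_id,
                "model": s.model,
                "pll_delta": _fmt(s.pll_delta),
                "n_haplotypes": str(s.n_haplotypes),
            }
            for s in sorted(
                self.summaries, key=lambda s: (s.transcript_id, s.model)
            )
        ]


def run_score(
    build: BuildResult, scorer_names: Sequence[str]
) -> ScoredResult:
    """Score every transcript's QC-passing proteoforms with each scorer."""
    records: list[ScoreRecord] = []
    summaries: list[TranscriptScoreSummary] = []
    unscored: list[tuple[str, str]] = []
    scorers = [scoring.get_scorer(n) for n in scorer_names]
    for scorer in scorers:
        cache: dict[str, float] = {}
        for tr in build.transcripts:
            proteins = {
                h.key: tr.proteoforms[h.key].protein
                for h in tr.haplotypes_retained
                if tr.proteoforms[h.key].qc_pass
            }
            if WT_KEY not in proteins:
                unscored.append((tr.model.transcript_id, scorer.name))
                continue
            freqs = {
                h.key: (h.freq_global or 0.0) for h in tr.haplotypes_retained
            }
            try:
                recs = scoring.score_haplotypes(
                    proteins,
                    scorer,
                    freqs,
                    tr.model.transcript_id,
                    cache=cache,
                )
            except scoring.ScoringError as exc:
                log.warning(
                    "transcript %s unscored by %s: %s",
                    tr.model.transcript_id,
                    scorer.name,
                    exc,
                )
                unscored.append((tr.model.transcript_id, scorer.name))
                continue
            records.extend(recs)
            summaries.append(scoring.compute_pll_delta(recs))
    return ScoredResult(
        build=build, records=records, summaries=summaries, unscored=unscored
    )


def score_table(
    table: pd.DataFrame, scorer_names: Sequence[str]
) -> pd.DataFrame:
    """Append per-model score columns to a build TSV re-read from disk.

    Operates purely on the table (protein, freq_global, qc columns), which
    is what lets `score` run as a separate subcommand on a prior build.
    """
    df = table.copy()
    for name in scorer_names:
        scorer = scoring.get_scorer(name)
        cache: dict[str, float] = {}
        pll_col: list[str] = []
        wt_col: list[str] = []
        mf_col: list[str] = []
        per_tx: dict[str, list[int]] = {}
        for i, row in df.iterrows():
            per_tx.setdefault(row["transcript_id"], []).append(i)
        values: dict[int, tuple] = {}
        for tid, idxs in per_tx.items():
            ok = [
                i
                for i in idxs
                if df.at[i, "qc"] == "pass" and df.at[i, "protein"] != "."
            ]
            proteins = {df.at[i, "haplotype_key"]: df.at[i, "protein"] for i in ok}
            if WT_KEY not in proteins:
                continue
            freqs = {
                df.at[i, "haplotype_key"]: float(df.at[i, "freq_global"])
                for i in ok
            }
            try:
                recs = scoring.score_haplotypes(
                    proteins, scorer, freqs, tid, cache=cache
                )
            except scoring.ScoringError:
                continue
            by_key = {r.haplotype_key: r for r in recs}
            for i in ok:
                r = by_key[df.at[i, "haplotype_key"]]
                values[i] = (r.pll, r.pllr_wt, r.pllr_mf)
        for i in df.index:
            v = values.get(i)
            pll_col.append(_fmt(v[0]) if v else "NA")
            wt_col.append(_fmt(v[1]) if v else "NA")
            mf_col.append(_fmt(v[2]) if v else "NA")
        df[f"{name}_pll"] = pll_col
        df[f"{name}_pllr_wt"] = wt_col
        df[f"{name}_pllr_mf"] = mf_col
    return df


def pll_delta_table(scored: pd.DataFrame, scorer_names: Sequence[str]) -> pd.DataFrame:
    """Per-transcript PLL_delta rows recomputed from a scored table."""
    rows = []
    for name in scorer_names:
        col = f"{name}_pll"
        if col not in scored.columns:
            continue
        for tid, grp in scored.groupby("transcript_id", sort=True):
            plls = [float(v) for v in grp[col] if v != "NA"]
            if not plls:
                continue
            rows.append(
                {
                    "transcript_id": tid,
                    "model": name,
                    "pll_delta": _fmt(max(plls) - min(plls)),
                    "n_haplotypes": str(len(plls)),
                }
            )
    rows.sort(key=lambda r: (r["transcript_id"], r["model"]))
    return pd.DataFrame(rows)
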
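"""Sequence-fitness scoring: PLL, PLLR_wt, PLLR_mf, PLL_delta, logit aggregation.

A scorer assigns each protein sequence a pseudo-log-likelihood
``PLL(x) = sum_i log p(x_i | x)``. The per-haplotype effect measures are the
differences against two references from the same transcript:

* ``PLLR_wt = PLL(x_mt) - PLL(x_wt)`` — against the wild type;
* ``PLLR_mf = PLL(x_mt) - PLL(x_mf)`` — against the cohort's most frequent
  haplotype.

Lower values mean greater predicted functional impairment. Per transcript,
``PLL_delta = max PLL - min PLL`` over its retained haplotypes summarises the
dispersion of predicted fitness across the allelic series.

Heavy protein language models (masked-marginal or autoregressive) plug in
through the :class:`ScorerPlugin` contract; the bundled unigram scorers are
deterministic reference implementations of the same additive structure.

External per-variant pathogenicity probabilities (AlphaMissense-style) are
mapped to the additive log-odds scale with ``s = ln(s~ / (1 - s~))`` and
aggregated per haplotype as both mean and sum of the variant logits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Protocol, Sequence

from .haplotypes import WT_KEY

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ScoringError(RuntimeError):
    """A scorer failed on a sequence; the transcript is left unscored."""


class ScorerPlugin(Protocol):
    """Contract for pluggable sequence scorers."""

    name: str
    deterministic: bool

    def score(self, protein: str) -> float:  # pragma: no cover - protocol
        ...


@dataclass(frozen=True)
class UnigramScorer:
    """Position-independent scorer: PLL(x) = sum_i ln p(x_i).

    The simplest model with the additive pseudo-log-likelihood structure;
    useful as a deterministic stand-in and for exercising score identities.
    """

    name: str
    logp: Mapping[str, float]
    deterministic: bool = True

    def score(self, protein: str) -> float:
        total = 0.0
        for i, aa in enumerate(protein, start=1):
            lp = self.logp.get(aa)
            if lp is None:
                raise ScoringError(
                    f"{self.name}: unknown residue {aa!r} at position {i}"
                )
            total += lp
        return total


def toy_unigram_scorer(
    freq_table: Mapping[str, float], name: str = "unigram"
) -> UnigramScorer:
    """Build a unigram scorer from a 20-residue probability table."""
    if not freq_table:
        raise ValueError("empty amino-acid frequency table")
    if any(p <= 0 for p in freq_table.values()):
        raise ValueError("probabilities must be positive")
    total = sum(freq_table.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {total}, expected 1")
    return UnigramScorer(
        name=name, logp={aa: math.log(p) for aa, p in freq_table.items()}
    )


#: UniProtKB/Swiss-Prot-like background amino-acid composition.
NATURAL_AA_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
_nat_total = sum(NATURAL_AA_FREQS.values())
NATURAL_AA_FREQS = {aa: p / _nat_total for aa, p in NATURAL_AA_FREQS.items()}

_REGISTRY: dict[str, ScorerPlugin] = {}


def register_scorer(scorer: ScorerPlugin) -> None:
    _REGISTRY[scorer.name] = scorer


def get_scorer(name: str) -> ScorerPlugin:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scorer {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def list_scorers() -> list[str]:
    return sorted(_REGISTRY)


register_scorer(
    toy_unigram_scorer(
        {aa: 1 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}, name="unigram-uniform"
    )
)
register_scorer(toy_unigram_scorer(NATURAL_AA_FREQS, name="unigram-natural"))


@dataclass(frozen=True)
class ScoreRecord:
    """Per-haplotype PLL and its two reference-relative differences."""

    transcript_id: str
    haplotype_key: str
    model: str
    pll: float
    pllr_wt: float
    pllr_mf: float


@dataclass(frozen=True)
class TranscriptScoreSummary:
    """Transcript-level spread of PLL across retained haplotypes."""

    transcript_id: str
    model: str
    pll_delta: float
    n_haplotypes: int


def select_most_frequent(
    keys: Sequence[str], freq_global: Mapping[str, float]
) -> str:
    """Most frequent haplotype with a deterministic tie-break.

    Highest global frequency wins; ties prefer the wild type, then the
    lexicographically smallest key.
    """
    def rank(key: str) -> tuple:
        return (-(freq_global.get(key) or 0.0), key != WT_KEY, key)

    return min(keys, key=rank)


def score_haplotypes(
    proteins: Mapping[str, str],
    scorer: ScorerPlugin,
    freq_global: Mapping[str, float],
    transcript_id: str,
    cache: Optional[dict[str, float]] = None,
) -> list[ScoreRecord]:
    """Score one transcript's QC-passing proteoforms.

    ``proteins`` maps haplotype key -> protein sequence and must include the
    wild type. Each distinct sequence is scored once (cache keyed by
    sequence). Scorer failure raises :class:`ScoringError`; the caller marks
    the transcript unscored for that model and moves on.
    """
    if WT_KEY not in proteins:
        raise ValueError("wild-type proteoform required for PLLR_wt")
    cache = cache if cache is not None else {}

    def pll(seq: str) -> float:
        if seq not in cache:
            cache[seq] = scorer.score(seq)
        return cache[seq]

    mf_key = select_most_frequent(list(proteins), freq_global)
    pll_wt = pll(proteins[WT_KEY])
    pll_mf = pll(proteins[mf_key])
    return [
        ScoreRecord(
            transcript_id=transcript_id,
            haplotype_key=key,
            model=scorer.name,
            pll=pll(seq),
            pllr_wt=pll(seq) - pll_wt,
            pllr_mf=pll(seq) - pll_mf,
        )
        for key, seq in proteins.items()
    ]


def compute_pll_delta(records: Sequence[ScoreRecord]) -> TranscriptScoreSummary:
    """max PLL - min PLL over one transcript's scored haplotypes (>= 0)."""
    if not records:
        raise ValueError("no score records")
    plls = [r.pll for r in records]
    return TranscriptScoreSummary(
        transcript_id=records[0].transcript_id,
        model=records[0].model,
        pll_delta=max(plls) - min(plls),
        n_haplotypes=len(records),
    )


def am_logit(prob: float) -> float:
    """Log-odds of a pathogenicity probability: ln(p / (1 - p))."""
    if not 0.0 < prob < 1.0:
        raise ValueError(f"probability must be in (0, 1), got {prob}")
    return math.log(prob / (1.0 - prob))


def am_sigmoid(logit: float) -> float:
    """Inverse of :func:`am_logit`."""
    return 1.0 / (1.0 + math.exp(-logit))


@dataclass(frozen=True)
class AMRecord:
    """Logit-scale aggregation of per-variant pathogenicity probabilities."""

    haplotype_key: str
    variant_probs: tuple[float, ...]
    logits: tuple[float, ...]
    logit_mean: float
    logit_sum: float


def aggregate_am(
    variant_probs: Sequence[float], haplotype_key: str = ""
) -> AMRecord:
    """Mean and sum of per-variant logits for one haplotype."""
    if not variant_probs:
        raise ValueError("no variant probabilities to aggregate")
    logits = tuple(am_logit(p) for p in variant_probs)
    total = math.fsum(logits)
    return AMRecord(
        haplotype_key=haplotype_key,
        variant_probs=tuple(variant_probs),
        logits=logits,
        logit_mean=total / len(logits),
        logit_sum=total,
    )
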
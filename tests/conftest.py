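"""Shared fixture builders: random edit sets, minus-strand genomes, cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from haploprot.haplotypes import TranscriptVariant
from haploprot.io_formats import Variant

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_tv(
    tpos: int, tref: str, talt: str, src: Variant | None = None
) -> TranscriptVariant:
    """TranscriptVariant with a placeholder (or given) genomic source."""
    return TranscriptVariant(
        source=src or Variant("chrT", tpos, tref, talt),
        tpos=tpos,
        tref=tref,
        talt=talt,
    )


def random_edit_set(
    rng: np.random.Generator, cds: str, max_variants: int = 5
) -> list[TranscriptVariant]:
    """Up to max_variants non-overlapping SNP/insertion/deletion edits."""
    tvs: list[TranscriptVariant] = []
    cursor = 1
    n_target = int(rng.integers(0, max_variants + 1))
    while len(tvs) < n_target and cursor <= len(cds) - 8:
        tpos = cursor + int(rng.integers(0, 4))
        kind = int(rng.integers(0, 3))
        if kind == 0:  # SNP
            tref = cds[tpos - 1]
            talt = BASES[(BASES.index(tref) + 1 + int(rng.integers(0, 3))) % 4]
        elif kind == 1:  # insertion after anchor
            tref = cds[tpos - 1]
            talt = tref + random_dna(rng, int(rng.integers(1, 5)))
        else:  # deletion of 1-4 bases after anchor
            dlen = int(rng.integers(1, 5))
            dlen = min(dlen, len(cds) - 4 - tpos)
            if dlen < 1:
                break
            tref = cds[tpos - 1 : tpos + dlen]
            talt = tref[0]
        tvs.append(make_tv(tpos, tref, talt))
        cursor = tpos + len(tref) + int(rng.integers(1, 4))
    return tvs


def apply_descending(cds: str, tvs) -> str:
    """Oracle: apply edits high-to-low coordinate, no shift tracking."""
    seq = cds
    for tv in sorted(tvs, key=lambda t: -t.tpos):
        i = tv.tpos - 1
        assert seq[i : i + len(tv.tref)] == tv.tref
        seq = seq[:i] + tv.talt + seq[i + len(tv.tref) :]
    return seq


@pytest.fixture(scope="session")
def cohort_bundle(tmp_path_factory):
    """One default 500-sample synthetic cohort shared across tests."""
    from haploprot.simulate import CohortSpec, generate_cohort

    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(CohortSpec(seed=11), out)


@pytest.fixture(scope="session")
def built_cohort(cohort_bundle):
    """Pipeline build result on the shared cohort."""
    from haploprot import pipeline

    return pipeline.run_build(
        cohort_bundle.vcf,
        cohort_bundle.gtf,
        cohort_bundle.fasta,
        cohort_bundle.popmap,
    )
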
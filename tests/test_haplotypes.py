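"""Variant mapping, haplotype enumeration, frequencies and retention."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from haploprot.haplotypes import (
    Haplotype,
    ReferenceMismatchError,
    WT_KEY,
    build_haplotypes,
    compute_frequencies,
    extract_cds,
    filter_haplotypes,
    haplotype_key,
    map_variants_to_transcript,
)
from haploprot.io_formats import (
    MISSING,
    PhasedGenotypes,
    PopulationMap,
    TranscriptModel,
    Variant,
)

from conftest import make_tv, random_dna


def plus_model(chrom="chr1", cds=((100, 129),), exons=None):
    exons = exons or cds
    return TranscriptModel("T1", "G1", "GX", chrom, "+", tuple(exons), tuple(cds))


def minus_model(chrom="chr1", cds=((100, 109),), exons=None):
    exons = exons or cds
    return TranscriptModel("T1", "G1", "GX", chrom, "-", tuple(exons), tuple(cds))


def genome(seq_100_onward: str, chrom="chr1", pad=99):
    return {chrom: "N" * pad + seq_100_onward}


class TestMapVariants:
    def test_plus_strand_snp_offset(self):
        ref = genome("ATG" + "CCC" * 9)
        (tv,) = map_variants_to_transcript(
            [Variant("chr1", 103, "C", "T")], plus_model(), ref
        )
        assert (tv.tpos, tv.tref, tv.talt) == (4, "C", "T")

    def test_minus_strand_snp_reverse_complement(self):
        # oracle: mutate the chromosome string, re-extract and reverse-
        # complement the CDS, diff against the wild-type CDS
        chrom_seq = "N" * 99 + random_dna(np.random.default_rng(3), 20)
        chrom = dict(chr1=chrom_seq)
        model = minus_model()
        base = chrom_seq[102]
        alt = {"A": "C", "C": "T", "G": "A", "T": "G"}[base]
        (tv,) = map_variants_to_transcript(
            [Variant("chr1", 103, base, alt)], model, chrom
        )
        assert tv.tpos == 109 - 103 + 1 == 7
        assert tv.tref == reverse_complement(base)
        assert tv.talt == reverse_complement(alt)
        mutated = chrom_seq[:102] + alt + chrom_seq[103:]
        wt_cds = extract_cds(model, chrom)
        mt_cds = reverse_complement(mutated[99:109])
        diffs = [i for i, (a, b) in enumerate(zip(wt_cds, mt_cds)) if a != b]
        assert diffs == [tv.tpos - 1]
        assert mt_cds[tv.tpos - 1] == tv.talt

    def test_deletion_crossing_cds_boundary_excluded(self):
        ref = genome("ATG" + "CCC" * 9 + "AAAA")
        # REF span 128-131 crosses the CDS 3' end at 129
        out = map_variants_to_transcript(
            [Variant("chr1", 128, ref["chr1"][127:131], ref["chr1"][127])],
            plus_model(),
            ref,
        )
        assert out == []

    def test_ref_mismatch_raises(self):
        ref = genome("ATG" + "CCC" * 9)
        with pytest.raises(ReferenceMismatchError, match="chr1:103"):
            map_variants_to_transcript(
                [Variant("chr1", 103, "G", "T")], plus_model(), ref
            )

    def test_sorted_by_tpos(self):
        ref = genome("ATG" + "CCC" * 9)
        tvs = map_variants_to_transcript(
            [Variant("chr1", 110, "C", "A"), Variant("chr1", 104, "C", "G")],
            plus_model(),
            ref,
        )
        assert [tv.tpos for tv in tvs] == [5, 11]


def make_genotypes(samples, sites, gt_matrix, phased=True):
    """gt_matrix[site][sample] = (a, b) with -1 for missing."""
    alleles = np.array(gt_matrix, dtype=np.int8)
    ph = np.full((len(sites), len(samples)), phased, dtype=bool)
    return PhasedGenotypes(list(samples), list(sites), alleles, ph)


S1 = Variant("chr1", 103, "C", "T")
S2 = Variant("chr1", 110, "C", "A")
TV1 = make_tv(4, "C", "T", src=S1)
TV2 = make_tv(11, "C", "A", src=S2)


class TestBuildHaplotypes:
    def test_trans_compound_enumeration(self):
        gt = make_genotypes(
            ["S1", "S2"],
            [S1, S2],
            [[(0, 1), (0, 0)], [(1, 0), (0, 0)]],
        )
        haps = build_haplotypes([TV1, TV2], gt, "T1")
        counts = {h.key: h.count for h in haps}
        assert counts == {WT_KEY: 2, "4:C>T": 1, "11:C>A": 1}

    def test_phase_sensitivity_cis_vs_trans(self):
        cis = make_genotypes(["S1"], [S1, S2], [[(1, 0)], [(1, 0)]])
        trans = make_genotypes(["S1"], [S1, S2], [[(1, 0)], [(0, 1)]])
        keys_cis = Counter(
            h.key for h in build_haplotypes([TV1, TV2], cis, "T1") for _ in range(h.count)
        )
        keys_trans = Counter(
            h.key
            for h in build_haplotypes([TV1, TV2], trans, "T1")
            for _ in range(h.count)
        )
        assert keys_cis == Counter({"4:C>T;11:C>A": 1, WT_KEY: 1})
        assert keys_trans == Counter({"4:C>T": 1, "11:C>A": 1})
        assert keys_cis != keys_trans

    def test_all_homozygous_reference(self):
        gt = make_genotypes(
            ["S1", "S2", "S3"], [S1], [[(0, 0), (0, 0), (0, 0)]]
        )
        (wt,) = build_haplotypes([TV1], gt, "T1")
        assert wt.key == WT_KEY and wt.count == 6

    def test_missing_excludes_both_chromosomes(self):
        gt = make_genotypes(
            ["S1", "S2"], [S1], [[(-1, -1), (0, 1)]]
        )
        haps = build_haplotypes([TV1], gt, "T1")
        assert sum(h.count for h in haps) == 2  # S1 fully excluded

    def test_unphased_het_excluded_unphased_hom_kept(self):
        gt = make_genotypes(
            ["S1", "S2"], [S1], [[(0, 1), (1, 1)]], phased=False
        )
        haps = build_haplotypes([TV1], gt, "T1")
        counts = {h.key: h.count for h in haps}
        assert counts == {WT_KEY: 0, "4:C>T": 2}

    def test_overlapping_variants_exclude_chromosome(self):
        tv_a = make_tv(4, "CT", "C")
        tv_b = make_tv(5, "T", "G")
        sa, sb = tv_a.source, tv_b.source
        gt = make_genotypes(["S1"], [sa, sb], [[(1, 0)], [(1, 0)]])
        haps = build_haplotypes([tv_a, tv_b], gt, "T1")
        assert sum(h.count for h in haps) == 1  # only haplotype B counted

    def test_brute_force_oracle_small_instances(self):
        # per-chromosome string enumeration on <=4 samples, <=5 sites
        rng = np.random.default_rng(17)
        for trial in range(30):
            n_samples = int(rng.integers(1, 5))
            n_sites = int(rng.integers(1, 6))
            sites = [
                Variant("chr1", 103 + 7 * i, "C", "T") for i in range(n_sites)
            ]
            tvs = [
                make_tv(4 + 7 * i, "C", "T", src=s)
                for i, s in enumerate(sites)
            ]
            mat = rng.integers(0, 2, size=(n_sites, n_samples, 2))
            gt = make_genotypes(
                [f"S{j}" for j in range(n_samples)], sites, mat.tolist()
            )
            expected = Counter()
            for j in range(n_samples):
                for k in (0, 1):
                    carried = [
                        tvs[i].label for i in range(n_sites) if mat[i, j, k] == 1
                    ]
                    expected[";".join(carried) or WT_KEY] += 1
            got = {
                h.key: h.count
                for h in build_haplotypes(tvs, gt, "T1")
                if h.count or h.key == WT_KEY
            }
            assert got == dict(expected) | {WT_KEY: expected[WT_KEY]}


class TestFrequencies:
    def make_counted(self, counts, carriers):
        haps = []
        for key, c in counts.items():
            h = Haplotype("T1", () if key == WT_KEY else (make_tv(4, "C", "T"),), key)
            h.count = c
            h.carriers = carriers.get(key, [])
            haps.append(h)
        return haps

    def test_global_fraction(self):
        haps = self.make_counted({WT_KEY: 5, "H1": 3}, {})
        compute_frequencies(haps)
        assert [h.freq_global for h in haps] == [0.625, 0.375]

    def test_per_population_restriction(self):
        # 4 AFR chromosomes in total, 3 of them carrying H1 -> AFR freq 0.75
        carriers = {
            WT_KEY: [("a1", 0), ("e1", 0), ("e1", 1), ("e2", 0), ("e2", 1)],
            "H1": [("a1", 1), ("a2", 0), ("a2", 1)],
        }
        haps = self.make_counted({WT_KEY: 5, "H1": 3}, carriers)
        pm = PopulationMap({"a1": "AFR", "a2": "AFR", "e1": "EUR", "e2": "EUR"})
        compute_frequencies(haps, pm)
        h1 = haps[1]
        assert h1.freq_by_pop["AFR"] == pytest.approx(3 / 4)
        assert h1.freq_by_pop["EUR"] == 0.0

    def test_single_population_matches_global(self):
        carriers = {WT_KEY: [("s1", 0)], "H1": [("s1", 1)]}
        haps = self.make_counted({WT_KEY: 1, "H1": 1}, carriers)
        pm = PopulationMap({"s1": "EAS"})
        compute_frequencies(haps, pm)
        for h in haps:
            assert h.freq_by_pop["EAS"] == h.freq_global

    def test_empty_population_is_undefined_not_zero(self):
        carriers = {WT_KEY: [("s1", 0), ("s1", 1)]}
        haps = self.make_counted({WT_KEY: 2}, carriers)
        pm = PopulationMap({"s1": "EAS", "unused": "SAS"})
        compute_frequencies(haps, pm)
        assert haps[0].freq_by_pop["SAS"] is None


class TestRetentionFilter:
    def make(self, freqs):
        haps = []
        for key, f in freqs.items():
            h = Haplotype("T1", () if key == WT_KEY else (make_tv(4, "C", "T"),), key)
            h.freq_global = f
            haps.append(h)
        return haps

    def test_paper_threshold(self):
        haps = self.make({WT_KEY: 0.001, "H1": 0.006, "H2": 0.004})
        assert [h.key for h in filter_haplotypes(haps)] == [WT_KEY, "H1"]

    def test_zero_threshold_keeps_all(self):
        haps = self.make({WT_KEY: 0.5, "H1": 0.3, "H2": 0.2})
        assert filter_haplotypes(haps, 0.0) == haps

    def test_wildtype_only(self):
        haps = self.make({WT_KEY: 1.0})
        assert [h.key for h in filter_haplotypes(haps)] == [WT_KEY]

    def test_boundary_inclusive(self):
        haps = self.make({WT_KEY: 0.995, "H1": 0.005})
        assert len(filter_haplotypes(haps, 0.005)) == 2
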
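"""Variant detection, informative sites, and mixture deconvolution."""

import itertools
import random

import numpy as np
import pytest

from pennid.readmap import Pileup, build_pileup, map_reads
from pennid.refpanel import LocusReference
from pennid.varcall import (IndelMixtureReport, deconvolve_its,
                            detect_mixed_indel, detect_variants,
                            exact_read_assignment, informative_sites,
                            write_vcf)
from pennid.simdata import GenotypeSpec, ReadSimConfig, simulate_short_reads


def _pileup_from_counts(reference, column_counts):
    """Hand-built pileup: column_counts maps pos -> {base: count}."""
    pileup = Pileup(reference)
    for pos, counts in column_counts.items():
        for base, count in counts.items():
            if base == "-":
                pileup.counts[4, pos] = count
            else:
                pileup.counts["ACGT".index(base), pos] = count
    return pileup


class TestDetectVariants:
    def test_homogeneous_pileup_empty(self):
        ref = "ACGTACGTAC"
        pileup = _pileup_from_counts(ref, {i: {ref[i]: 50} for i in range(10)})
        assert detect_variants(pileup) == []

    def test_forty_percent_snv_called(self):
        ref = "ACGTACGTAC"
        counts = {i: {ref[i]: 1000} for i in range(10)}
        counts[3] = {"A": 600, "G": 400}  # reference T replaced by A/G split
        pileup = _pileup_from_counts(ref, counts)
        calls = detect_variants(pileup)
        by_alt = {(c.position, c.alt_allele): c for c in calls}
        assert (3, "G") in by_alt
        assert by_alt[(3, "G")].frequency == pytest.approx(0.4)

    def test_two_percent_not_called_at_default_floor(self):
        ref = "ACGTACGTAC"
        counts = {i: {ref[i]: 1000} for i in range(10)}
        counts[5] = {ref[5]: 980, "T" if ref[5] != "T" else "A": 20}
        pileup = _pileup_from_counts(ref, counts)
        assert all(c.position != 5 for c in detect_variants(pileup))

    def test_matches_direct_counting_oracle(self):
        rng = random.Random(8)
        ref = "".join(rng.choice("ACGT") for _ in range(40))
        counts = {}
        for pos in range(40):
            col = {b: rng.randrange(0, 30) for b in "ACGT"}
            col["-"] = rng.randrange(0, 5)
            counts[pos] = col
        pileup = _pileup_from_counts(ref, counts)
        md, mc, mf = 10, 2, 0.05
        calls = detect_variants(pileup, md, mc, mf)
        called = {(c.position, c.alt_allele if c.kind == "SNV" else "-")
                  for c in calls}
        expected = set()
        for pos in range(40):
            depth = sum(counts[pos].values())
            if depth < md:
                continue
            for allele, n in counts[pos].items():
                if allele == ref[pos]:
                    continue
                if n >= mc and n / depth >= mf:
                    expected.add((pos, allele))
        assert called == expected

    @pytest.mark.parametrize("tighter", [
        {"min_depth": 50}, {"min_count": 10}, {"min_freq": 0.2}])
    def test_monotone_in_thresholds(self, tighter):
        rng = random.Random(17)
        ref = "".join(rng.choice("ACGT") for _ in range(30))
        counts = {pos: {b: rng.randrange(0, 40) for b in "ACGT"}
                  for pos in range(30)}
        pileup = _pileup_from_counts(ref, counts)
        base = {(c.position, c.alt_allele, c.kind)
                for c in detect_variants(pileup)}
        tightened = {(c.position, c.alt_allele, c.kind)
                     for c in detect_variants(pileup, **tighter)}
        assert tightened <= base

    def test_vcf_export_one_based(self, tmp_path):
        ref = "ACGTACGTAC"
        counts = {i: {ref[i]: 100} for i in range(10)}
        counts[3] = {"A": 60, "G": 40}
        calls = detect_variants(_pileup_from_counts(ref, counts))
        path = tmp_path / "calls.vcf"
        write_vcf(calls, "rbcL", path)
        lines = [l for l in path.read_text().splitlines()
                 if not l.startswith("#")]
        fields = lines[0].split("\t")
        assert fields[0] == "rbcL" and fields[1] == "4"


def _mini_variants():
    """Four 60-nt variants with planted, disjoint differences."""
    rng = random.Random(33)
    base = "".join(rng.choice("ACGT") for _ in range(60))

    def mutate(seq, positions):
        out = list(seq)
        for p in positions:
            out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
        return "".join(out)

    a1 = base
    s1 = mutate(a1, [10, 20, 30, 40, 50])
    a2 = mutate(a1, [15, 25])
    s2 = mutate(s1, [35])
    return [("aI", LocusReference("ITS", "advena", "I", a1)),
            ("aII", LocusReference("ITS", "advena", "II", a2)),
            ("sI", LocusReference("ITS", "setaceum", "I", s1)),
            ("sII", LocusReference("ITS", "setaceum", "II", s2))]


class TestInformativeSites:
    def test_identical_pair_empty(self):
        seq = "ACGTACGTACGTACGTACGT"
        pair = [("aI", LocusReference("ITS", "advena", "I", seq)),
                ("aII", LocusReference("ITS", "advena", "II", seq))]
        assert len(informative_sites(pair)) == 0

    def test_planted_differences_recovered(self):
        table = informative_sites(_mini_variants())
        assert table.positions() == [10, 15, 20, 25, 30, 35, 40, 50]

    def test_single_reference_rejected(self):
        with pytest.raises(ValueError):
            informative_sites(_mini_variants()[:1])

    def test_gap_column_flagged(self):
        a = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        b = a[:16] + a[17:]  # 1-nt deletion
        pair = [("aI", LocusReference("ITS", "advena", "I", a)),
                ("aII", LocusReference("ITS", "advena", "II", b))]
        table = informative_sites(pair)
        assert any(site.has_gap for site in table.sites)

    def test_panel_table_contains_intra_and_inter_sites(self, panel):
        from pennid.pipeline import its_site_table

        table = its_site_table(panel)
        # 60 between-species + 3 advena + 2 setaceum disjoint sites
        assert len(table) == 65


class TestDeconvolution:
    def _reads_spanning(self, variants, mixture, n=400, seed=1):
        """Full-length reads (span every informative site) from a mixture."""
        rng = random.Random(seed)
        labels = sorted(mixture)
        seqs = dict((l, r.sequence) for l, r in variants)
        reads = []
        for i in range(n):
            u, acc = rng.random(), 0.0
            label = labels[-1]
            for l in labels:
                acc += mixture[l]
                if u < acc:
                    label = l
                    break
            reads.append(type("R", (), {"read_id": f"r{i}:src={label}",
                                        "sequence": seqs[label]})())
        return reads

    def test_pure_template_gives_unit_proportion(self):
        variants = _mini_variants()
        table = informative_sites(variants)
        reads = self._reads_spanning(variants, {"aI": 1.0})
        anchor = dict(variants)["aI"].sequence
        profile = deconvolve_its(map_reads(reads, anchor), table, "pure")
        assert profile.proportions == {"aI": 1.0}

    def test_matches_exact_per_read_identification(self):
        """Reads spanning all informative sites: voting equals brute-force
        per-read template identification."""
        variants = _mini_variants()
        table = informative_sites(variants)
        mixture = {"aI": 0.4, "aII": 0.25, "sI": 0.2, "sII": 0.15}
        reads = self._reads_spanning(variants, mixture, n=500, seed=7)
        anchor = dict(variants)["aI"].sequence
        alignments = map_reads(reads, anchor)
        profile = deconvolve_its(alignments, table, noise_floor=0.0)

        # independent oracle: nearest template per read by direct comparison
        truth_counts = {l: 0 for l, _ in variants}
        seqs = dict((l, r.sequence) for l, r in variants)
        for read in reads:
            dists = {l: sum(1 for x, y in zip(read.sequence, s) if x != y)
                     for l, s in seqs.items()}
            best = min(dists.values())
            winners = [l for l, d in dists.items() if d == best]
            assert len(winners) == 1
            truth_counts[winners[0]] += 1
        total = sum(truth_counts.values())
        for label, count in truth_counts.items():
            assert profile.proportions.get(label, 0.0) == \
                pytest.approx(count / total, abs=1e-9)
        # the package's own exact-assignment cross-check agrees too
        assert exact_read_assignment(alignments, table) == \
            pytest.approx(profile.proportions)

    def test_proportions_sum_to_one(self, panel):
        from pennid.pipeline import its_site_table

        spec = GenotypeSpec("mix", "advena",
                            {"aI": 0.45, "aII": 0.15, "sI": 0.40})
        cfg = ReadSimConfig(coverage=300, error_rate=0.001, seed=23)
        reads = simulate_short_reads(spec, panel, cfg, loci=("ITS",))["ITS"]
        anchor = panel.get("ITS", "advena", "I").sequence
        table = its_site_table(panel)
        profile = deconvolve_its(map_reads(reads, anchor), table, "mix")
        assert sum(profile.proportions.values()) == pytest.approx(1.0)
        assert set(profile.proportions) == {"aI", "aII", "sI"}

    def test_tie_reallocation_recovers_skewed_within_species_ratio(self, panel):
        """Proportional tie handling avoids the pull toward 50/50 that an
        equal split produces when many reads cannot separate sI from sII."""
        from pennid.pipeline import its_site_table

        spec = GenotypeSpec("skew", "setaceum", {"sI": 0.70, "sII": 0.30})
        cfg = ReadSimConfig(coverage=2000, error_rate=0.0, seed=29)
        reads = simulate_short_reads(spec, panel, cfg, loci=("ITS",))["ITS"]
        anchor = panel.get("ITS", "advena", "I").sequence
        table = its_site_table(panel)
        alignments = map_reads(reads, anchor)
        em = deconvolve_its(alignments, table, tie_method="em")
        equal = deconvolve_its(alignments, table, tie_method="equal")
        assert em.proportions["sI"] == pytest.approx(0.70, abs=0.05)
        assert abs(equal.proportions["sI"] - 0.70) > \
            abs(em.proportions["sI"] - 0.70)

    def test_no_informative_coverage_flagged(self):
        variants = _mini_variants()
        table = informative_sites(variants)
        profile = deconvolve_its([], table, "empty")
        assert profile.proportions == {}
        assert "no read covers" in profile.note

    def test_empty_table_rejected(self):
        seq = "ACGT" * 10
        pair = [("aI", LocusReference("ITS", "advena", "I", seq)),
                ("aII", LocusReference("ITS", "advena", "II", seq))]
        with pytest.raises(ValueError):
            deconvolve_its([], informative_sites(pair))


class TestMixedIndelDetection:
    def test_even_indel_mixture_reported(self, panel):
        spec = GenotypeSpec("Simons 2006", "setaceum",
                            {"sI": 0.7, "sII": 0.3},
                            chloroplast_indel_mixture=True)
        cfg = ReadSimConfig(coverage=500, error_rate=0.0, seed=31)
        reads = simulate_short_reads(spec, panel, cfg,
                                     loci=("trnH-psbA",))["trnH-psbA"]
        anchor = panel.species_reference("trnH-psbA", "advena").sequence
        pileup = build_pileup(map_reads(reads, anchor), anchor)
        report = detect_mixed_indel(pileup)
        assert report is not None
        assert report.kind == "insertion"
        assert report.frequency == pytest.approx(0.5, abs=0.05)

    def test_single_template_no_report(self, panel):
        spec = GenotypeSpec("pure", "setaceum", {"sI": 1.0})
        cfg = ReadSimConfig(coverage=100, error_rate=0.0, seed=31)
        reads = simulate_short_reads(spec, panel, cfg,
                                     loci=("trnH-psbA",))["trnH-psbA"]
        anchor = panel.species_reference("trnH-psbA", "advena").sequence
        pileup = build_pileup(map_reads(reads, anchor), anchor)
        assert detect_mixed_indel(pileup) is None

    def test_ninety_ten_outside_band(self):
        pileup = Pileup("ACGTACGTACGTACGTACGT")
        for pos in range(20):
            pileup.counts["ACGT".index(pileup.reference[pos]), pos] = 1000
        from collections import Counter

        pileup.insertions[9] = Counter({"G": 100})  # 10% insertion
        assert detect_mixed_indel(pileup) is None
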
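"""Synthetic-data generator: divergence structure, reads, determinism."""

import numpy as np
import pytest

from pennid import iupac
from pennid.refpanel import diagnostic_sites, pairwise_identity
from pennid.simdata import (GenotypeSpec, PanelConfig, ReadSimConfig,
                            make_reference_panel, paper_scenarios,
                            simulate_sanger_pair, simulate_short_reads,
                            write_fastq)


def _diff_positions(a: str, b: str) -> list[int]:
    assert len(a) == len(b)
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


class TestReferencePanel:
    def test_configured_divergence_holds_exactly(self, panel):
        rbcl = diagnostic_sites(panel.species_reference("rbcL", "advena"),
                                panel.species_reference("rbcL", "setaceum"))
        trnh = diagnostic_sites(panel.species_reference("trnH-psbA", "advena"),
                                panel.species_reference("trnH-psbA", "setaceum"))
        assert (len(rbcl), len(trnh)) == (2, 4)
        ident = pairwise_identity(panel.get("ITS", "advena", "I").sequence,
                                  panel.get("ITS", "setaceum", "I").sequence)
        assert abs(ident.percent_identity - 90.0) <= 1.0

    def test_intraspecific_variant_snp_counts(self, panel):
        a1 = panel.get("ITS", "advena", "I").sequence
        a2 = panel.get("ITS", "advena", "II").sequence
        s1 = panel.get("ITS", "setaceum", "I").sequence
        s2 = panel.get("ITS", "setaceum", "II").sequence
        assert len(_diff_positions(a1, a2)) == 3
        assert len(_diff_positions(s1, s2)) == 2

    def test_trnh_indel_haplotype_pair(self, panel):
        v1 = panel.get("trnH-psbA", "setaceum", "I").sequence
        v2 = panel.get("trnH-psbA", "setaceum", "II").sequence
        assert len(v2) == len(v1) + 1

    def test_same_seed_reproduces_panel(self, panel_cfg, panel):
        again = make_reference_panel(panel_cfg)
        assert {r.key: r.sequence for r in again} == \
            {r.key: r.sequence for r in panel}

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            PanelConfig(chloroplast_substitutions={"rbcL": 600,
                                                   "trnH-psbA": 4})
        with pytest.raises(ValueError):
            make_reference_panel(PanelConfig(its_identity_pct=1.0))


class TestGenotypeSpec:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GenotypeSpec("x", "advena", {"aI": 0.5, "aII": 0.4})

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            GenotypeSpec("x", "advena", {"zz": 1.0})

    def test_hybrid_flag(self):
        hybrid = GenotypeSpec("x", "advena", {"aI": 0.6, "sI": 0.4})
        pure = GenotypeSpec("y", "advena", {"aI": 1.0})
        assert hybrid.is_hybrid and not pure.is_hybrid


class TestShortReads:
    def test_pure_error_free_reads_are_exact_substrings(self, panel):
        spec = GenotypeSpec("pure", "advena", {"aI": 1.0})
        cfg = ReadSimConfig(coverage=20, error_rate=0.0, seed=3)
        reads = simulate_short_reads(spec, panel, cfg, loci=("ITS",))["ITS"]
        template = panel.get("ITS", "advena", "I").sequence
        assert reads
        assert all(r.sequence in template for r in reads)

    def test_chloroplast_reads_carry_species_alleles(self, panel):
        spec = GenotypeSpec("seta", "setaceum", {"sI": 1.0})
        cfg = ReadSimConfig(coverage=50, error_rate=0.0, seed=3)
        reads = simulate_short_reads(spec, panel, cfg, loci=("rbcL",))["rbcL"]
        sites = diagnostic_sites(panel.species_reference("rbcL", "advena"),
                                 panel.species_reference("rbcL", "setaceum"))
        template = panel.species_reference("rbcL", "setaceum").sequence
        for read in reads:
            start = template.find(read.sequence)
            assert start >= 0
            for site in sites.sites:
                if start <= site.pos_s < start + len(read.sequence):
                    assert read.sequence[site.pos_s - start] == site.allele_s

    def test_mixture_allele_fractions_converge(self, panel):
        """Empirical allele frequencies approach the configured proportions
        (coverage 10,000, tolerance 2 percentage points)."""
        spec = GenotypeSpec("mix", "advena", {"aI": 0.55, "aII": 0.45})
        cfg = ReadSimConfig(coverage=10_000, error_rate=0.0, seed=5)
        reads = simulate_short_reads(spec, panel, cfg, loci=("ITS",))["ITS"]
        a1 = panel.get("ITS", "advena", "I").sequence
        a2 = panel.get("ITS", "advena", "II").sequence
        for pos in _diff_positions(a1, a2):
            covering = carrying = 0
            for read in reads:
                start = int(read.read_id.rsplit("pos=", 1)[1])
                if start <= pos < start + len(read.sequence):
                    covering += 1
                    carrying += read.sequence[pos - start] == a1[pos]
            assert covering > 1000
            assert carrying / covering == pytest.approx(0.55, abs=0.02)

    def test_same_seed_byte_identical(self, panel, tmp_path):
        spec = GenotypeSpec("det", "setaceum", {"sI": 0.7, "sII": 0.3})
        cfg = ReadSimConfig(coverage=30, error_rate=0.01, seed=9)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(simulate_short_reads(spec, panel, cfg)["ITS"], p1)
        write_fastq(simulate_short_reads(spec, panel, cfg)["ITS"], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_mixture_reference_rejected(self, panel):
        from pennid.refpanel import ReferencePanel

        stripped = ReferencePanel(r for r in panel
                                  if r.key != ("ITS", "setaceum", "II"))
        spec = GenotypeSpec("x", "setaceum", {"sI": 0.5, "sII": 0.5})
        with pytest.raises(KeyError):
            simulate_short_reads(spec, stripped,
                                 ReadSimConfig(coverage=5, seed=1),
                                 loci=("ITS",))


class TestSangerSimulation:
    def test_pure_template_has_no_ambiguity(self, panel):
        spec = GenotypeSpec("pure", "advena", {"aI": 1.0})
        fwd, rev = simulate_sanger_pair(spec, panel, "ITS",
                                        include_primers=False, seed=1)
        template = panel.get("ITS", "advena", "I").sequence
        assert fwd.bases == template[:len(fwd)]
        assert all(b in "ACGT" for b in fwd.bases)
        assert rev.bases == iupac.reverse_complement(template)[:len(rev)]

    def test_fifty_fifty_snp_mixture_emits_covering_code(self, panel):
        spec = GenotypeSpec("het", "advena", {"aI": 0.5, "sI": 0.5})
        fwd, _ = simulate_sanger_pair(spec, panel, "ITS",
                                      include_primers=False, seed=1)
        a1 = panel.get("ITS", "advena", "I").sequence
        s1 = panel.get("ITS", "setaceum", "I").sequence
        for pos in _diff_positions(a1, s1):
            if pos < len(fwd):
                code = fwd.bases[pos]
                assert iupac.bases_of(code) == {a1[pos], s1[pos]}

    def test_minority_below_threshold_invisible(self, panel):
        spec = GenotypeSpec("skew", "advena",
                            {"aI": 0.45, "aII": 0.15, "sI": 0.40})
        fwd, _ = simulate_sanger_pair(spec, panel, "ITS",
                                      include_primers=False, seed=1)
        a1 = panel.get("ITS", "advena", "I").sequence
        a2 = panel.get("ITS", "advena", "II").sequence
        for pos in _diff_positions(a1, a2):
            if pos < len(fwd):  # aII at 15% stays below the 20% peak threshold
                assert fwd.bases[pos] == a1[pos]

    def test_indel_mixture_scrambles_downstream_on_both_strands(self, panel):
        spec = GenotypeSpec("Simons 2006", "setaceum",
                            {"sI": 0.7, "sII": 0.3},
                            chloroplast_indel_mixture=True)
        fwd, rev = simulate_sanger_pair(spec, panel, "trnH-psbA",
                                        include_primers=False, seed=1)
        v1 = panel.get("trnH-psbA", "setaceum", "I").sequence
        v2 = panel.get("trnH-psbA", "setaceum", "II").sequence
        indel_pos = next(i for i in range(len(v1)) if v1[i] != v2[i])
        low_fwd = [q for q in fwd.qualities[indel_pos:]]
        low_rev = [q for q in rev.qualities[len(v1) - indel_pos:]]
        assert low_fwd and max(low_fwd) < 30
        assert low_rev and max(low_rev) < 30
        assert min(fwd.qualities[:max(indel_pos - 60, 1)]) > 30


class TestScenarios:
    def test_thirteen_specimens_matching_study_design(self, scenarios):
        assert len(scenarios) == 13
        by_id = {s.specimen_id: s for s in scenarios}
        assert by_id["Cherry Sparkler"].its_mixture == \
            {"aI": 0.45, "aII": 0.15, "sI": 0.40}
        assert by_id["Sky Rocket"].its_mixture == \
            {"aI": 0.20, "aII": 0.50, "sI": 0.30}
        assert by_id["Simons 2006"].chloroplast_indel_mixture
        assert by_id["Mooney 9419"].its_mixture == {"sI": 0.30, "sII": 0.70}
        hybrids = [s.specimen_id for s in scenarios if s.is_hybrid]
        assert sorted(hybrids) == ["Cherry Sparkler", "Sky Rocket"]
        advena_cp = [s for s in scenarios if s.chloroplast_species == "advena"]
        assert len(advena_cp) == 7
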
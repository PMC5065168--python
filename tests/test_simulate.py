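import math

import numpy as np
import pandas as pd
import pytest

from karyoshatter.genome import ConfigurationError
from karyoshatter.simulate import (Event, SimulationConfig, TrueVariant,
                                   simulate_chromothripsis_chromosome,
                                   simulate_cohort, simulate_patient_profile,
                                   simulate_variant_table)


def rle_switches(states):
    """Independent run-length scan: adjacent unequal pairs."""
    states = list(states)
    return sum(1 for a, b in zip(states, states[1:]) if a != b)


class TestPatientProfile:
    def test_no_events_no_noise_is_flat_zero(self, tiny_genome):
        table, realized, switches = simulate_patient_profile(
            tiny_genome, [], noise_sd=0.0, seed=0)
        assert (table["log2ratio"] == 0.0).all()
        assert realized == []
        assert all(v == 0 for v in switches.values())

    @pytest.mark.parametrize("state,expected", [
        (1, -1.0),
        (3, math.log2(3 / 2)),
    ])
    def test_noiseless_event_levels_are_exact(self, tiny_genome, state, expected):
        ev = Event("chrA", 10_000_000, 50_000_000, state)
        table, realized, _ = simulate_patient_profile(
            tiny_genome, [ev], noise_sd=0.0, seed=0)
        chrA = table[table["chrom"] == "chrA"]
        covered = chrA[(chrA["pos"] - 1 >= ev.start) & (chrA["pos"] - 1 < ev.end)]
        assert len(covered) == realized[0].n_probes > 0
        np.testing.assert_allclose(covered["log2ratio"], expected)
        outside = chrA.drop(covered.index)
        np.testing.assert_allclose(outside["log2ratio"], 0.0)

    def test_overlapping_events_rejected(self, tiny_genome):
        events = [Event("chrA", 0, 30_000_000, 1),
                  Event("chrA", 20_000_000, 60_000_000, 3)]
        with pytest.raises(ValueError, match="overlapping"):
            simulate_patient_profile(tiny_genome, events, 0.0, 0)

    def test_event_covering_no_probe_rejected(self, tiny_genome):
        # probes are ~500 kb apart; a 10 bp event falls between them
        ev = Event("chrA", 1_000_001, 1_000_011, 1)
        with pytest.raises(ConfigurationError, match="covers no probe"):
            simulate_patient_profile(tiny_genome, [ev], 0.0, 0)

    def test_female_profile_has_no_y_probes(self, default_genome):
        table, _, _ = simulate_patient_profile(
            default_genome, [], 0.0, 0, sex="female")
        assert "chrY" not in set(table["chrom"])

    def test_switch_count_matches_independent_rle(self, tiny_genome):
        events = [Event("chrA", 0, 20_000_000, 1),
                  Event("chrA", 20_000_000, 40_000_000, 3),
                  Event("chrA", 60_000_000, 80_000_000, 1)]
        _, _, switches = simulate_patient_profile(tiny_genome, events, 0.0, 0)
        # per-probe truth: 1...3...2...1...2 -> 4 transitions
        assert switches["chrA"] == 4
        assert switches["chrB"] == 0


class TestChromothripsisSimulation:
    def test_requested_switches_realized(self, default_genome):
        events = simulate_chromothripsis_chromosome(
            default_genome, "chr13", 18, (1, 2, 3), seed=5)
        assert len(events) == 19
        assert rle_switches([e.copy_state for e in events]) == 18

    def test_single_switch_two_distinct_states(self, default_genome):
        events = simulate_chromothripsis_chromosome(
            default_genome, "chr13", 1, (1, 2, 3), seed=1)
        assert len(events) == 2
        assert events[0].copy_state != events[1].copy_state

    @pytest.mark.parametrize("seed", range(5))
    def test_adjacent_segments_always_differ(self, default_genome, seed):
        events = simulate_chromothripsis_chromosome(
            default_genome, "chr13", 12, (1, 2), seed=seed)
        states = [e.copy_state for e in events]
        assert all(a != b for a, b in zip(states, states[1:]))
        assert set(states) <= {1, 2}
        assert rle_switches(states) == 12

    def test_too_many_segments_rejected(self, tiny_genome):
        with pytest.raises(ConfigurationError, match="exceed"):
            simulate_chromothripsis_chromosome(
                tiny_genome, "chrA", 99, (1, 2, 3), seed=0,
                min_probes_per_segment=20)

    def test_profile_roundtrip_preserves_switch_count(self, default_genome):
        events = simulate_chromothripsis_chromosome(
            default_genome, "chr13", 15, (1, 2, 3), seed=7)
        _, _, switches = simulate_patient_profile(
            default_genome, events, 0.0, 0)
        assert switches["chr13"] == 15


class TestVariantTable:
    def test_large_depth_concentrates_on_true_vaf(self):
        v = TrueVariant("P1", "TP53", "c.1A>G", "p.Met1Val", "missense",
                        50.0, "heterozygous")
        depth = 10_000
        table = simulate_variant_table([v], depth, seed=0)
        sd = 100 * math.sqrt(0.5 * 0.5 / depth)
        assert abs(table.loc[0, "vaf"] - 50.0) < 3 * sd

    def test_vaf_100_always_observed_100(self):
        v = TrueVariant("P1", "TET2", "c.2C>T", "p.Pro1Leu", "nonsense",
                        100.0, "homozygous_or_hemizygous")
        for depth in (1, 10, 500):
            table = simulate_variant_table([v], depth, seed=3)
            assert table.loc[0, "vaf"] == 100.0

    def test_seeded_rerun_identical(self):
        vs = [TrueVariant("P1", "TP53", "c.1A>G", "p.M1V", "missense",
                          40.0, "heterozygous")] * 5
        t1 = simulate_variant_table(vs, 100, seed=9)
        t2 = simulate_variant_table(vs, 100, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestCohort:
    def test_all_zero_frequencies_give_quiet_cohort(self):
        cfg = SimulationConfig(
            n_patients=6, probe_count=12_000, noise_sd=0.0,
            chromothripsis_prevalence=0.0, event_frequency_table={},
            germline_cnv_rate=0.0, non_informative_fraction=0.0, seed=0)
        cohort = simulate_cohort(cfg)
        for truth in cohort.truth:
            assert truth.somatic_events() == []
            assert all(v == 0 for v in truth.switch_counts.values())
            assert truth.karyotype_status == "normal"

    def test_implanted_class_counts_are_exact(self):
        cfg = SimulationConfig(
            n_patients=40, probe_count=12_000,
            chromothripsis_prevalence=0.5, seed=11)
        cohort = simulate_cohort(cfg)
        n_ct = sum(t.chromothripsis for t in cohort.truth)
        assert n_ct == 20
        rerun = simulate_cohort(cfg)
        assert [t.patient for t in cohort.truth if t.chromothripsis] == \
               [t.patient for t in rerun.truth if t.chromothripsis]

    def test_class_counts_within_binomial_error_of_fractions(self):
        cfg = SimulationConfig(n_patients=301, probe_count=12_000, seed=2)
        cohort = simulate_cohort(cfg)
        n = cfg.n_patients
        by_class: dict[str, int] = {}
        for t in cohort.truth:
            for e in t.somatic_events():
                name = e.event.name.split(":")[0]
                by_class[name] = by_class.get(name, 0) + 1
        for cls, frac in cfg.event_frequency_table.items():
            if cls == "-Y":
                continue  # implanted among males only; fewer eligible
            expected = frac * n
            sd = math.sqrt(n * frac * (1 - frac))
            assert abs(by_class.get(cls, 0) - expected) <= max(3 * sd, 1), cls

    def test_seeded_outputs_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_patients=4, probe_count=12_000, seed=7,
                               chromothripsis_prevalence=0.25)
        simulate_cohort(cfg, tmp_path / "a")
        simulate_cohort(cfg, tmp_path / "b")
        for rel in ["karyotypes.tsv", "mutations.tsv", "truth.json",
                    "probes/P0001.tsv", "probes/P0004.tsv"]:
            assert (tmp_path / "a" / rel).read_bytes() == \
                   (tmp_path / "b" / rel).read_bytes(), rel

    def test_truth_switch_counts_consistent_with_events(self):
        cfg = SimulationConfig(n_patients=8, probe_count=12_000, seed=4,
                               chromothripsis_prevalence=0.5, noise_sd=0.0)
        cohort = simulate_cohort(cfg)
        for truth in cohort.truth:
            if not truth.chromothripsis:
                continue
            chrom = truth.chromothripsis_chromosome
            states = [e.event.copy_state for e in truth.events
                      if e.event.chromosome == chrom]
            assert rle_switches(states) == truth.chromothripsis_switches
            assert truth.switch_counts[chrom] == truth.chromothripsis_switches

    def test_karyotype_encodes_only_large_events(self):
        cfg = SimulationConfig(
            n_patients=30, probe_count=12_000, seed=13,
            chromothripsis_prevalence=0.0, non_informative_fraction=0.0,
            germline_cnv_rate=0.0,
            event_frequency_table={"del(5q)": 0.3, "cryptic-at-gene": 0.3})
        cohort = simulate_cohort(cfg)
        karyo = {pid: iscn for pid, iscn, _ in cohort.karyotypes}
        for truth in cohort.truth:
            classes = {e.event.name.split(":")[0] for e in truth.somatic_events()}
            iscn = karyo[truth.patient]
            if "del(5q)" in classes:
                assert "del(5)" in iscn
            else:
                assert "del(5)" not in iscn
            # cryptic events never surface in the karyotype
            assert "del(4)" not in iscn and "del(2)" not in iscn

    def test_non_informative_patients_emit_no_metaphases(self):
        cfg = SimulationConfig(n_patients=10, probe_count=12_000, seed=5,
                               non_informative_fraction=0.5)
        cohort = simulate_cohort(cfg)
        n_noninf = sum(1 for _, iscn, m in cohort.karyotypes
                       if m == 0 and iscn == "")
        assert n_noninf == 5

    def test_invalid_frequency_tables_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(event_frequency_table={"del(5q)": 1.4})
        with pytest.raises(ConfigurationError):
            SimulationConfig(event_frequency_table={"del(99z)": 0.1})
        with pytest.raises(ConfigurationError):
            SimulationConfig(chromothripsis_prevalence=-0.1)
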
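"""Synthetic-data generator: determinism, VAF law, ground-truth wiring."""

import json
import filecmp

import numpy as np
import pytest

from tgctevo.hla import classify_hla_gene
from tgctevo.model import ValidationError
from tgctevo.simulate import (
    CohortEvent,
    SegmentPlan,
    SimulationConfig,
    simulate_cohort,
    simulate_hla,
    simulate_pon_sites,
    simulate_segment_variants,
    simulate_sv_callsets,
    simulate_tumour,
    write_cohort,
    write_tumour,
)

SMALL = SimulationConfig(seed=5, chromosomes=("21", "22"))


def test_zero_mutation_rate_gives_no_variants():
    cfg = SimulationConfig(seed=1, mu=0.0, subclonal_mu=0.0, chromosomes=("21",))
    sim = simulate_tumour(cfg)
    assert sim.variants == []


def test_same_seed_same_files(tmp_path):
    a = simulate_tumour(SMALL, seed=9)
    b = simulate_tumour(SMALL, seed=9)
    write_tumour(a, tmp_path / "a")
    write_tumour(b, tmp_path / "b")
    for name in ("SIM-0001.segments.tsv", "SIM-0001.somatic.vcf"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_different_seeds_differ():
    a = simulate_tumour(SMALL, seed=9)
    b = simulate_tumour(SMALL, seed=10)
    assert a.variants != b.variants


def test_pure_tetraploid_vaf_peak_at_quarter(rng):
    """rho=1, 2:2 genome: single-copy clonal mutations peak at VAF 1/4."""
    plan = SegmentPlan("1", 1, 50_000_000, 2, 2, event_time=0.0)
    variants, truth = simulate_segment_variants(
        plan, purity=1.0, rng=rng, mu=0.5, subclone_ccfs=(), depth=100,
    )
    assert all(t.multiplicity == 1 for t in truth)  # t=0: nothing pre-dates WGD
    vafs = [v.vaf for v in variants]
    assert np.mean(vafs) == pytest.approx(0.25, abs=0.01)


@pytest.mark.parametrize(
    "state,purity,m",
    [((2, 1), 0.8, 1), ((2, 1), 0.8, 2), ((2, 2), 0.6, 2), ((1, 1), 1.0, 1)],
)
def test_mean_vaf_matches_formula_within_3_se(state, purity, m):
    rng = np.random.default_rng(77)
    major, minor = state
    n_t = major + minor
    t = 0.5 if m == 2 else 0.0
    plan = SegmentPlan("1", 1, 200_000_000, major, minor, event_time=t)
    variants, truth = simulate_segment_variants(
        plan, purity=purity, rng=rng, subclone_ccfs=(), depth=100,
        n_informative=6000,
    )
    picked = [v.vaf for v, tr in zip(variants, truth) if tr.multiplicity == m]
    assert len(picked) >= 1000
    f = m * purity / (2 * (1 - purity) + n_t * purity)
    se = np.std(picked) / np.sqrt(len(picked))
    assert abs(np.mean(picked) - f) <= 3 * se


def test_early_fraction_encodes_wgd_time():
    """The multiplicity-2 share in a 2:2 segment implies t_hat -> t_wgd."""
    rng = np.random.default_rng(3)
    t_true = 0.3
    plan = SegmentPlan("1", 1, 100_000_000, 2, 2, event_time=t_true)
    _, truth = simulate_segment_variants(
        plan, purity=0.8, rng=rng, mu=0.2, subclone_ccfs=(), n_informative=3000,
    )
    n2 = sum(t.multiplicity == 2 for t in truth)
    n1 = len(truth) - n2
    t_hat = 2 * n2 / (2 * n2 + n1)
    assert abs(t_hat - t_true) <= 0.05


def test_unknown_state_rejected(rng):
    with pytest.raises(ValidationError):
        simulate_segment_variants(
            SegmentPlan("1", 1, 1000, 5, 2, 0.1), purity=1.0, rng=rng
        )


class TestCohort:
    def test_latent_order_holds_in_every_sample(self):
        events = [
            CohortEvent("A", "gain", "21", 0.1),
            CohortEvent("B", "gain", "22", 0.9),
        ]
        cfg = SimulationConfig(seed=2, n_samples=10, chromosomes=("21", "22"),
                               wgd_probability=0.0)
        cohort = simulate_cohort(cfg, events)
        assert cohort.true_order == ["A", "B"]
        for sim in cohort.samples:
            times = {p.chrom: p.event_time for p in sim.plans if p.event_time is not None}
            if "21" in times and "22" in times:
                assert times["21"] < times["22"]

    def test_manifest_lists_all_samples(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_samples=3, chromosomes=("21", "22"))
        cohort = simulate_cohort(cfg, [])
        manifest = write_cohort(cohort, tmp_path)
        data = json.loads(open(manifest).read())
        assert len(data["samples"]) == 3

    def test_no_events_only_stochastic_differences(self):
        cfg = SimulationConfig(seed=4, n_samples=2, chromosomes=("21",),
                               wgd_probability=1.0, cnloh_rate=0.0)
        cohort = simulate_cohort(cfg, [])
        states = [{p.state for p in s.plans} for s in cohort.samples]
        assert states[0] == states[1] == {"2:2"}


class TestHlaSim:
    def test_loh_truth_emits_low_lost_allele(self):
        cfg = SimulationConfig(seed=8, n_samples=30, hla_noise_sd=0.02,
                               hla_state_probs=(0.0, 0.0, 1.0))
        reports, truth = simulate_hla(cfg)
        for r in reports:
            assert min(r.cn1, r.cn2) < 0.5

    def test_classification_recovers_truth_states(self):
        cfg = SimulationConfig(seed=8, n_samples=60, hla_noise_sd=0.03)
        reports, truth = simulate_hla(cfg)
        label_map = {"balanced": "balanced", "imbalance": "AI", "loh": "LOH"}
        correct = sum(
            classify_hla_gene(r).classification
            == label_map[truth[(r.sample_id, r.gene)]]
            for r in reports
        )
        assert correct / len(reports) >= 0.95


class TestSvSim:
    def test_perfect_detection_no_jitter_identical_breakpoints(self):
        cfg = SimulationConfig(seed=6, sv_detection_prob=1.0, sv_jitter_sd=0.0,
                               sv_false_per_caller=0.0, sv_n_true=10)
        sim = simulate_sv_callsets(cfg)
        keysets = [
            {(c.chrom1, c.pos1, c.chrom2, c.pos2, c.sv_type) for c in calls}
            for calls in sim.callsets.values()
        ]
        assert keysets[0] == keysets[1] == keysets[2]
        assert len(keysets[0]) == 10

    def test_zero_false_rate_gives_no_private_calls(self):
        cfg = SimulationConfig(seed=6, sv_detection_prob=1.0, sv_jitter_sd=0.0,
                               sv_false_per_caller=0.0, sv_n_true=5)
        sim = simulate_sv_callsets(cfg)
        true_keys = {(s.chrom1, s.pos1) for s in sim.true_svs}
        for calls in sim.callsets.values():
            assert {(c.chrom1, c.pos1) for c in calls} <= true_keys


def test_pon_sites_artefacts_resemble_tumour_ratio():
    cfg = SimulationConfig(seed=9, pon_artefact_rate=0.5)
    sites = simulate_pon_sites(cfg, n_sites=40)
    for v, p, is_artefact in sites:
        pon_vaf = p.alt_depth_total / (p.alt_depth_total + p.ref_depth_total)
        if is_artefact:
            assert pon_vaf > 0.01
        else:
            assert pon_vaf < 0.001
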
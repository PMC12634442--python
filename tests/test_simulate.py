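"""Synthetic cohort generator and platform observation models."""

import numpy as np
import pytest
from scipy import stats

from leukotype.models import CNVKind, CNVSegment, Platform
from leukotype.simulate import (
    CohortConfig,
    default_platform_models,
    dilution_series,
    generate_cohort,
    observe_with_platform,
)


@pytest.fixture(scope="module")
def models():
    return default_platform_models()


class TestGenerator:
    def test_same_seed_gives_identical_cohorts(self):
        cfg = CohortConfig(n_cases=40, seed=5)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_cases=40, seed=5))
        b = generate_cohort(CohortConfig(n_cases=40, seed=6))
        assert a != b

    def test_invalid_weights_rejected(self):
        cfg = CohortConfig(n_cases=5, subtype_weights={"who_fusion": 0.5, "nos": 0.4})
        with pytest.raises(ValueError, match="sum"):
            generate_cohort(cfg)

    def test_two_subtype_split_within_three_binomial_sd(self):
        n = 10_000
        cfg = CohortConfig(
            n_cases=n, seed=9, subtype_weights={"who_mutation": 0.5, "nos": 0.5},
            itd_case_rate=0.0, cooperating_variant_rate=0.0, lscnv_case_rate=0.0,
        )
        cohort = generate_cohort(cfg)
        n_mut = sum(1 for c in cohort if c.variants)
        sd = (n * 0.25) ** 0.5
        assert abs(n_mut - n / 2) < 3 * sd

    def test_blast_counts_stay_in_published_range(self):
        cohort = generate_cohort(CohortConfig(n_cases=200, seed=3))
        blasts = [c.blast_percent for c in cohort]
        assert all(5.0 <= b <= 96.0 for b in blasts)
        assert 50 < np.median(blasts) < 75


class TestObservation:
    def _cnv(self, size, cf, case="X"):
        return CNVSegment(
            case_id=case, chrom="chr9", start=10_000_000, end=10_000_000 + size - 1,
            kind=CNVKind.LOSS, clone_fraction=cf,
        )

    def test_cytogenetics_sees_large_clonal_cnv(self, models):
        truth = generate_cohort(CohortConfig(n_cases=1, seed=0))[0]
        truth = truth.model_copy(update={"cnvs": [self._cnv(12_000_000, 0.8)], "svs": []})
        observed = observe_with_platform(truth, models[Platform.CYTOGENETICS], 0)
        assert len(observed.cnvs) == 1

    def test_cytogenetics_misses_sub_band_cnv(self, models):
        truth = generate_cohort(CohortConfig(n_cases=1, seed=0))[0]
        truth = truth.model_copy(update={"cnvs": [self._cnv(4_000_000, 0.9)], "svs": []})
        assert observe_with_platform(truth, models[Platform.CYTOGENETICS], 0).cnvs == []

    def test_fully_cryptic_fusion_always_missed(self, models):
        from leukotype.fixtures import _fusion_event

        truth = generate_cohort(CohortConfig(n_cases=1, seed=0))[0]
        truth = truth.model_copy(update={"svs": [_fusion_event("X", "NUP98::NSD1")], "cnvs": []})
        for seed in range(20):
            assert observe_with_platform(truth, models[Platform.CYTOGENETICS], seed).svs == []

    def test_wgs_vaf_floor_drops_subclonal_variants(self, models):
        from conftest import make_variant

        truth = generate_cohort(CohortConfig(n_cases=1, seed=0))[0]
        keep = make_variant(pos=10, wgs=0.30)
        drop = make_variant(pos=20, wgs=0.02)
        truth = truth.model_copy(update={"variants": [keep, drop]})
        observed = observe_with_platform(truth, models[Platform.WGS], 1)
        assert [v.pos for v in observed.variants] == [10]
        vaf = observed.variants[0].vaf_by_platform[Platform.WGS]
        assert 0.1 < vaf < 0.5  # binomial jitter around 0.30 at 60x


class TestDilution:
    def test_detection_monotone_over_published_purities(self, models):
        rng = np.random.default_rng(0)
        segs = [
            CNVSegment(
                case_id="COLO829", chrom="chr1", start=1, end=20_000_000,
                kind=CNVKind.LOSS, clone_fraction=float(cf),
            )
            for cf in rng.uniform(0.4, 1.0, size=50)
        ]
        d = dilution_series(segs, [1.0, 0.4, 0.3], models[Platform.WGS], 0)
        assert d[1.0] >= d[0.4] >= d[0.3]

    def test_full_purity_full_clonality_detects_everything(self, models):
        segs = [
            CNVSegment(case_id="X", chrom="chr1", start=1, end=10_000_000,
                       kind=CNVKind.LOSS, clone_fraction=1.0)
        ]
        assert dilution_series(segs, [1.0], models[Platform.WGS], 0) == {1.0: 1.0}

    def test_zero_purity_is_out_of_domain(self, models):
        segs = [
            CNVSegment(case_id="X", chrom="chr1", start=1, end=10_000_000,
                       kind=CNVKind.LOSS, clone_fraction=1.0)
        ]
        with pytest.raises(ValueError, match="purity"):
            dilution_series(segs, [0.0], models[Platform.WGS], 0)


class TestEndToEndRecovery:
    def test_ideal_sensitivity_gives_full_agreement(self, models):
        from leukotype.concord import detection_table
        from leukotype.models import PlatformModel

        ideal = PlatformModel(platform=Platform.CYTOGENETICS)  # no floors, no misses
        cohort = generate_cohort(CohortConfig(n_cases=60, seed=2))
        pairs = []
        for i, case in enumerate(cohort):
            seen = {id(sv) for sv in observe_with_platform(case, ideal, i).svs}
            # ideal model keeps every object, so compare by identity count
            pairs.extend((sv.fusion_name(), True) for sv in case.svs)
            assert len(observe_with_platform(case, ideal, i).svs) == len(case.svs)
        table = detection_table(pairs)
        assert table.total_row().pct_missed_b == 0.0

    def test_recovers_configured_cryptic_miss_rates(self, models):
        """Simulate -> observe -> tabulate recovers the configured per-fusion
        cytogenetic miss probabilities within exact binomial 95% bounds."""
        from collections import Counter

        from leukotype.simulate import default_cryptic_miss_prob

        cohort = generate_cohort(CohortConfig(n_cases=1200, seed=13))
        model = models[Platform.CYTOGENETICS]
        truth_counts: Counter = Counter()
        miss_counts: Counter = Counter()
        seed_rng = np.random.default_rng(13)  # per-case seeds off one stream
        for case in cohort:
            observed = observe_with_platform(case, model, int(seed_rng.integers(2**31)))
            kept = {
                (sv.breakpoint_a.chrom, sv.breakpoint_a.pos, sv.breakpoint_b.pos)
                for sv in observed.svs
            }
            for sv in case.svs:
                name = sv.fusion_name()
                truth_counts[name] += 1
                if (sv.breakpoint_a.chrom, sv.breakpoint_a.pos, sv.breakpoint_b.pos) not in kept:
                    miss_counts[name] += 1
        configured = default_cryptic_miss_prob()
        total_events = sum(truth_counts.values())
        assert total_events >= 500
        checked = 0
        for name, n in truth_counts.items():
            if name not in configured or n < 30:
                continue
            lo, hi = stats.binom.interval(0.95, n, configured[name])
            assert lo <= miss_counts[name] <= hi, (name, n, miss_counts[name], configured[name])
            checked += 1
        assert checked >= 3
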
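import math

import numpy as np
import pytest

from poolscan import scan
from poolscan.scan import (
    DeltaRecord,
    FilterConfig,
    RegionConfig,
    auto_cutoffs,
    compute_deltas,
    delta_frequency,
    detect_regions,
    filter_snps,
)
from poolscan.types import Phenotype, PoolDesign, PoolEntry, PoolRole, Sex

from conftest import make_record


def delta(pos, value, chrom="chr2", stratum="male"):
    return DeltaRecord(chrom=chrom, pos=pos, delta=value, sex_stratum=stratum,
                       n_pools_used=4)


class TestFilter:
    def test_depth_8_removed(self, design_male4):
        rec = make_record(100, {"r1": (8, 0.5), "r2": (30, 0.5),
                                "s1": (30, 0.5), "s2": (30, 0.5)})
        assert filter_snps([rec], FilterConfig(), design_male4, Sex.MALE) == []

    def test_depth_9_boundary_retained(self, design_male4):
        rec = make_record(100, {pid: (9, 0.5) for pid in design_male4.pools})
        assert filter_snps([rec], FilterConfig(), design_male4, Sex.MALE) == [rec]

    def test_missing_pool_removed(self, design_male4):
        rec = make_record(100, {"r1": None, "r2": (30, 0.5),
                                "s1": (30, 0.5), "s2": (30, 0.5)})
        assert filter_snps([rec], FilterConfig(), design_male4, Sex.MALE) == []

    def test_other_stratum_missing_irrelevant(self, design8):
        freqs = {pid: (30, 0.5) for pid in design8.pools}
        freqs["res_f_1"] = None  # female pool: must not affect the male scan
        rec = make_record(100, freqs)
        assert len(filter_snps([rec], FilterConfig(), design8, Sex.MALE)) == 1
        assert filter_snps([rec], FilterConfig(), design8, Sex.FEMALE) == []

    def test_empty_stratum_is_config_error(self, design_male4):
        with pytest.raises(scan.ScanConfigError):
            filter_snps([], FilterConfig(), design_male4, Sex.FEMALE)

    def test_random_tables_match_brute_force(self, design_male4):
        rng = np.random.default_rng(42)
        pool_ids = list(design_male4.pools)
        records = []
        for pos in range(1, 301):
            per_pool = {}
            for pid in pool_ids:
                if rng.random() < 0.15:
                    per_pool[pid] = None
                else:
                    per_pool[pid] = (int(rng.integers(0, 40)), float(rng.random()))
            records.append(make_record(pos, per_pool))
        cfg = FilterConfig(min_depth=9)
        got = filter_snps(records, cfg, design_male4, Sex.MALE)
        # independent row-by-row re-check of the two rules
        expected = []
        for rec in records:
            entries = [rec.per_pool[pid] for pid in pool_ids]
            if any(e is None for e in entries):
                continue
            if any(e.depth < 9 for e in entries):
                continue
            expected.append(rec)
        assert got == expected

    def test_raising_min_depth_is_monotone(self, design_male4):
        rng = np.random.default_rng(7)
        records = [
            make_record(pos, {pid: (int(rng.integers(0, 30)), 0.5)
                              for pid in design_male4.pools})
            for pos in range(1, 101)
        ]
        previous = None
        for min_depth in (0, 5, 10, 20, 40):
            n = len(filter_snps(records, FilterConfig(min_depth=min_depth),
                                design_male4, Sex.MALE))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_require_all_pools_survivors_are_subset(self, design_male4):
        rng = np.random.default_rng(11)
        records = []
        for pos in range(1, 201):
            per_pool = {pid: (None if rng.random() < 0.3 else (30, 0.5))
                        for pid in design_male4.pools}
            records.append(make_record(pos, per_pool))
        strict = filter_snps(records, FilterConfig(require_all_pools=True),
                             design_male4, Sex.MALE)
        lax = filter_snps(records, FilterConfig(require_all_pools=False),
                          design_male4, Sex.MALE)
        assert set(id(r) for r in strict) <= set(id(r) for r in lax)


class TestDelta:
    def test_plus_sixty_percent(self, design_male4):
        rec = make_record(100, {"r1": 0.9, "r2": 0.8, "s1": 0.2, "s2": 0.3})
        d = delta_frequency(rec, design_male4, Sex.MALE)
        assert d.delta == pytest.approx(0.60)
        assert d.n_pools_used == 4

    def test_all_equal_gives_zero(self, design_male4):
        rec = make_record(100, {pid: 0.5 for pid in design_male4.pools})
        assert delta_frequency(rec, design_male4, Sex.MALE).delta == 0.0

    def test_missing_frequency_is_precondition_violation(self, design_male4):
        rec = make_record(100, {"r1": None, "r2": None, "s1": 0.5, "s2": 0.5})
        with pytest.raises(ValueError, match="filter"):
            delta_frequency(rec, design_male4, Sex.MALE)

    def test_1000_random_records_match_oracle(self, design_male4):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            freqs = {pid: float(rng.random()) for pid in design_male4.pools}
            rec = make_record(100, dict(freqs))
            d = delta_frequency(rec, design_male4, Sex.MALE)
            expected = (freqs["r1"] + freqs["r2"]) / 2 - (freqs["s1"] + freqs["s2"]) / 2
            assert d.delta == pytest.approx(expected, abs=1e-15)

    def test_swapping_role_labels_negates_delta(self, design_male4):
        swapped = PoolDesign(pools={
            pid: PoolRole(
                phenotype=(Phenotype.SUSCEPTIBLE
                           if role.phenotype == Phenotype.RESISTANT
                           else Phenotype.RESISTANT),
                sex=role.sex, replicate=role.replicate,
            )
            for pid, role in design_male4.pools.items()
        })
        rng = np.random.default_rng(5)
        for _ in range(200):
            rec = make_record(100, {pid: float(rng.random())
                                    for pid in design_male4.pools})
            d1 = delta_frequency(rec, design_male4, Sex.MALE).delta
            d2 = delta_frequency(rec, swapped, Sex.MALE).delta
            assert d1 == pytest.approx(-d2, abs=1e-15)


class TestAutoCutoffs:
    def test_defaults_when_auto_off(self):
        deltas = [delta(i, 0.0) for i in range(1, 201)]
        assert auto_cutoffs(deltas, RegionConfig()) == (0.20, 0.40)

    def test_all_zero_deltas_floor(self):
        deltas = [delta(i, 0.0) for i in range(1, 201)]
        cfg = RegionConfig(auto_cutoff=True)
        assert auto_cutoffs(deltas, cfg) == (0.05, 0.10)

    def test_too_few_deltas_warns_and_uses_defaults(self):
        deltas = [delta(i, 0.0) for i in range(1, 50)]
        cfg = RegionConfig(auto_cutoff=True)
        with pytest.warns(UserWarning, match="100"):
            assert auto_cutoffs(deltas, cfg) == (0.20, 0.40)

    def test_null_deltas_at_depth_30_land_near_analytic_sd(self):
        # pure binomial read sampling at p=0.5, d=30: delta SD is
        # sqrt(p(1-p)/d) = 0.091, so mean|d| + 3 SD(|d|) rounds to ~0.25
        rng = np.random.default_rng(19)
        p, d = 0.5, 30
        deltas = []
        for i in range(5000):
            obs = rng.binomial(d, p, size=4) / d
            deltas.append(delta(i + 1, float((obs[0] + obs[1]) / 2
                                             - (obs[2] + obs[3]) / 2)))
        cfg = RegionConfig(auto_cutoff=True)
        c_low, c_high = auto_cutoffs(deltas, cfg)
        assert 0.15 <= c_low <= 0.35
        assert c_high == pytest.approx(min(2 * c_low, 1.0))


def brute_force_regions(deltas, cfg):
    """O(n^2) reimplementation of gap-bounded clustering for the oracle."""
    out = []
    for direction, sign in (("resistance", 1), ("susceptibility", -1)):
        qualifying = [d for d in deltas if sign * d.delta >= cfg.c_low]
        by_chrom = {}
        for d in qualifying:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, snps in by_chrom.items():
            snps = sorted(snps, key=lambda d: d.pos)
            # all-pairs single linkage: union adjacency within max_gap_bp
            n = len(snps)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if abs(snps[i].pos - snps[j].pos) <= cfg.max_gap_bp:
                        parent[find(j)] = find(i)
            groups = {}
            for i in range(n):
                groups.setdefault(find(i), []).append(snps[i])
            for members in groups.values():
                if len(members) < cfg.min_snps_low:
                    continue
                out.append((
                    chrom,
                    min(m.pos for m in members),
                    max(m.pos for m in members),
                    direction,
                    len(members),
                    sum(1 for m in members if sign * m.delta >= cfg.c_high),
                ))
    return sorted(out)


class TestDetectRegions:
    def test_all_zero_deltas_yield_no_regions(self):
        deltas = [delta(i * 1000, 0.0) for i in range(1, 101)]
        assert detect_regions(deltas) == []

    def test_25_consecutive_snps_form_one_region(self):
        deltas = []
        for i in range(100):
            deltas.append(delta(1 + i * 1000, 0.0))
        for i in range(25):
            deltas.append(delta(200_000 + i * 1000, 0.5))
        deltas.sort(key=lambda d: d.pos)
        regions = detect_regions(deltas)
        assert len(regions) == 1
        (reg,) = regions
        assert (reg.start, reg.end) == (200_000, 224_000)
        assert reg.n_snps_low == reg.n_snps_high == 25
        assert reg.direction == "resistance"
        assert reg.peak_delta == pytest.approx(0.5)
        # cross-check with the exhaustive reimplementation
        assert brute_force_regions(deltas, RegionConfig()) == [
            ("chr2", 200_000, 224_000, "resistance", 25, 25)
        ]

    def test_snp_exactly_at_cutoff_included(self):
        deltas = [delta(1 + i * 1000, 0.20) for i in range(25)]
        (reg,) = detect_regions(deltas)
        assert reg.n_snps_low == 25

    def test_unsorted_input_is_error(self):
        deltas = [delta(200, 0.5), delta(100, 0.5)]
        with pytest.raises(ValueError, match="sorted"):
            detect_regions(deltas)

    def test_susceptibility_direction_detected(self):
        deltas = [delta(1 + i * 1000, -0.5) for i in range(30)]
        (reg,) = detect_regions(deltas)
        assert reg.direction == "susceptibility"
        assert reg.peak_delta == pytest.approx(-0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_tracks_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = RegionConfig(c_low=0.2, c_high=0.4, max_gap_bp=5_000, min_snps_low=3)
        deltas = []
        pos = 0
        for chrom in ("chr1", "chr2"):
            pos = 0
            for _ in range(200):
                pos += int(rng.integers(100, 8_000))
                deltas.append(delta(pos, float(rng.uniform(-0.7, 0.7)), chrom=chrom))
        deltas.sort(key=lambda d: (d.chrom, d.pos))
        got = sorted(
            (r.chrom, r.start, r.end, r.direction, r.n_snps_low, r.n_snps_high)
            for r in detect_regions(deltas, cfg)
        )
        assert got == brute_force_regions(deltas, cfg)


class TestNullCalibration:
    def test_null_delta_sd_matches_analytic(self, design_male4):
        """Empirical SD of delta under a shared true frequency vs the
        binomial read + binomial bird sampling derivation."""
        rng = np.random.default_rng(23)
        p, d, pool_alleles = 0.3, 30, 20
        n_snps = 12_000
        pools = rng.binomial(pool_alleles, p, size=(n_snps, 4)) / pool_alleles
        obs = rng.binomial(d, pools) / d
        records = [
            make_record(i + 1, {"r1": (d, obs[i, 0]), "r2": (d, obs[i, 1]),
                                "s1": (d, obs[i, 2]), "s2": (d, obs[i, 3])})
            for i in range(n_snps)
        ]
        deltas = compute_deltas(records, design_male4, Sex.MALE)
        empirical_sd = float(np.std([x.delta for x in deltas]))
        # mean over two pools per side, two independent sides:
        # var = p(1-p) * (1/d + 1/pool_alleles)
        analytic_sd = math.sqrt(p * (1 - p) * (1 / d + 1 / pool_alleles))
        assert abs(empirical_sd - analytic_sd) / analytic_sd < 0.15
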
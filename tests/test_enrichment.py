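"""Per-bin enrichment, spike normalization, domain calls, and matrices."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germchrom.domains import DomainSegment, GenomicBin
from germchrom.enrichment import (
    DomainCall,
    EnrichmentTable,
    SampleLibrary,
    bin_enrichment,
    call_domains,
    class_density,
    count_reads_per_bin,
    default_pseudocount,
    enrichment_table,
    fold_change_summary,
    order_rows_by_sum,
    peak_matrix,
    rpm_scale,
    share_counts,
    share_domains,
    spike_normalization_factor,
    tss_window_enrichment,
)
from germchrom.synthetic import TaggedRead, simulate_chip_pair


def _lib(reads, role="IP", sample_id="s"):
    return SampleLibrary(sample_id, role, reads)


def _spiked(n_target, n_spike, chrom="chr1", L=10_000):
    rng = np.random.default_rng(0)
    reads = [
        TaggedRead("target", chrom, int(s), int(s) + 75)
        for s in rng.integers(0, L, n_target)
    ]
    reads += [
        TaggedRead("spike", "spike1", int(s), int(s) + 75)
        for s in rng.integers(0, L, n_spike)
    ]
    return _lib(reads)


class TestCountReadsPerBin:
    BINS = [GenomicBin("chr1", s, s + 5000) for s in range(0, 5001, 500)]

    def test_no_reads_all_zero(self):
        counts = count_reads_per_bin(_lib([]), self.BINS)
        assert (counts == 0).all()

    def test_midpoint_lands_in_every_overlapping_bin(self):
        # midpoint 2600 falls in the 6 bins starting 0..2500
        read = TaggedRead("target", "chr1", 2563, 2638)
        counts = count_reads_per_bin(_lib([read]), self.BINS)
        assert counts.sum() == 6
        hit = [b.start for b, c in zip(self.BINS, counts) if c]
        assert hit == [0, 500, 1000, 1500, 2000, 2500]

    def test_spike_reads_never_counted(self):
        reads = [TaggedRead("spike", "chr1", 2000, 2075)] * 5
        assert count_reads_per_bin(_lib(reads), self.BINS).sum() == 0

    @given(
        reads=st.lists(st.integers(0, 990), max_size=200),
        bins=st.lists(st.integers(0, 900), min_size=1, max_size=50),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_interval_counting(self, reads, bins):
        lib = _lib([TaggedRead("target", "c", s, s + 10) for s in reads])
        binlist = [GenomicBin("c", b, b + 100) for b in bins]
        counts = count_reads_per_bin(lib, binlist)
        for b, c in zip(binlist, counts):
            brute = sum(1 for s in reads if b.start <= s + 5 < b.end)
            assert c == brute


class TestRpmAndAlpha:
    def test_rpm_arithmetic(self):
        assert rpm_scale(np.array([10]), 10**6)[0] == 10
        assert rpm_scale(np.array([0]), 10**6)[0] == 0
        assert rpm_scale(np.array([37]), 2 * 10**6)[0] == pytest.approx(18.5)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            rpm_scale(np.array([1]), 0)

    def test_equal_spike_fractions_give_unit_alpha(self):
        ip = _spiked(900, 100)
        inp = _spiked(1800, 200)
        assert spike_normalization_factor(ip, inp) == pytest.approx(1.0)

    def test_worked_alpha_case(self):
        # input spike fraction 0.10, IP spike fraction 0.05 -> alpha = 2.0
        ip = _spiked(1900, 100)
        inp = _spiked(900, 100)
        assert spike_normalization_factor(ip, inp) == pytest.approx(2.0)

    def test_missing_spike_raises_with_guidance(self):
        with pytest.raises(ValueError, match="without spike normalization"):
            spike_normalization_factor(_spiked(100, 0), _spiked(90, 10))

    def test_alpha_invariant_under_subsampling(self, small_genome, small_config):
        segments, _ = small_genome
        ip, inp = simulate_chip_pair(segments, small_config)
        alpha_full = spike_normalization_factor(_lib(ip), _lib(inp, "Input"))
        rng = np.random.default_rng(1)
        sub_ip = [r for r in ip if rng.random() < 0.5]
        sub_in = [r for r in inp if rng.random() < 0.5]
        alpha_sub = spike_normalization_factor(_lib(sub_ip), _lib(sub_in, "Input"))
        assert alpha_sub == pytest.approx(alpha_full, rel=0.05)

    def test_global_signal_doubling_doubles_normalized_enrichment(
        self, small_genome, small_config
    ):
        # doubling every target IP rate at fixed spike mass dilutes the IP
        # spike fraction; spike normalization must restore the 2x gain
        segments, _ = small_genome
        cfg = dataclasses.replace(small_config, ip_depth=100_000,
                                  input_depth=100_000)
        bins = [
            GenomicBin(s.chrom, st_, st_ + 5000, s.cls)
            for s in segments
            if len(s) >= 5000
            for st_ in range(s.start, s.end - 5000 + 1, 5000)
        ]
        mult = cfg.enrichment_multipliers
        doubled = {k: 2 * v for k, v in mult.items()}
        means = {}
        for name, m in (("base", mult), ("doubled", doubled)):
            ip, inp = simulate_chip_pair(segments, cfg, multipliers=m,
                                         stage=f"chip-{name}")
            table = enrichment_table(_lib(ip), _lib(inp, "Input"), bins,
                                     epsilon=0.0)
            means[name] = table.enrichment.mean()
        assert means["doubled"] / means["base"] == pytest.approx(2.0, rel=0.05)


class TestBinEnrichment:
    def test_identical_tracks_give_unit_enrichment(self):
        bins = [GenomicBin("c", 0, 5000), GenomicBin("c", 500, 5500)]
        rpm = np.array([3.0, 7.0])
        table = bin_enrichment(bins, rpm, rpm, alpha=1.0, epsilon=0.1)
        assert table.enrichment == pytest.approx([1.0, 1.0])

    def test_worked_ratio(self):
        bins = [GenomicBin("c", 0, 5000)]
        t = bin_enrichment(bins, np.array([20.0]), np.array([2.0]),
                           alpha=1.0, epsilon=0.0)
        assert t.enrichment[0] == pytest.approx(10.0)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError, match="align"):
            bin_enrichment([GenomicBin("c", 0, 5000)], np.zeros(2), np.zeros(2))

    def test_rpm_weighted_mean_is_one_without_normalization(self, small_genome,
                                                            small_config):
        # with eps = 0 and alpha = 1, Input-RPM-weighted mean of E over the
        # bin universe equals 1 (both totals computed over the same reads)
        segments, _ = small_genome
        ip, inp = simulate_chip_pair(segments, small_config)
        bins = [GenomicBin("chr1", s, s + 5000)
                for s in range(0, 200_000 - 5000 + 1, 5000)]
        lib_ip, lib_in = _lib(ip), _lib(inp, "Input")
        ip_rpm = rpm_scale(count_reads_per_bin(lib_ip, bins), lib_ip.target_count)
        in_rpm = rpm_scale(count_reads_per_bin(lib_in, bins), lib_in.target_count)
        ok = in_rpm > 0
        weighted = np.average(ip_rpm[ok] / in_rpm[ok], weights=in_rpm[ok])
        assert weighted == pytest.approx(1.0, rel=1e-9)


class TestClassRecovery:
    def test_multiplier_ratios_recovered_per_class(self, small_genome,
                                                   small_config):
        segments, _ = small_genome
        cfg = dataclasses.replace(small_config, ip_depth=200_000,
                                  input_depth=200_000)
        from germchrom.domains import annotate_bins, make_bins

        bins = annotate_bins(make_bins({"chr1": cfg.chrom_length}), segments)
        ip, inp = simulate_chip_pair(segments, cfg)
        table = enrichment_table(_lib(ip), _lib(inp, "Input"), bins)
        cls = table.classes()
        med = {
            c: np.median(table.enrichment[cls == c])
            for c in ("active", "inactive", "PcG")
        }
        m = cfg.enrichment_multipliers
        assert med["PcG"] / med["inactive"] == pytest.approx(
            m["PcG"] / m["inactive"], rel=0.1
        )
        assert med["active"] / med["inactive"] == pytest.approx(
            m["active"] / m["inactive"], rel=0.1
        )


class TestClassDensity:
    def _table(self, values, classes):
        bins = [
            GenomicBin("c", i * 500, i * 500 + 5000, cls)
            for i, cls in enumerate(classes)
        ]
        return EnrichmentTable(bins, 1.0, 0.0, np.asarray(values, dtype=float))

    def test_unit_enrichment_concentrates_at_zero(self):
        t = self._table([1.0] * 10, ["PcG"] * 10)
        dens = class_density(t, classes=("PcG",))
        grid, d = dens["PcG"]
        assert abs(grid[np.argmax(d)]) < 0.1

    def test_each_class_curve_integrates_to_one(self):
        rng = np.random.default_rng(0)
        values = np.exp(rng.normal(0, 1, 200))
        classes = ["PcG"] * 100 + ["inactive"] * 100
        dens = class_density(self._table(values, classes))
        for grid, d in dens.values():
            assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=1e-6)

    def test_empty_class_omitted_with_warning(self):
        t = self._table([1.0, 2.0], ["PcG", "PcG"])
        with pytest.warns(UserWarning, match="active"):
            dens = class_density(t, classes=("PcG", "active"))
        assert set(dens) == {"PcG"}


class TestDomainCallsAndSharing:
    def _uniform_table(self, value, cls="PcG", n=5):
        bins = [GenomicBin("c", i * 5000, (i + 1) * 5000, cls) for i in range(n)]
        return EnrichmentTable(bins, 1.0, 0.0, np.full(n, float(value)))

    def test_enriched_domain_call(self):
        dom = DomainSegment("c", 0, 25_000, "PcG")
        calls = call_domains([dom], self._uniform_table(10.0), threshold=2.0)
        assert calls[0].enriched is True
        assert calls[0].mean_enrichment == pytest.approx(10.0)

    def test_domain_without_usable_bins_reported_undefined(self):
        dom = DomainSegment("c", 0, 25_000, "active")  # bins are PcG-classed
        calls = call_domains([dom], self._uniform_table(10.0))
        assert calls[0].enriched is None
        assert np.isnan(calls[0].mean_enrichment)

    def test_short_domains_excluded_by_span_cutoff(self):
        dom = DomainSegment("c", 0, 9000, "PcG")
        assert call_domains([dom], self._uniform_table(10.0)) == []

    def test_perfect_three_way_sharing(self):
        doms = [DomainSegment("c", i * 30_000, (i + 1) * 30_000, "PcG")
                for i in range(5)]
        bins = [GenomicBin("c", s, s + 5000, "PcG")
                for s in range(0, 150_000 - 5000 + 1, 5000)]
        table = EnrichmentTable(bins, 1.0, 0.0, np.full(len(bins), 10.0))
        calls = {
            s: call_domains(doms, table) for s in ("follicle", "nurse", "S2")
        }
        sharing = share_domains(calls)
        assert sharing["shared_all"] == 5
        assert sharing["union"] == 5
        assert sharing["pct_shared"] == pytest.approx(100.0)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_sharing_equals_set_algebra_oracle(self, data):
        n_dom = data.draw(st.integers(1, 20))
        n_samp = data.draw(st.integers(1, 4))
        mat = data.draw(
            st.lists(
                st.lists(st.booleans(), min_size=n_samp, max_size=n_samp),
                min_size=n_dom,
                max_size=n_dom,
            )
        )
        frame = pd.DataFrame(mat, columns=[f"s{i}" for i in range(n_samp)])
        res = share_counts(frame)
        sets = [
            {d for d in range(n_dom) if mat[d][s]} for s in range(n_samp)
        ]
        inter = set.intersection(*sets)
        union = set.union(*sets)
        assert res["shared_all"] == len(inter)
        assert res["union"] == len(union)
        if union:
            assert res["pct_shared"] == pytest.approx(100 * len(inter) / len(union))


class TestFoldChangeSummary:
    def _tables(self, e_a, e_b, classes, pre=None):
        bins = [
            GenomicBin("c", i * 5000, (i + 1) * 5000, cls,
                       bool(pre[i]) if pre is not None else False)
            for i, cls in enumerate(classes)
        ]
        ta = EnrichmentTable(bins, 1.0, 0.0, np.asarray(e_a, dtype=float))
        tb = EnrichmentTable(bins, 1.0, 0.0, np.asarray(e_b, dtype=float))
        return ta, tb

    def test_identical_tables_give_zero_medians(self):
        e = [1.0, 2.0, 4.0, 8.0]
        ta, tb = self._tables(e, e, ["inactive", "inactive", "PcG", "PcG"])
        _, summary = fold_change_summary(ta, tb)
        assert summary.loc["inactive", "median"] == 0
        assert summary.loc["PcG", "median"] == 0

    def test_notch_width_halves_when_n_quadruples(self):
        rng = np.random.default_rng(3)
        vals = np.exp(rng.normal(0, 0.5, 100))
        ta, tb = self._tables(vals, np.ones(100), ["PcG"] * 100)
        _, s1 = fold_change_summary(ta, tb, classes=("PcG",))
        ta4, tb4 = self._tables(np.tile(vals, 4), np.ones(400), ["PcG"] * 400)
        _, s4 = fold_change_summary(ta4, tb4, classes=("PcG",))
        ratio = s4.loc["PcG", "notch"] / s1.loc["PcG", "notch"]
        assert ratio == pytest.approx(0.5, rel=0.01)

    def test_mismatched_bins_raise(self):
        ta, _ = self._tables([1.0], [1.0], ["PcG"])
        _, tb = self._tables([1.0, 1.0], [1.0, 1.0], ["PcG", "PcG"])
        with pytest.raises(ValueError, match="identical bin list"):
            fold_change_summary(ta, tb)

    def test_pre_split_partitions_pcg_bins(self):
        e = [2.0, 4.0, 8.0, 1.0]
        ta, tb = self._tables(e, e, ["PcG", "PcG", "PcG", "inactive"],
                              pre=[1, 0, 0, 0])
        _, summary = fold_change_summary(ta, tb, classes=("inactive", "PcG"),
                                         split_pre=True)
        assert summary.loc["PRE", "n"] == 1
        assert summary.loc["PcG", "n"] == 2

    def test_simulated_pcg_knockdown_direction(self, small_genome, small_config):
        # halving only the PcG IP rate: PcG bins move to about -1 in log2,
        # inactive bins stay near 0
        segments, _ = small_genome
        cfg = dataclasses.replace(small_config, ip_depth=200_000,
                                  input_depth=200_000)
        from germchrom.domains import annotate_bins, make_bins

        bins = annotate_bins(make_bins({"chr1": cfg.chrom_length}), segments)
        ip_c, in_c = simulate_chip_pair(segments, cfg, stage="ctrl")
        kd = dict(cfg.enrichment_multipliers)
        kd["PcG"] /= 2
        ip_k, in_k = simulate_chip_pair(segments, cfg, multipliers=kd,
                                        stage="kd")
        tc = enrichment_table(_lib(ip_c), _lib(in_c, "Input"), bins)
        tk = enrichment_table(_lib(ip_k), _lib(in_k, "Input"), bins)
        _, summary = fold_change_summary(tk, tc)
        assert summary.loc["PcG", "median"] == pytest.approx(-1.0, abs=0.15)
        assert summary.loc["inactive", "median"] == pytest.approx(0.0, abs=0.15)


class TestPeakMatrix:
    SIZES = {"chr1": 100_000}

    def test_no_reads_all_zero(self):
        mat = peak_matrix(_lib([]), [("chr1", 50_000)], self.SIZES)
        assert mat.shape == (1, 100)
        assert (mat == 0).all()

    def test_read_at_summit_fills_center_column(self):
        read = TaggedRead("target", "chr1", 49_990, 50_010)  # midpoint 50000
        mat = peak_matrix(_lib([read]), [("chr1", 50_000)], self.SIZES,
                          window=20_000, binsize=200)
        assert mat[0, 50] == 1  # column covering [50000, 50200)
        assert np.nansum(mat) == 1

    def test_summit_near_chromosome_end_pads_nan(self):
        mat = peak_matrix(_lib([]), [("chr1", 5000)], self.SIZES,
                          window=20_000, binsize=200)
        assert np.isnan(mat[0, :25]).all()  # columns before base 0
        assert np.isfinite(mat[0, 25:]).all()

    def test_row_sums_equal_brute_force_window_counts(self):
        rng = np.random.default_rng(7)
        starts = rng.integers(0, 99_000, 500)
        reads = [TaggedRead("target", "chr1", int(s), int(s) + 50)
                 for s in starts]
        summits = [("chr1", 30_000), ("chr1", 60_000)]
        mat = peak_matrix(_lib(reads), summits, self.SIZES)
        mids = starts + 25
        for row, (_, pos) in zip(mat, summits):
            brute = int(((mids >= pos - 10_000) & (mids < pos + 10_000)).sum())
            assert np.nansum(row) == brute

    def test_row_ordering_by_sum(self):
        mat = np.array([[1.0, 0.0], [3.0, 4.0], [2.0, 0.0]])
        assert list(order_rows_by_sum(mat)) == [1, 2, 0]

    def test_no_summits_raise(self):
        with pytest.raises(ValueError, match="summit"):
            peak_matrix(_lib([]), [], self.SIZES)


class TestTssWindowEnrichment:
    SIZES = {"chr1": 50_000}

    def _libs(self):
        reads = [TaggedRead("target", "chr1", 10_100, 10_150)] * 6
        reads += [TaggedRead("target", "chr1", 9600, 9650)] * 2
        ip = _lib(reads + [TaggedRead("spike", "spike1", 0, 75)] * 10)
        inp_reads = [TaggedRead("target", "chr1", s, s + 50)
                     for s in range(0, 50_000, 100)]
        inp = _lib(inp_reads + [TaggedRead("spike", "spike1", 0, 75)] * 55,
                   role="Input")
        return ip, inp

    def test_strand_aware_windows(self):
        ip, inp = self._libs()
        res = tss_window_enrichment(
            ip, inp,
            [("gplus", "chr1", 10_000, "+"), ("gminus", "chr1", 10_000, "-")],
            self.SIZES, alpha=1.0, epsilon=0.0,
        )
        assert (res.loc["gplus", ["start", "end"]] == [10_000, 10_500]).all()
        assert (res.loc["gminus", ["start", "end"]] == [9_500, 10_000]).all()

    def test_values_match_direct_midpoint_recomputation(self):
        ip, inp = self._libs()
        res = tss_window_enrichment(
            ip, inp, [("g", "chr1", 10_000, "+")], self.SIZES,
            alpha=1.0, epsilon=0.0,
        )
        # 6 IP midpoints at 10125 in [10000, 10500); input has 5 midpoints
        ip_rpm = 6 * 1e6 / ip.total
        in_rpm = 5 * 1e6 / inp.total
        assert res.loc["g", "enrichment"] == pytest.approx(ip_rpm / in_rpm)

    def test_window_off_chromosome_is_undefined(self):
        ip, inp = self._libs()
        res = tss_window_enrichment(
            ip, inp, [("g", "chr1", 200, "-")], self.SIZES, alpha=1.0,
        )
        assert not res.loc["g", "defined"]
        assert np.isnan(res.loc["g", "enrichment"])
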
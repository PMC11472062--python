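"""QC statistics: quality summaries, PCR-cycle bias, GC correlation, pool concordance."""

import math

import numpy as np
import pytest
from scipy import stats

from dorqseq import (
    AbundanceTable,
    PoolComposition,
    ProbeSet,
    Read,
    SimConfig,
    compare_pools,
    gc_bias_correlation,
    pcr_bias_profile,
    pcr_weights,
    qscore_summary,
    quantify_sample,
    simulate_reads,
)
from dorqseq.probe_design import Family, build_probe
from dorqseq.qc_bias import (
    BaselineMissingError,
    BiasProfile,
    DegenerateError,
    EmptyInputError,
    InsufficientOverlapError,
)


def _table(counts):
    total = sum(counts.values())
    return AbundanceTable(counts=counts, total_reads=total, too_short=0, unassigned=0)


def _reads(quality_lists):
    return [
        Read(id=f"r{i}", sequence="A" * len(qs), qualities=tuple(qs))
        for i, qs in enumerate(quality_lists)
    ]


class TestQscoreSummary:
    def test_uniform_quality(self):
        summary = qscore_summary(_reads([[33] * 10] * 3))
        assert summary["mean_q"] == 33.0
        assert summary["fraction_bases_below_q30"] == 0.0

    def test_arithmetic_mean_of_mixed(self):
        summary = qscore_summary(_reads([[30] * 5, [40] * 5]))
        assert summary["mean_q"] == 35.0
        assert summary["fraction_bases_below_q30"] == 0.0
        summary = qscore_summary(_reads([[29] * 5, [40] * 5]))
        assert summary["fraction_bases_below_q30"] == 0.5

    def test_per_position_means(self):
        summary = qscore_summary(_reads([[30, 40], [40, 40]]))
        assert summary["per_position_mean"] == [35.0, 40.0]

    def test_reorder_invariant(self):
        a = _reads([[30] * 4, [38] * 4, [20] * 4])
        assert qscore_summary(a)["mean_q"] == qscore_summary(a[::-1])["mean_q"]

    def test_simulator_emits_configured_q(self, small_probe_set):
        comp = PoolComposition({small_probe_set.names[0]: 1.0})
        reads = simulate_reads(
            small_probe_set, comp, SimConfig(n_reads=100, q_score=34.0, seed=3)
        )
        assert qscore_summary(reads)["mean_q"] == 34.0

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            qscore_summary([])


class TestPcrBiasProfile:
    def test_identical_tables_give_unit_fold_change(self):
        table = _table({"a": 50, "b": 50})
        profiles = pcr_bias_profile({2: table, 6: table})
        assert profiles[6].fold_change == {"a": 1.0, "b": 1.0}
        assert profiles[6].max_enrichment == 1.0
        assert profiles[6].baseline_cycle == 2

    def test_matches_pcr_weights_closed_form(self):
        # two families 0.5/0.5, e=(1.0, 0.5), 6 cycles: 0.849/0.151
        base = PoolComposition({"a": 0.5, "b": 0.5})
        eff = {"a": 1.0, "b": 0.5}
        amplified = pcr_weights(base, eff, 6)
        tables = {
            0: _table({"a": 5000, "b": 5000}),
            6: _table(
                {
                    "a": round(10_000 * amplified["a"]),
                    "b": round(10_000 * amplified["b"]),
                }
            ),
        }
        profile = pcr_bias_profile(tables)[6]
        assert profile.fold_change["a"] == pytest.approx(1.698, abs=1e-3)
        assert profile.fold_change["b"] == pytest.approx(0.302, abs=1e-3)

    def test_closed_form_exact_for_generated_tables(self):
        base = PoolComposition({"a": 0.2, "b": 0.3, "c": 0.5})
        eff = {"a": 0.9, "b": 0.6, "c": 0.3}
        n = 10**7
        tables = {}
        for cycles in (2, 5, 9):
            comp = pcr_weights(base, eff, cycles)
            tables[cycles] = _table(
                {f: round(n * comp[f]) for f in comp.fractions}
            )
        profiles = pcr_bias_profile(tables)  # baseline 2
        for cycles in (5, 9):
            base_comp = pcr_weights(base, eff, 2)
            comp = pcr_weights(base, eff, cycles)
            for fam in ("a", "b", "c"):
                assert profiles[cycles].fold_change[fam] == pytest.approx(
                    comp[fam] / base_comp[fam], rel=1e-5
                )

    def test_flagging_threshold(self):
        profiles = pcr_bias_profile(
            {0: _table({"a": 50, "b": 50}), 6: _table({"a": 80, "b": 20})}
        )
        flagged = profiles[6].flagged(threshold=0.5)
        assert "b" in flagged  # 0.4x is |log2| = 1.32
        assert "a" in flagged  # 1.6x is |log2| = 0.68
        assert profiles[6].flagged(threshold=1.5) == {}

    def test_missing_baseline(self):
        table = _table({"a": 1})
        with pytest.raises(BaselineMissingError):
            pcr_bias_profile({3: table, 6: table}, baseline=2)

    def test_absent_at_baseline_flagged_not_divided(self):
        profiles = pcr_bias_profile(
            {0: _table({"a": 100, "b": 0}), 6: _table({"a": 50, "b": 50})}
        )
        assert profiles[6].absent_at_baseline == ("b",)
        assert "b" not in profiles[6].fold_change


def _probe_set_with_gc(gc_counts):
    # recognitions with controlled G+C content, mutually distant
    probes = []
    for i, gc in enumerate(gc_counts):
        region = ("G" * gc + "A" * (40 - gc)) if i % 2 == 0 else (
            "C" * gc + "T" * (40 - gc)
        )
        probes.append(
            build_probe(Family((f"r{i}",), region), f"p{i}", "cytosolic")
        )
    return ProbeSet(probes=probes)


class TestGcBiasCorrelation:
    def test_exact_linear_dependence(self):
        probe_set = _probe_set_with_gc([8, 16, 24, 32])
        profile = BiasProfile(
            baseline_cycle=0, cycle=6,
            fold_change={p.name: 2.0 ** (2 * p.gc_fraction) for p in probe_set},
            log2_fc={p.name: 2 * p.gc_fraction for p in probe_set},
            absent_at_baseline=(),
        )
        result = gc_bias_correlation(profile, probe_set)
        assert result["pearson_r"] == pytest.approx(1.0)

    def test_constant_fold_change_degenerate(self):
        probe_set = _probe_set_with_gc([8, 16, 24])
        profile = BiasProfile(
            baseline_cycle=0, cycle=6,
            fold_change={p.name: 1.0 for p in probe_set},
            log2_fc={p.name: 0.0 for p in probe_set},
            absent_at_baseline=(),
        )
        result = gc_bias_correlation(profile, probe_set)
        assert result["pearson_r"] == 0.0
        assert result["degenerate"]

    def test_zero_gc_variance_raises(self):
        # same GC content, distinct recognitions
        probes = [
            build_probe(
                Family((f"r{i}",), "A" * i + "G" * 20 + "A" * (20 - i)),
                f"p{i}", "cytosolic",
            )
            for i in range(3)
        ]
        probe_set = ProbeSet(probes=probes)
        profile = BiasProfile(
            baseline_cycle=0, cycle=6,
            fold_change={p.name: 1.0 + i for i, p in enumerate(probe_set)},
            log2_fc={p.name: float(i) for i, p in enumerate(probe_set)},
            absent_at_baseline=(),
        )
        with pytest.raises(DegenerateError):
            gc_bias_correlation(profile, probe_set)

    def test_independent_fold_changes_weakly_correlated(self):
        """Null Pearson r at n=38: |r| < 0.32 for ~95% of seeds."""
        probe_set = _probe_set_with_gc(list(range(2, 40)))  # 38 probes
        rng = np.random.default_rng(55)
        below = 0
        n_trials = 100
        for _ in range(n_trials):
            log2_fc = {p.name: float(x) for p, x in zip(
                probe_set, rng.normal(0, 1, size=38)
            )}
            profile = BiasProfile(
                baseline_cycle=0, cycle=6,
                fold_change={k: 2.0**v for k, v in log2_fc.items()},
                log2_fc=log2_fc, absent_at_baseline=(),
            )
            r = gc_bias_correlation(profile, probe_set)["pearson_r"]
            if abs(r) < 0.32:
                below += 1
        assert below >= 90  # expected ~95, with binomial slack


class TestComparePools:
    def test_identical_tables_perfect(self):
        table = _table({"a": 10, "b": 30, "c": 60})
        result = compare_pools(table, table)
        assert result["r_squared"] == pytest.approx(1.0)
        assert result["adjusted_r_squared"] == pytest.approx(1.0)

    def test_permuted_fractions_lose_concordance(self):
        counts = {"a": 5, "b": 10, "c": 20, "d": 40, "e": 80, "f": 160}
        names = list(counts)
        permuted = dict(zip(names, [counts[n] for n in names[1:] + names[:1]]))
        result = compare_pools(_table(counts), _table(permuted))
        assert result["r_squared"] < 0.5

    def test_symmetric(self):
        a = _table({"a": 11, "b": 29, "c": 45, "d": 15})
        b = _table({"a": 18, "b": 31, "c": 36, "d": 15})
        assert compare_pools(a, b)["r_squared"] == pytest.approx(
            compare_pools(b, a)["r_squared"]
        )

    def test_adjusted_r2_formula(self):
        a = _table({"a": 11, "b": 29, "c": 45, "d": 15})
        b = _table({"a": 18, "b": 31, "c": 36, "d": 15})
        result = compare_pools(a, b)
        r2, n = result["r_squared"], result["n"]
        assert result["adjusted_r_squared"] == pytest.approx(
            1 - (1 - r2) * (n - 1) / (n - 2)
        )

    def test_replicate_simulations_concordant(self, ten_family_probe_set):
        rng = np.random.default_rng(66)
        raw = rng.dirichlet(np.full(10, 3.0))
        comp = PoolComposition.from_weights(
            dict(zip(ten_family_probe_set.names, raw.tolist()))
        )
        tables = [
            quantify_sample(
                simulate_reads(
                    ten_family_probe_set, comp,
                    SimConfig(n_reads=100_000, q_score=33.6, seed=seed),
                ),
                ten_family_probe_set,
            )
            for seed in (1, 2)
        ]
        assert compare_pools(*tables)["r_squared"] >= 0.99

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientOverlapError):
            compare_pools(_table({"a": 1, "b": 1}), _table({"a": 1, "b": 1}))
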
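"""Tests of the probe-level DSP chain: AOI QC, Grubbs flagging, probe
collapse, negative factors, Q3 normalization, morphology DEG, signatures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bccniche as bn
from bccniche.dsp import NormalizedAOITable, grubbs_critical_value

from conftest import make_probe_table, small_sim_config


# ---------------------------------------------------------------------------
# AOI QC


class TestAoiQC:
    def make(self):
        counts = {"low": {"p1": 5000, "p2": 4999},
                  "edge": {"p1": 5000, "p2": 5000},
                  "high": {"p1": 20000, "p2": 20000}}
        table = make_probe_table(counts, {"p1": "GENE", "p2": "NEGATIVE"})
        return table

    def test_boundary(self):
        kept = bn.aoi_qc(self.make(), min_reads=10_000).counts.index
        assert "low" not in kept        # 9,999 reads
        assert "edge" in kept           # exactly 10,000
        assert "high" in kept

    def test_all_dropped_errors(self):
        with pytest.raises(ValueError, match="minimum"):
            bn.aoi_qc(self.make(), min_reads=10 ** 9)

    def test_empty_table_errors(self):
        table = self.make()
        with pytest.raises(ValueError):
            bn.aoi_qc(table.subset_aois(pd.Index([])))


# ---------------------------------------------------------------------------
# Grubbs outlier flagging


def independent_grubbs_decision(values, alpha):
    """Direct textbook evaluation of the two-sided Grubbs test."""
    x = np.log2(np.asarray(values, dtype=float) + 1.0)
    n = len(x)
    s = x.std(ddof=1)
    if s == 0 or n < 3:
        return None
    g = np.abs(x - x.mean()).max() / s
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
    return (int(np.abs(x - x.mean()).argmax()), g > crit)


def _one_target_table(probe_counts_per_aoi):
    probes = [f"p{j}" for j in range(len(next(iter(probe_counts_per_aoi.values()))))]
    counts = {aoi: dict(zip(probes, vals))
              for aoi, vals in probe_counts_per_aoi.items()}
    counts = {aoi: {**v, "neg": 5} for aoi, v in counts.items()}
    gene_map = {p: "G1" for p in probes}
    gene_map["neg"] = "NEGATIVE"
    return make_probe_table(counts, gene_map)


class TestGrubbs:
    def test_zero_variance_not_flagged(self):
        table = _one_target_table({"a1": [8, 8, 8, 8]})
        flags, excluded = bn.flag_outlier_probes(table)
        assert not flags.to_numpy().any() and len(excluded) == 0

    def test_decision_matches_independent_formula(self):
        vals = [2 ** 3 - 1, 2 ** 3 - 1, 2 ** 3 - 1, 2 ** 10 - 1]  # log2 = 3,3,3,10
        table = _one_target_table({"a1": vals})
        flags, _ = bn.flag_outlier_probes(table, alpha=0.01)
        idx, expected = independent_grubbs_decision(vals, 0.01)
        assert bool(flags.iloc[0, idx]) == expected

    def test_two_probe_targets_pass_untested(self):
        table = _one_target_table({"a1": [1, 100000]})
        flags, _ = bn.flag_outlier_probes(table)
        assert not flags.to_numpy().any()

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            vals = rng.poisson(rng.uniform(5, 500), size=n)
            table = _one_target_table({"a1": list(vals)})
            flags, _ = bn.flag_outlier_probes(table, alpha=0.01)
            oracle = independent_grubbs_decision(vals, 0.01)
            if oracle is None:
                assert not flags.to_numpy().any()
            else:
                idx, hit = oracle
                assert bool(flags.iloc[0].to_numpy().any()) == hit
                if hit:
                    assert bool(flags.iloc[0, idx])

    def test_planted_outlier_flagged_in_most_aois(self):
        """An 8x aberrant probe on a well-expressed 5-probe target is flagged
        in >=95% of 200 replicate AOIs at alpha 0.01."""
        rng = np.random.default_rng(1)
        aois = {f"a{i:03d}": list(rng.poisson([200] * 4 + [1600]))
                for i in range(200)}
        table = _one_target_table(aois)
        flags, excluded = bn.flag_outlier_probes(table, alpha=0.01)
        assert flags["p4"].mean() >= 0.95
        assert "p4" in excluded

    def test_global_exclusion_via_simulation(self):
        """Planted aberrant probes on well-expressed targets are globally
        excluded from the simulated study."""
        cfg = small_sim_config(seed=31, probes_per_gene=5, n_aoi_per_group=13,
                               outlier_probe_rate=0.01, probe_cv=0.05,
                               aoi_depth=2.5e5)
        adata, truth = bn.simulate_sc_counts(cfg)
        table, truth = bn.simulate_dsp_probes(cfg, truth)
        flags, excluded = bn.flag_outlier_probes(table)
        medians = table.counts.median(axis=0)
        strong = [p for p in truth.planted_outlier_probes if medians[p] >= 100]
        assert len(strong) >= 3
        assert np.mean([p in excluded for p in strong]) >= 0.9


# ---------------------------------------------------------------------------
# Probe collapse and negative factors


class TestCollapse:
    def test_geometric_mean_exact(self):
        table = make_probe_table({"a1": {"p1": 4, "p2": 9, "n": 3}},
                                 {"p1": "G", "p2": "G", "n": "NEGATIVE"})
        out = bn.collapse_probes(table)
        assert out.loc["G", "a1"] == pytest.approx(6.0, abs=1e-9)

    def test_three_equal_probes(self):
        table = make_probe_table({"a1": {"p1": 8, "p2": 8, "p3": 8, "n": 3}},
                                 {"p1": "G", "p2": "G", "p3": "G",
                                  "n": "NEGATIVE"})
        assert bn.collapse_probes(table).loc["G", "a1"] == pytest.approx(8.0)

    def test_flagged_probe_excluded(self):
        table = make_probe_table(
            {"a1": {"p1": 4, "p2": 9, "p3": 1000, "n": 3}},
            {"p1": "G", "p2": "G", "p3": "G", "n": "NEGATIVE"})
        flags = pd.DataFrame(False, index=["a1"], columns=["p1", "p2", "p3"])
        flags.loc["a1", "p3"] = True
        out = bn.collapse_probes(table, flags)
        assert out.loc["G", "a1"] == pytest.approx(6.0, abs=1e-9)

    def test_globally_excluded_probe_removed_everywhere(self):
        table = make_probe_table(
            {"a1": {"p1": 4, "p2": 9, "p3": 7, "n": 3},
             "a2": {"p1": 16, "p2": 36, "p3": 7, "n": 3}},
            {"p1": "G", "p2": "G", "p3": "G", "n": "NEGATIVE"})
        out = bn.collapse_probes(table, excluded=pd.Index(["p3"]))
        assert out.loc["G", "a1"] == pytest.approx(6.0, abs=1e-9)
        assert out.loc["G", "a2"] == pytest.approx(24.0, abs=1e-9)

    def test_probe_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 100, size=6)
        t1 = make_probe_table(
            {"a1": {f"p{j}": int(vals[j]) for j in range(6)} | {"n": 2}},
            {f"p{j}": "G" for j in range(6)} | {"n": "NEGATIVE"})
        perm = rng.permutation(6)
        t2 = make_probe_table(
            {"a1": {f"p{j}": int(vals[perm[j]]) for j in range(6)} | {"n": 2}},
            {f"p{j}": "G" for j in range(6)} | {"n": "NEGATIVE"})
        assert bn.collapse_probes(t1).loc["G", "a1"] == pytest.approx(
            bn.collapse_probes(t2).loc["G", "a1"], abs=1e-9)

    def test_scale_equivariance(self):
        table = make_probe_table({"a1": {"p1": 4, "p2": 9, "n": 3}},
                                 {"p1": "G", "p2": "G", "n": "NEGATIVE"})
        scaled = make_probe_table({"a1": {"p1": 12, "p2": 27, "n": 3}},
                                  {"p1": "G", "p2": "G", "n": "NEGATIVE"})
        assert bn.collapse_probes(scaled).loc["G", "a1"] == pytest.approx(
            3 * bn.collapse_probes(table).loc["G", "a1"], abs=1e-9)


class TestNegativeFactors:
    def test_geometric_mean(self):
        table = make_probe_table({"a1": {"n1": 10, "n2": 40, "p1": 5}},
                                 {"n1": "NEGATIVE", "n2": "NEGATIVE",
                                  "p1": "G"})
        out = bn.negative_probe_factors(table)
        assert out.loc["a1", "P1"] == pytest.approx(20.0)

    def test_single_negative(self):
        table = make_probe_table({"a1": {"n1": 7, "p1": 5}},
                                 {"n1": "NEGATIVE", "p1": "G"})
        assert bn.negative_probe_factors(table).loc["a1", "P1"] == pytest.approx(7.0)

    def test_all_zero_negatives_pseudocount(self):
        table = make_probe_table({"a1": {"n1": 0, "n2": 0, "p1": 5}},
                                 {"n1": "NEGATIVE", "n2": "NEGATIVE",
                                  "p1": "G"})
        assert bn.negative_probe_factors(table).loc["a1", "P1"] == pytest.approx(0.5)

    def test_per_pool_factors(self):
        table = make_probe_table(
            {"a1": {"n1": 10, "n2": 40, "p1": 5}},
            {"n1": "NEGATIVE", "n2": "NEGATIVE", "p1": "G"},
            probe_pool={"n1": "P1", "n2": "P2", "p1": "P1"})
        out = bn.negative_probe_factors(table)
        assert out.loc["a1", "P1"] == pytest.approx(10.0)
        assert out.loc["a1", "P2"] == pytest.approx(40.0)


# ---------------------------------------------------------------------------
# Q3 normalization


class TestQ3:
    def test_identical_aois_identity(self):
        g = pd.DataFrame({"a1": [1.0, 2, 3, 4], "a2": [1.0, 2, 3, 4]},
                         index=list("wxyz"))
        out = bn.q3_normalize(g)
        assert (out.q3_factors == 1.0).all()
        pd.testing.assert_frame_equal(out.values, g)

    def test_two_aoi_factors(self):
        g = pd.DataFrame({"a1": [100.0] * 4, "a2": [400.0] * 4})
        out = bn.q3_normalize(g)
        assert out.q3_factors["a1"] == pytest.approx(0.5)
        assert out.q3_factors["a2"] == pytest.approx(2.0)
        assert out.values.quantile(0.75, axis=0).tolist() == pytest.approx(
            [200.0, 200.0])

    def test_post_normalization_q3_equal(self):
        rng = np.random.default_rng(0)
        g = pd.DataFrame(rng.gamma(2, 50, size=(300, 12)),
                         columns=[f"a{i}" for i in range(12)])
        out = bn.q3_normalize(g)
        q3 = out.values.quantile(0.75, axis=0)
        assert np.ptp(q3.to_numpy()) < 1e-9

    def test_zero_q3_errors_with_aoi_name(self):
        g = pd.DataFrame({"good": [1.0, 2, 3, 4], "bad": [0.0, 0, 0, 0]})
        with pytest.raises(ValueError, match="bad"):
            bn.q3_normalize(g)

    def test_outlier_factor_flagged(self):
        rng = np.random.default_rng(6)
        g = pd.DataFrame(rng.normal(100, 1, size=(20, 8)),
                         columns=[f"a{i}" for i in range(8)])
        g.iloc[:, 0] *= 64
        out = bn.q3_normalize(g)
        assert bool(out.qc_flags["a0"])


# ---------------------------------------------------------------------------
# Morphology DEG and signatures


def _norm_table(values: pd.DataFrame, compartments, morphologies):
    meta = pd.DataFrame({"sample": "s", "compartment": compartments,
                         "morphology": morphologies,
                         "total_reads": 10 ** 6}, index=values.columns)
    return NormalizedAOITable(values=values,
                              q3_factors=pd.Series(1.0, index=values.columns),
                              aoi_meta=meta)


class TestDspDeg:
    def make(self, lfc=0.5):
        rng = np.random.default_rng(0)
        aois = [f"t{i}" for i in range(8)]
        base = rng.uniform(1, 3, size=(50, 1))
        x = np.tile(base, (1, 8)) + rng.normal(0, 0.05, size=(50, 8))
        x[0, 4:] += lfc                     # planted on log2 scale
        values = pd.DataFrame(2 ** x - 1, index=[f"g{i}" for i in range(50)],
                              columns=aois)
        return _norm_table(values, ["tumor"] * 8,
                           ["nodular"] * 4 + ["infiltrative"] * 4)

    def test_effect_detected(self):
        tbl = bn.dsp_deg(self.make(lfc=0.5), "tumor")
        assert bool(tbl.loc["g0", "significant"])
        assert tbl.loc["g0", "log2fc"] == pytest.approx(0.5, abs=0.1)

    def test_exact_threshold_not_significant(self):
        # dyadic values make the group-mean difference exactly representable
        aois = [f"t{i}" for i in range(6)]
        x = np.array([[0.875, 1.0, 1.125, 1.375, 1.5, 1.625]])
        values = pd.DataFrame(2 ** x - 1, index=["g0"], columns=aois)
        norm = _norm_table(values, ["tumor"] * 6,
                           ["nodular"] * 3 + ["infiltrative"] * 3)
        at_cut = bn.dsp_deg(norm, "tumor", log2fc_cut=0.5)
        assert at_cut.loc["g0", "log2fc"] == 0.5
        assert at_cut.loc["g0", "p_value"] < 0.05
        assert not bool(at_cut.loc["g0", "significant"])  # strict >
        below_cut = bn.dsp_deg(norm, "tumor", log2fc_cut=0.4)
        assert bool(below_cut.loc["g0", "significant"])

    def test_antisymmetry_under_label_swap(self):
        norm = self.make()
        swapped = _norm_table(norm.values, ["tumor"] * 8,
                              ["infiltrative"] * 4 + ["nodular"] * 4)
        t1 = bn.dsp_deg(norm, "tumor").sort_index()
        t2 = bn.dsp_deg(swapped, "tumor").sort_index()
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-9)
        np.testing.assert_allclose(t1["p_value"], t2["p_value"], atol=1e-9)

    def test_too_few_aois_errors(self):
        norm = self.make()
        norm.aoi_meta.loc[norm.aoi_meta.index[:3], "morphology"] = "infiltrative"
        with pytest.raises(ValueError, match=">=2 AOIs"):
            bn.dsp_deg(norm, "tumor")

    def test_null_significant_fraction_bounded(self):
        rng = np.random.default_rng(5)
        aois = [f"t{i}" for i in range(48)]
        values = pd.DataFrame(rng.gamma(20, 10, size=(1800, 48)),
                              index=[f"g{i}" for i in range(1800)],
                              columns=aois)
        tbl = bn.dsp_deg(_norm_table(values, ["tumor"] * 48,
                                     ["nodular"] * 24 + ["infiltrative"] * 24),
                         "tumor")
        assert tbl["significant"].mean() <= 0.05


def test_planted_morphology_deg_recovery():
    """Planted 1.0-log2FC morphology programs are recovered with high
    sensitivity and controlled FDR at 12 AOIs per group."""
    cfg = small_sim_config(seed=41, n_aoi_per_group=12, n_program_genes=30,
                           n_genes=800)
    adata, truth = bn.simulate_sc_counts(cfg)
    table, truth = bn.simulate_dsp_probes(cfg, truth)
    table = bn.aoi_qc(table)
    flags, excluded = bn.flag_outlier_probes(table)
    genes = bn.collapse_probes(table, flags, excluded)
    norm = bn.q3_normalize(genes, aoi_meta=table.aoi_meta)
    deg = bn.dsp_deg(norm, "tumor")
    own = truth.program_gene_sets["inf"] + truth.program_gene_sets["nod"]
    sens = deg.loc[own, "significant"].mean()
    assert sens >= 0.9
    program_union = set().union(*(truth.program_gene_sets[k]
                                  for k in ("inf", "nod", "ecm", "quiescent")))
    called = set(deg.index[deg["significant"]])
    fdr = len(called - program_union) / max(len(called), 1)
    assert fdr <= 0.1


class TestRawSignatures:
    def _deg(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "log2fc", "significant"])
        df["p_value"] = 0.001
        return df.set_index("gene")

    def test_empty_tables(self):
        empty = self._deg([])
        sigs = bn.build_raw_signatures(empty, empty)
        assert sigs.as_dict() == {"t_nod": [], "t_inf": [], "s_nod": [],
                                  "s_inf": []}

    def test_sign_partition(self):
        deg_t = self._deg([("a", 1.0, True), ("b", -1.0, True),
                           ("c", 2.0, False)])
        deg_s = self._deg([("d", 0.5, True)])
        sigs = bn.build_raw_signatures(deg_t, deg_s)
        assert sigs.t_inf == ["a"] and sigs.t_nod == ["b"]
        assert sigs.s_inf == ["d"] and sigs.s_nod == []
        assert "c" not in sigs.t_inf

    def test_shared_gene_reported_in_overlap(self):
        deg_t = self._deg([("a", 1.0, True)])
        deg_s = self._deg([("a", 0.8, True)])
        sigs = bn.build_raw_signatures(deg_t, deg_s)
        assert sigs.overlaps["inf_shared"] == ["a"]
        assert "a" in sigs.t_inf and "a" in sigs.s_inf
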
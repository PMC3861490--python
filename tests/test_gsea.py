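"""Per-dataset GSEA: t statistics, set scores, permutation p-values."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crossgsea import (
    GeneSetCollection,
    GseaParams,
    SimulationConfig,
    classify_sets,
    gene_t_statistics,
    generate_collection,
    permutation_test,
    preprocess_dataset,
    set_scores,
    simulate_dataset,
)
from crossgsea.io_formats import ExpressionDataset


def brute_t(case, control):
    """Textbook equal-variance two-sample t, written independently."""
    n1, n2 = len(case), len(control)
    m1, m2 = sum(case) / n1, sum(control) / n2
    ss = sum((x - m1) ** 2 for x in case) + sum((x - m2) ** 2 for x in control)
    sp = math.sqrt(ss / (n1 + n2 - 2))
    return (m1 - m2) / (sp * math.sqrt(1 / n1 + 1 / n2))


class TestGeneT:
    def test_zero_numerator_gives_zero(self, dataset_factory):
        ds = dataset_factory([[5, 7, 5, 7]], ["g1"],
                             ["case", "case", "control", "control"])
        assert gene_t_statistics(ds)["g1"] == pytest.approx(0.0)

    def test_hand_value(self, dataset_factory):
        """case=[2,4], control=[1,3]: diff=1, s_p=sqrt(2), factor 1 -> 1/sqrt(2)."""
        ds = dataset_factory([[2, 4, 1, 3]], ["g1"],
                             ["case", "case", "control", "control"])
        t = gene_t_statistics(ds)["g1"]
        assert t == pytest.approx(1 / math.sqrt(2), abs=1e-12)
        assert t == pytest.approx(brute_t([2, 4], [1, 3]), abs=1e-12)

    def test_constant_equal_groups_gives_zero(self, dataset_factory):
        ds = dataset_factory([[3, 3, 3, 3]], ["g1"],
                             ["case", "case", "control", "control"])
        assert gene_t_statistics(ds)["g1"] == 0.0

    def test_zero_variance_unequal_means_dropped_with_warning(self,
                                                              dataset_factory):
        ds = dataset_factory([[3, 3, 1, 1], [2, 4, 1, 3]], ["g1", "g2"],
                             ["case", "case", "control", "control"])
        with pytest.warns(UserWarning, match="zero pooled SD"):
            t = gene_t_statistics(ds)
        assert list(t.index) == ["g2"]

    def test_matches_brute_force_on_random_data(self, rng, dataset_factory):
        vals = rng.normal(size=(30, 12))
        ds = dataset_factory(vals, [f"g{i}" for i in range(30)],
                             ["case"] * 5 + ["control"] * 7)
        t = gene_t_statistics(ds)
        for i in range(30):
            expected = brute_t(list(vals[i, :5]), list(vals[i, 5:]))
            assert t[f"g{i}"] == pytest.approx(expected, abs=1e-10)


class TestSetScores:
    def test_mean_of_constant_ts(self):
        t = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        coll = GeneSetCollection([("S", "d", list(t.index))])
        sc = set_scores(t, coll, min_set_size=10)["S"]
        assert not sc.excluded and sc.mean_t == pytest.approx(1.0)

    def test_below_min_size_excluded(self):
        t = pd.Series(1.0, index=[f"g{i}" for i in range(9)])
        coll = GeneSetCollection([("S", "d", list(t.index) + ["absent"])])
        sc = set_scores(t, coll, min_set_size=10)["S"]
        assert sc.excluded and sc.n_genes == 9

    def test_balanced_ts_average_to_zero(self):
        t = pd.Series([2.0, -2.0, 1.0, -1.0], index=list("abcd"))
        coll = GeneSetCollection([("S", "d", list("abcd"))])
        assert set_scores(t, coll, 1)["S"].mean_t == pytest.approx(0.0)


def exhaustive_set_pvalues(dataset, collection, min_set_size=1):
    """Independent oracle: enumerate EVERY case-group assignment of the
    observed group sizes and compute the per-set mean-t distribution
    directly with the textbook formula (no shared code path)."""
    samples = list(dataset.values.columns)
    n1 = dataset.n_case
    arr = dataset.values
    genes = list(dataset.probe_ids)
    member_idx = {
        s.name: [g for g in s.members if g in genes] for s in collection
    }
    observed_case = set(dataset.case_samples)

    def mean_ts(case_set):
        case_cols = [s for s in samples if s in case_set]
        ctrl_cols = [s for s in samples if s not in case_set]
        out = {}
        for name, members in member_idx.items():
            if len(members) < min_set_size:
                continue
            ts = []
            for g in members:
                row = arr.loc[g]
                ts.append(brute_t(list(row[case_cols]), list(row[ctrl_cols])))
            out[name] = sum(ts) / len(ts)
        return out

    obs = mean_ts(observed_case)
    combos = [set(c) for c in itertools.combinations(samples, n1)]
    perm_stats = {name: [] for name in obs}
    for c in combos:
        for name, v in mean_ts(c).items():
            perm_stats[name].append(v)
    pvals = {}
    for name, stats_ in perm_stats.items():
        n_ge = sum(1 for v in stats_ if v >= obs[name] - 1e-12)
        n_le = sum(1 for v in stats_ if v <= obs[name] + 1e-12)
        m = len(stats_)
        pvals[name] = (n_ge / m, n_le / m)
    return obs, pvals


def toy_3v3(seed=0, n_genes=8):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    vals = rng.normal(8, 1, size=(n_genes, 6))
    vals[: n_genes // 2, :3] += 1.2  # shift half the genes in cases
    samples = [f"s{i}" for i in range(6)]
    ds = ExpressionDataset(
        dataset_id="toy",
        values=pd.DataFrame(vals, index=pd.Index(genes, name="probe_id"),
                            columns=samples),
        gene_of_probe=pd.Series(genes, index=pd.Index(genes, name="probe_id")),
        group_of_sample=pd.Series(["case"] * 3 + ["control"] * 3,
                                  index=pd.Index(samples)),
    )
    coll = GeneSetCollection(
        [("UP", "d", genes[: n_genes // 2]), ("REST", "d", genes[n_genes // 2:])]
    )
    return ds, coll


class TestPermutationTest:
    def test_sampled_agrees_with_exhaustive_enumeration(self):
        """3v3: all 20 label assignments enumerated independently; sampled
        permutation p-values must agree within 0.02."""
        ds, coll = toy_3v3()
        _, exact = exhaustive_set_pvalues(ds, coll)
        params = GseaParams(n_permutations=10000, alpha=0.05, min_set_size=1,
                            seed=42)
        res = permutation_test(ds, coll, params)
        for name in ("UP", "REST"):
            p_up_exact, p_down_exact = exact[name]
            assert res.table.loc[name, "p_up"] == pytest.approx(
                p_up_exact, abs=0.02
            )
            assert res.table.loc[name, "p_down"] == pytest.approx(
                p_down_exact, abs=0.02
            )

    def test_observed_statistic_is_an_enumerated_value(self):
        ds, coll = toy_3v3(seed=3)
        obs, _ = exhaustive_set_pvalues(ds, coll)
        res = permutation_test(ds, coll, GseaParams(min_set_size=1, seed=1))
        for name, v in obs.items():
            assert res.table.loc[name, "mean_t"] == pytest.approx(v, abs=1e-10)

    def test_label_swap_exchanges_tails_exactly(self):
        ds, coll = toy_3v3(seed=5)
        swapped = ExpressionDataset(
            dataset_id="toy_swapped",
            values=ds.values,
            gene_of_probe=ds.gene_of_probe,
            group_of_sample=ds.group_of_sample.map(
                {"case": "control", "control": "case"}
            ),
        )
        params = GseaParams(n_permutations=500, min_set_size=1, seed=9)
        a = permutation_test(ds, coll, params)
        b = permutation_test(swapped, coll, params)
        assert np.allclose(a.table["p_up"], b.table["p_down"])
        assert np.allclose(a.table["p_down"], b.table["p_up"])
        assert np.allclose(a.table["mean_t"], -b.table["mean_t"])

    def test_pvalues_never_zero_and_tails_overlap(self):
        ds, coll = toy_3v3(seed=8)
        res = permutation_test(ds, coll, GseaParams(min_set_size=1, seed=2))
        t = res.table.dropna(subset=["p_up"])
        assert (t["p_up"] > 0).all() and (t["p_down"] > 0).all()
        assert (t["p_up"] + t["p_down"] >= 1).all()

    def test_seed_reproducibility(self):
        ds, coll = toy_3v3(seed=6)
        params = GseaParams(n_permutations=300, min_set_size=1, seed=17)
        a = permutation_test(ds, coll, params)
        b = permutation_test(ds, coll, params)
        assert a.table.equals(b.table)

    def test_small_set_excluded(self):
        ds, coll = toy_3v3()
        res = permutation_test(ds, coll, GseaParams(min_set_size=10, seed=1))
        assert (res.table["call"] == "excluded").all()

    def test_planted_direction_recovered(self):
        """delta=1.5, sigma=0.5, 10v10, full coverage: planted sets must be
        called in the right direction."""
        cfg = SimulationConfig(
            n_genes=150, n_sets=6, set_size_range=(12, 15), n_datasets=1,
            cases_per_dataset=(10,), controls_per_dataset=(10,),
            gene_coverage=1.0, probes_per_gene_max=1,
            planted_up=("SET001",), planted_down=("SET002",), seed=4,
        )
        coll = generate_collection(cfg)
        ds = preprocess_dataset(simulate_dataset(cfg, coll, 0), coll)
        res = permutation_test(ds, coll, GseaParams(seed=12))
        assert res.table.loc["SET001", "call"] == "up"
        assert res.table.loc["SET002", "call"] == "down"


class TestClassify:
    def _result(self, rows):
        table = pd.DataFrame(
            rows, columns=["set", "n_genes", "mean_t", "p_up", "p_down", "call"]
        ).set_index("set")
        from crossgsea.gsea import DatasetGseaResult

        return DatasetGseaResult("D", table, 1000, 0.05, 10)

    def test_alpha_boundary_is_inclusive(self):
        res = self._result([("S", 12, 2.0, 0.05, 0.999, "up")])
        up, down, ns, excluded = classify_sets(res)
        assert up == ["S"]

    def test_all_pup_one_gives_empty_up_list(self):
        res = self._result([("S", 12, -2.0, 1.0, 0.01, "down")])
        up, down, ns, excluded = classify_sets(res)
        assert up == [] and down == ["S"]

    def test_excluded_never_in_other_lists(self):
        res = self._result([("S", 3, np.nan, np.nan, np.nan, "excluded")])
        up, down, ns, excluded = classify_sets(res)
        assert excluded == ["S"] and not (up or down or ns)

    def test_sorted_by_p_then_name(self):
        res = self._result(
            [
                ("B", 12, 2.0, 0.01, 0.999, "up"),
                ("A", 12, 2.0, 0.01, 0.999, "up"),
                ("C", 12, 3.0, 0.001, 1.0, "up"),
            ]
        )
        up, *_ = classify_sets(res)
        assert up == ["C", "A", "B"]
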
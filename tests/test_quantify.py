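import numpy as np
import pandas as pd
import pytest

from myoarray import (
    CtTable,
    ValidationError,
    delta_delta_ct,
    generate_ct_table,
    group_fold_report,
    normalize_bands,
)


def ct_table(rows, groups, reference_group="ctrl"):
    data = pd.DataFrame(rows, columns=["sample", "gene", "ct"])
    return CtTable(data=data, groups=groups, reference_gene="18S",
                   reference_group=reference_group)


def triplicate(sample, gene, ct):
    return [(sample, gene, ct)] * 3


class TestDeltaDeltaCt:
    def test_one_cycle_advantage_doubles_fold(self):
        rows = (triplicate("c1", "TG", 25.0) + triplicate("c1", "18S", 12.0)
                + triplicate("t1", "TG", 24.0) + triplicate("t1", "18S", 12.0))
        res = delta_delta_ct(
            ct_table(rows, {"c1": "ctrl", "t1": "drug"}), "TG")
        assert res.per_sample.at["t1", "fold"] == pytest.approx(2.0)
        assert res.per_sample.at["c1", "fold"] == pytest.approx(1.0)

    def test_sample_at_reference_mean_fold_one(self):
        rows = (triplicate("c1", "TG", 25.0) + triplicate("c1", "18S", 12.0)
                + triplicate("c2", "TG", 25.0) + triplicate("c2", "18S", 12.0))
        res = delta_delta_ct(ct_table(rows, {"c1": "ctrl", "c2": "ctrl"}), "TG")
        np.testing.assert_allclose(res.per_sample["fold"], 1.0)

    def test_reference_group_geometric_mean_fold_is_one(self):
        rows = []
        groups = {}
        for i, ct in enumerate([24.2, 25.1, 25.9]):
            rows += triplicate(f"c{i}", "TG", ct) + triplicate(f"c{i}", "18S", 12.0)
            groups[f"c{i}"] = "ctrl"
        res = delta_delta_ct(ct_table(rows, groups), "TG")
        folds = res.per_sample["fold"].to_numpy()
        assert np.exp(np.mean(np.log(folds))) == pytest.approx(1.0, rel=1e-12)

    def test_global_ct_shift_invariance(self):
        def build(shift):
            rows = (triplicate("c1", "TG", 25.0 + shift)
                    + triplicate("c1", "18S", 12.0 + shift)
                    + triplicate("t1", "TG", 23.5 + shift)
                    + triplicate("t1", "18S", 12.0 + shift))
            return delta_delta_ct(
                ct_table(rows, {"c1": "ctrl", "t1": "drug"}), "TG")
        np.testing.assert_allclose(build(0.0).per_sample["fold"],
                                   build(3.0).per_sample["fold"])

    def test_triplicates_averaged_on_ct_scale(self):
        rows = ([("c1", "TG", 24.0), ("c1", "TG", 25.0), ("c1", "TG", 26.0)]
                + triplicate("c1", "18S", 12.0)
                + triplicate("t1", "TG", 24.0) + triplicate("t1", "18S", 12.0))
        res = delta_delta_ct(ct_table(rows, {"c1": "ctrl", "t1": "drug"}), "TG")
        # mean Ct(c1, TG) = 25 -> t1 is one cycle lower -> fold 2
        assert res.per_sample.at["t1", "fold"] == pytest.approx(2.0)

    def test_missing_reference_wells_names_sample(self):
        rows = (triplicate("c1", "TG", 25.0) + triplicate("c1", "18S", 12.0)
                + triplicate("t1", "TG", 24.0))
        with pytest.raises(ValidationError, match="t1"):
            delta_delta_ct(ct_table(rows, {"c1": "ctrl", "t1": "drug"}), "TG")

    def test_order_safe_exponentiation(self):
        """For noise-free triplicates, exponentiating the mean ΔΔCt equals the
        geometric mean of per-replicate folds."""
        cts = {"c1": 25.0, "t1": 23.2}
        rows = []
        for s, ct in cts.items():
            rows += triplicate(s, "TG", ct) + triplicate(s, "18S", 12.0)
        res = delta_delta_ct(ct_table(rows, {"c1": "ctrl", "t1": "drug"}), "TG")
        per_rep = [2.0 ** -((cts["t1"] - 12.0) - (cts["c1"] - 12.0))] * 3
        geo = np.exp(np.mean(np.log(per_rep)))
        assert res.per_sample.at["t1", "fold"] == pytest.approx(geo, rel=1e-12)


class TestGenerateRoundTrip:
    def test_noise_free_recovery_exact(self):
        folds = {"veh7": 1.0, "nan7": 1.3, "veh35": 0.6, "nan35": 2.0}
        table = generate_ct_table(folds, n_per_group=4, ct_noise_sd=0.0,
                                  seed=5, gene="RCAN2", reference_group="veh7")
        res = delta_delta_ct(table, "RCAN2")
        for sample, row in res.per_sample.iterrows():
            assert row["fold"] == pytest.approx(folds[row["group"]], rel=1e-12)

    def test_noisy_recovery_near_truth(self):
        table = generate_ct_table({"ctrl": 1.0, "drug": 2.0}, n_per_group=8,
                                  ct_noise_sd=0.2, seed=11,
                                  reference_group="ctrl")
        res = delta_delta_ct(table, "GENE")
        est = res.group_summary.at["drug", "mean"]
        assert 1.6 < est < 2.4

    def test_same_seed_identical(self):
        t1 = generate_ct_table({"ctrl": 1.0, "drug": 2.0}, seed=3)
        t2 = generate_ct_table({"ctrl": 1.0, "drug": 2.0}, seed=3)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValidationError):
            generate_ct_table({"ctrl": 1.0, "drug": 0.0})


class TestBands:
    def test_ratio_and_scale_invariance(self):
        records = pd.DataFrame({"target": [500.0, 300.0],
                                "reference": [250.0, 300.0]})
        out = normalize_bands(records)
        np.testing.assert_allclose(out["ratio"], [2.0, 1.0])
        doubled = normalize_bands(records * 2.0)
        np.testing.assert_allclose(doubled["ratio"], out["ratio"])

    def test_batch_matches_elementwise_division(self, rng):
        records = pd.DataFrame({"target": rng.uniform(100, 900, 8),
                                "reference": rng.uniform(100, 900, 8)})
        out = normalize_bands(records)
        expected = [t / r for t, r in zip(records["target"],
                                          records["reference"])]
        np.testing.assert_allclose(out["ratio"], expected)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValidationError):
            normalize_bands(pd.DataFrame({"target": [1.0], "reference": [0.0]}))


class TestGroupFoldReport:
    def test_mean_and_sem_hand_computed(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 4.0, 4.0])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3)
        report = group_fold_report(values, groups)
        assert report["summary"].at["g1", "mean"] == pytest.approx(2.0)
        assert report["summary"].at["g1", "sem"] == pytest.approx(0.5773502692)

    def test_identical_groups_p_one_no_flags(self):
        values = pd.Series([1.0, 2.0, 3.0] * 2)
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        report = group_fold_report(values, groups)
        assert report["anova"].p_value == pytest.approx(1.0)
        assert report["posthoc"].significant_pairs() == []

    def test_shifted_group_flagged(self, rng):
        """One of four groups at 2-fold, n=8, CV 10% -> flagged vs the rest."""
        folds, labels = [], []
        for g, level in zip("abcd", (1.0, 1.0, 1.0, 2.0)):
            folds += list(level * rng.lognormal(0, 0.1, 8))
            labels += [g] * 8
        report = group_fold_report(pd.Series(folds), pd.Series(labels))
        order = report["group_order"]
        shifted = order.index("d")
        sig = report["posthoc"].significant_pairs()
        flagged_vs = {i if j == shifted else j
                      for i, j in sig if shifted in (i, j)}
        assert flagged_vs == {order.index(g) for g in "abc"}
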
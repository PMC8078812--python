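"""BH adjustment, Kruskal-Wallis/Dunn, percent change, two-step procedure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from weanotype import association
from weanotype.association import bh_adjust, kruskal_dunn, percent_change, two_step_radg
from weanotype.tables import RelAbundanceTable, SampleMetadata
from tests.conftest import make_metadata


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])
        out2 = bh_adjust([0.005, 0.04, 0.03])
        # ranks: 0.005*3/1=0.015; 0.03*3/2=0.045; 0.04*3/3=0.04 -> monotone 0.04
        assert np.allclose(out2, [0.015, 0.04, 0.04])

    def test_single_p_unchanged_and_cap(self):
        assert bh_adjust([0.7])[0] == 0.7
        assert bh_adjust([0.9, 0.95])[1] <= 1.0

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=30))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _rel_table(values, index):
    df = pd.DataFrame(values, index=index)
    df.columns = [f"t{j}" for j in range(df.shape[1])]
    return RelAbundanceTable(df.div(df.sum(axis=1), axis=0))


class TestKruskalDunn:
    def test_two_groups_equal_rank_sum_test(self):
        rng = np.random.default_rng(2)
        vals = rng.dirichlet(np.ones(3), size=30)
        rel = _rel_table(vals, [f"s{i}" for i in range(30)])
        factor = pd.Series(["a"] * 15 + ["b"] * 15, index=rel.data.index)
        res = kruskal_dunn(rel, factor)
        for taxon in rel.data.columns:
            a = rel.data.loc[factor == "a", taxon]
            b = rel.data.loc[factor == "b", taxon]
            kw_p = res.table.loc[taxon, "p"]
            mw = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    use_continuity=False, method="asymptotic")
            assert kw_p == pytest.approx(mw.pvalue, abs=1e-6)

    def test_shifted_taxon_detected(self):
        rng = np.random.default_rng(3)
        base = rng.dirichlet(np.full(4, 20.0), size=40)
        base[:20, 0] += 5 * base[:, 0].std()
        rel = _rel_table(base, [f"s{i}" for i in range(40)])
        factor = pd.Series(["hi"] * 20 + ["lo"] * 20, index=rel.data.index)
        res = kruskal_dunn(rel, factor)
        assert res.table.loc["t0", "p"] < 0.001

    def test_dunn_conclusions_invariant_to_relabeling(self):
        rng = np.random.default_rng(4)
        vals = rng.dirichlet(np.ones(2), size=30)
        vals[:10, 0] *= 4
        rel = _rel_table(vals, [f"s{i}" for i in range(30)])
        f1 = pd.Series(["x"] * 10 + ["y"] * 10 + ["z"] * 10, index=rel.data.index)
        f2 = f1.map({"x": "g3", "y": "g1", "z": "g2"})
        r1, r2 = kruskal_dunn(rel, f1), kruskal_dunn(rel, f2)
        for taxon in r1.dunn:
            d1 = r1.dunn[taxon].copy()
            d2 = r2.dunn[taxon].copy()
            m = {"x": "g3", "y": "g1", "z": "g2"}
            d1["pair"] = [frozenset((m[a], m[b])) for a, b in zip(d1.level_a, d1.level_b)]
            d2["pair"] = [frozenset((a, b)) for a, b in zip(d2.level_a, d2.level_b)]
            merged = d1.set_index("pair")[["p"]].join(
                d2.set_index("pair")[["p"]], rsuffix="_2")
            assert np.allclose(merged["p"], merged["p_2"])

    def test_small_level_dropped(self):
        rng = np.random.default_rng(5)
        rel = _rel_table(rng.dirichlet(np.ones(2), size=5), [f"s{i}" for i in range(5)])
        factor = pd.Series(["a", "a", "b", "b", "lone"], index=rel.data.index)
        res = kruskal_dunn(rel, factor)  # 'lone' dropped with warning
        assert res.table["p"].notna().all()


class TestPercentChange:
    def _paired(self, rng, n_pigs, d35_scale):
        meta = make_metadata(n_pigs=n_pigs, n_farms=2)
        rows = {}
        for s in meta.data.index:
            base = rng.dirichlet(np.full(4, 50.0))
            if meta.data.loc[s, "age_point"] == "d35":
                base = base * d35_scale
            rows[s] = base / base.sum()
        rel = RelAbundanceTable(pd.DataFrame.from_dict(rows, orient="index"))
        rel.data.columns = [f"t{j}" for j in range(4)]
        return rel, meta

    def test_direction_follows_construction(self):
        rng = np.random.default_rng(6)
        rel, meta = self._paired(rng, 40, np.array([2.0, 1.0, 1.0, 1.0]))
        out = percent_change(rel, meta)
        assert out.loc["t0", "percent_change"] > 0
        assert out.loc["t0", "p_adj"] < 0.05
        assert (out.loc[["t1", "t2", "t3"], "percent_change"] < 0).all()

    def test_null_change_small(self):
        rng = np.random.default_rng(7)
        rel, meta = self._paired(rng, 200, np.ones(4))
        out = percent_change(rel, meta)
        assert out["percent_change"].abs().max() < 5.0

    def test_zero_baseline_flagged(self):
        meta = make_metadata(n_pigs=3)
        data = pd.DataFrame(0.0, index=meta.data.index, columns=["a", "b"])
        data["a"] = 1.0
        d35 = meta.data["age_point"] == "d35"
        data.loc[d35, "b"] = 0.5
        data.loc[d35, "a"] = 0.5
        out = percent_change(RelAbundanceTable(data), meta)
        assert out.loc["b", "undefined_baseline"]
        assert np.isnan(out.loc["b", "percent_change"])


def _two_step_inputs(rng, n_pigs=60, interaction=0.0):
    """Paired cohort where taxon t0 rises more after weaning in rADG+ pigs
    when ``interaction`` > 0."""
    meta = make_metadata(n_pigs=n_pigs, n_farms=4)
    pig_ids = sorted(meta.data["pig_id"].unique())
    # farms cycle with i % 4, so alternate classes in blocks of 4 to keep
    # both classes present within every farm
    cls = {p: ("rADG+" if (i // 4) % 2 == 0 else "rADG-")
           for i, p in enumerate(pig_ids)}
    rows = {}
    for s in meta.data.index:
        pig = meta.data.loc[s, "pig_id"]
        is_d35 = meta.data.loc[s, "age_point"] == "d35"
        alpha = np.full(4, 30.0)
        if is_d35 and cls[pig] == "rADG+":
            alpha[0] *= 1.0 + interaction
        base = rng.dirichlet(alpha)
        rows[s] = base
    rel = RelAbundanceTable(pd.DataFrame.from_dict(rows, orient="index"))
    rel.data.columns = [f"t{j}" for j in range(4)]
    records = pd.DataFrame({
        "farm_id": meta.data.drop_duplicates("pig_id").set_index("pig_id")["farm_id"],
        "radg": 40.0,
        "growth_class": pd.Series(cls),
    }).rename_axis("pig_id")
    return rel, records, meta


class TestTwoStep:
    def test_constructed_interaction_detected(self):
        rng = np.random.default_rng(8)
        rel, records, meta = _two_step_inputs(rng, n_pigs=80, interaction=1.0)
        res = two_step_radg(rel, records, meta, n_perm=199, seed=0, adjust_step1=False)
        assert res.step1.loc["t0", "retained"]
        assert res.step2.loc["t0", "p_interaction"] < 0.05

    def test_age_effect_ss_invariant_under_class_permutation(self):
        """With both ages present for every pig the centered age contrast is
        orthogonal to any pig-level class assignment, so the age effect sum
        of squares cannot depend on how classes are shuffled."""
        rng = np.random.default_rng(9)
        rel, records, meta = _two_step_inputs(rng, n_pigs=20, interaction=0.0)
        pigs = sorted(records.index)
        y = rel.data.loc[
            [f"{p}.d26" for p in pigs] + [f"{p}.d35" for p in pigs], "t0"
        ].to_numpy()
        age_c = np.r_[np.zeros(len(pigs)), np.ones(len(pigs))] - 0.5
        ss_age = (age_c @ y) ** 2 / (age_c @ age_c)
        cls = (records.loc[pigs, "growth_class"] == "rADG+").to_numpy().astype(float)
        for _ in range(10):
            perm = rng.permutation(cls)
            cls_c = np.r_[perm, perm] - perm.mean()
            # orthogonality of the balanced design
            assert cls_c @ age_c == pytest.approx(0.0, abs=1e-9)
            assert (cls_c * age_c) @ age_c == pytest.approx(0.0, abs=1e-9)
        assert ss_age > 0  # the contrast itself is well-defined

    def test_permutation_p_within_bounds(self):
        rng = np.random.default_rng(10)
        rel, records, meta = _two_step_inputs(rng, n_pigs=40, interaction=0.5)
        res = two_step_radg(rel, records, meta, n_perm=99, seed=1, adjust_step1=False)
        lo = 1 / 100
        for col in ("p_class", "p_age", "p_interaction"):
            if len(res.step2):
                assert ((res.step2[col] >= lo) & (res.step2[col] <= 1)).all()

    def test_too_few_complete_pigs_rejected(self):
        rng = np.random.default_rng(11)
        rel, records, meta = _two_step_inputs(rng, n_pigs=4)
        records["growth_class"] = ["rADG+", "rADG-", "excluded", "excluded"]
        with pytest.raises(ValueError, match="complete pigs"):
            two_step_radg(rel, records, meta, n_perm=19, seed=0)
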
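import numpy as np
import pandas as pd
import pytest

from replibio import differential
from replibio.differential import IqrThresholds

from conftest import biorep_design, build_matrix


class TestIqrThresholds:
    def test_hand_computed_tukey_fences(self):
        thr = differential.iqr_thresholds([1.0, 2.0, 3.0, 4.0])
        assert thr.q1 == pytest.approx(1.75)
        assert thr.q3 == pytest.approx(3.25)
        assert thr.iqr == pytest.approx(1.5)
        assert thr.lower == pytest.approx(-0.5)
        assert thr.upper == pytest.approx(5.5)

    def test_requires_four_finite_deltas(self):
        with pytest.raises(ValueError, match="at least 4"):
            differential.iqr_thresholds([1.0, 2.0, np.nan, np.nan, 3.0])

    def test_constant_distribution_degenerates(self):
        thr = differential.iqr_thresholds([2.0] * 6)
        assert thr.iqr == 0.0 and thr.lower == thr.upper == 2.0

    def test_translation_equivariant(self):
        rng = np.random.default_rng(5)
        deltas = rng.normal(size=30)
        thr = differential.iqr_thresholds(deltas)
        shifted = differential.iqr_thresholds(deltas + 3.7)
        assert shifted.lower == pytest.approx(thr.lower + 3.7, abs=1e-12)
        assert shifted.upper == pytest.approx(thr.upper + 3.7, abs=1e-12)


class TestEnrichmentRatios:
    def make_matrices(self, bait_nt, bait_hu, baseline):
        """Single prey per value; log2 matrices with constant replicates."""
        n = len(bait_nt)
        d_nt = biorep_design("B1", "NT") + biorep_design("control_gfp_nls", "NT") \
            + biorep_design("control_parental", "NT") + biorep_design("control_gfp", "NT")
        d_hu = biorep_design("B1", "HU") + biorep_design("control_gfp_nls", "HU")
        cols_nt = {d.sample_id: [np.log2(bait_nt[i]) if d.label == "B1" else np.log2(baseline[i]) for i in range(n)] for d in d_nt}
        cols_hu = {d.sample_id: [np.log2(bait_hu[i]) if d.label == "B1" else np.log2(baseline[i]) for i in range(n)] for d in d_hu}
        q_nt = build_matrix({k: [1.0] * n for k in cols_nt}, intensity=cols_nt, log_transformed=True)
        q_hu = build_matrix({k: [1.0] * n for k in cols_hu}, intensity=cols_hu, log_transformed=True)
        return q_nt, q_hu, d_nt + d_hu

    def test_ratio_arithmetic_and_inclusive_gate(self):
        q_nt, q_hu, design = self.make_matrices(
            bait_nt=[4.0, 16.0, 8.0], bait_hu=[4.0, 16.0, 8.0], baseline=[4.0, 4.0, 4.0]
        )
        records = differential.enrichment_ratios(q_nt, q_hu, design)
        r = records.set_index("prey")
        assert r.loc["P1", "ratio_nt"] == pytest.approx(0.0)  # bait mean == baseline
        assert not r.loc["P1", "enriched_nt"]
        assert r.loc["P2", "ratio_nt"] == pytest.approx(2.0)  # 4x baseline
        assert r.loc["P3", "ratio_nt"] == pytest.approx(1.0)
        assert bool(r.loc["P3", "enriched_nt"])  # log2 ratio exactly 1 is enriched
        assert np.allclose(records["delta"], records["ratio_hu"] - records["ratio_nt"])

    def test_nonpositive_baseline_rejected(self):
        q_nt, q_hu, design = self.make_matrices([4.0], [4.0], [4.0])
        q_nt.intensity.loc["P1", "control_gfp_nls.NT.b1"] = np.nan
        q_nt.intensity.loc["P1", "control_gfp_nls.NT.b2"] = np.nan
        q_nt.intensity.loc["P1", "control_gfp_nls.NT.b3"] = np.nan
        with pytest.raises(ValueError, match="baseline"):
            differential.enrichment_ratios(q_nt, q_hu, design)


def classify_oracle(rec, thr, interactors):
    """Independent straight-line restatement of the decision rule."""
    if rec.prey not in interactors:
        return "not_interactor"
    if rec.delta > thr.upper and rec.enriched_hu:
        return "gained"
    if rec.delta < thr.lower and rec.enriched_nt:
        return "depleted"
    return "unchanged"


class TestClassify:
    def random_records(self, n=1000, seed=11):
        rng = np.random.default_rng(seed)
        preys = [f"P{i}" for i in range(n)]
        ratio_nt = rng.normal(0, 2, n)
        ratio_hu = rng.normal(0, 2, n)
        return pd.DataFrame(
            {
                "bait": "B1",
                "prey": preys,
                "ratio_nt": ratio_nt,
                "ratio_hu": ratio_hu,
                "delta": ratio_hu - ratio_nt,
                "enriched_nt": ratio_nt >= 1.0,
                "enriched_hu": ratio_hu >= 1.0,
            }
        )

    def test_rule_examples(self):
        thr = IqrThresholds("B1", q1=-0.5, q3=0.5, iqr=1.0, lower=-2.0, upper=2.0)
        records = pd.DataFrame(
            {
                "bait": ["B1"] * 3,
                "prey": ["gain", "outlier_nonint", "flat"],
                "ratio_nt": [0.5, 0.0, 1.5],
                "ratio_hu": [3.5, 3.0, 1.6],
                "delta": [3.0, 3.0, 0.1],
                "enriched_nt": [False, False, True],
                "enriched_hu": [True, True, True],
            }
        )
        out = differential.classify(records, thr, {"gain", "flat"}, {"gain", "flat"})
        status = out.set_index("prey")["status"]
        assert status["gain"] == "gained"
        assert status["outlier_nonint"] == "not_interactor"  # outlier but never an interactor
        assert status["flat"] == "unchanged"

    def test_agrees_with_bruteforce_oracle(self):
        records = self.random_records()
        rng = np.random.default_rng(12)
        interactors = set(rng.choice(records["prey"], size=400, replace=False))
        thr = differential.iqr_thresholds(records["delta"], bait="B1")
        out = differential.classify(records, thr, interactors, set())
        for rec in out.itertuples(index=False):
            assert rec.status == classify_oracle(rec, thr, interactors)

    def test_statuses_exclusive_and_exhaustive(self):
        records = self.random_records(seed=13)
        thr = differential.iqr_thresholds(records["delta"], bait="B1")
        out = differential.classify(records, thr, set(records["prey"][:500]), set(records["prey"][250:700]))
        assert out["status"].isin(differential.STATUSES).all()
        gained = set(out.loc[out["status"] == "gained", "prey"])
        depleted = set(out.loc[out["status"] == "depleted", "prey"])
        assert gained.isdisjoint(depleted)


class TestSummarize:
    def records(self, statuses):
        return pd.DataFrame(
            [
                {"bait": b, "prey": p, "ratio_nt": 0.0, "ratio_hu": 0.0, "delta": 0.0,
                 "enriched_nt": True, "enriched_hu": True, "status": s}
                for b, p, s in statuses
            ]
        )

    def test_disjoint_gained_sets_intersect_empty(self):
        records = self.records(
            [("B1", "X1", "gained"), ("B1", "X2", "gained"), ("B2", "Y1", "gained")]
        )
        table, venn = differential.summarize_by_group(records, {"B1": "CMG", "B2": "RPA"})
        assert venn[frozenset({"CMG", "RPA"})] == 0
        assert venn[frozenset({"CMG"})] == 2 and venn[frozenset({"RPA"})] == 1

    def test_venn_counts_sum_to_union(self):
        rng = np.random.default_rng(21)
        rows = []
        for bait, group in (("B1", "CMG"), ("B2", "POL"), ("B3", "RPA")):
            for p in rng.choice(50, size=20, replace=False):
                rows.append((bait, f"P{p}", "gained" if p % 2 else "depleted"))
        records = self.records(rows)
        _, venn = differential.summarize_by_group(records, {"B1": "CMG", "B2": "POL", "B3": "RPA"})
        union = {r[1] for r in rows}
        assert sum(venn.values()) == len(union)

    def test_unassigned_bait_rejected(self):
        records = self.records([("B1", "X1", "gained")])
        with pytest.raises(ValueError, match="without functional group"):
            differential.summarize_by_group(records, {})
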
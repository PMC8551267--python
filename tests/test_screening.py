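"""Library screening, validation accounting, permutations and drug pairs."""

import numpy as np
import pandas as pd
import pytest

import pathcalib as pc
from pathcalib.drug_simulation import Weights
from pathcalib.screening import (ScreenResult, combine, permutation_robustness,
                                 screen, validate, weight_sweep)


def _null_drug_library(targets: pc.DrugTargetSet) -> pc.DrugTargetSet:
    rec = pd.DataFrame([("NULLDRUG", "NOT_A_PATHWAY_GENE", 1)],
                       columns=["drug_id", "target", "effect"])
    return pc.DrugTargetSet(records=pd.concat([targets.records, rec],
                                              ignore_index=True))


class TestScreen:
    def test_null_drug_changes_nothing(self, pipeline):
        lib = _null_drug_library(pipeline.targets)
        res = screen(pipeline.model, pipeline.pas, lib, pipeline.sets,
                     pipeline.profile, drug_ids=["NULLDRUG"])
        assert res.proportion_of("NULLDRUG") == 0.0

    def test_count_conservation_and_ranking(self, pipeline):
        res = screen(pipeline.model, pipeline.pas, pipeline.targets,
                     pipeline.sets, pipeline.profile)
        t = res.table
        assert (t["responder_count"] <= t["eligible_count"]).all()
        props = t["responder_proportion"].to_numpy()
        assert (np.diff(props) <= 0).all()
        assert (t["prioritized"] == (props >= res.threshold)).all()

    def test_screen_is_deterministic(self, pipeline):
        args = (pipeline.model, pipeline.pas, pipeline.targets, pipeline.sets,
                pipeline.profile)
        pd.testing.assert_frame_equal(screen(*args).table, screen(*args).table)

    def test_threshold_monotonicity(self, pipeline):
        args = (pipeline.model, pipeline.pas, pipeline.targets, pipeline.sets,
                pipeline.profile)
        lo = screen(*args, threshold=0.5).prioritized
        hi = screen(*args, threshold=0.9).prioritized
        assert hi <= lo

    def test_threshold_is_inclusive_at_the_boundary(self):
        """A drug flipping 79% of patients is not prioritized at 0.8; one
        flipping exactly 80% is."""
        table = pd.DataFrame(
            [("D79", 79, 100, 0.79), ("D80", 80, 100, 0.80)],
            columns=["drug_id", "responder_count", "eligible_count",
                     "responder_proportion"])
        res = ScreenResult(table=table.assign(
            prioritized=table["responder_proportion"] >= 0.8),
            threshold=0.8, weights=Weights(), eligible_samples=[])
        assert res.prioritized == {"D80"}

    def test_invalid_threshold_rejected(self, pipeline):
        with pytest.raises(ValueError):
            screen(pipeline.model, pipeline.pas, pipeline.targets,
                   pipeline.sets, pipeline.profile, threshold=0.0)


def _result_from_counts(n_library: int, prioritized: list[str],
                        all_ids: list[str]) -> ScreenResult:
    pri = set(prioritized)
    rows = [(d, 80 if d in pri else 0, 100, 0.8 if d in pri else 0.0)
            for d in all_ids]
    table = pd.DataFrame(rows, columns=["drug_id", "responder_count",
                                        "eligible_count",
                                        "responder_proportion"])
    table["prioritized"] = table["responder_proportion"] >= 0.8
    return ScreenResult(table=table, threshold=0.8, weights=Weights(),
                        eligible_samples=[])


class TestValidate:
    def test_true_positive_proportion_arithmetic(self):
        """31 true positives among 129 prioritized out of a 1346-drug
        library -> 24.03%."""
        ids = [f"D{i:04d}" for i in range(1346)]
        prioritized = ids[:129]
        positives = ids[:31] + ids[500:520]          # 31 hits, 20 misses
        truth = pc.GroundTruth(indications={"x": {
            "approved": frozenset(positives[:26]),
            "clinical_trials": frozenset(positives[26:])}})
        rep = validate(_result_from_counts(1346, prioritized, ids), truth, "x")
        assert rep.n_prioritized == 129
        assert rep.n_true_positives == 31
        assert rep.proportion_true_positives == pytest.approx(100 * 31 / 129)
        assert rep.enrichment_p < 1e-6

    def test_empty_prioritized_set_flags_undefined_proportion(self):
        ids = ["D1", "D2"]
        truth = pc.GroundTruth(indications={"x": {
            "approved": frozenset(["D1"]), "clinical_trials": frozenset()}})
        rep = validate(_result_from_counts(2, [], ids), truth, "x")
        assert rep.proportion_true_positives is None
        assert rep.enrichment_p is None

    def test_all_true_positives_give_100_percent_and_small_p(self):
        ids = [f"D{i}" for i in range(50)]
        truth = pc.GroundTruth(indications={"x": {
            "approved": frozenset(ids[:5]), "clinical_trials": frozenset()}})
        rep = validate(_result_from_counts(50, ids[:5], ids), truth, "x")
        assert rep.proportion_true_positives == 100.0
        assert rep.enrichment_p <= (5 / 50) ** 5   # naive binomial bound

    def test_drug_in_both_lists_counted_once(self):
        ids = [f"D{i}" for i in range(10)]
        truth = pc.GroundTruth(indications={"x": {
            "approved": frozenset(["D0"]), "clinical_trials": frozenset(["D0"])}})
        rep = validate(_result_from_counts(10, ["D0", "D1"], ids), truth, "x")
        assert rep.n_true_positives == 1
        assert rep.proportion_true_positives == pytest.approx(50.0)


class TestPermutation:
    def test_fixed_seed_reproduces_replicates(self, pipeline):
        kwargs = dict(model=pipeline.model, pas=pipeline.pas,
                      targets=pipeline.targets, sets=pipeline.sets,
                      profile=pipeline.profile, n_reps=5, seed=21,
                      gene_universe=pipeline.expr.gene_ids)
        a = permutation_robustness(**kwargs)
        b = permutation_robustness(**kwargs)
        assert a == b

    def test_replicate_count_and_p_value_accounting(self, pipeline):
        summ = permutation_robustness(
            pipeline.model, pipeline.pas, pipeline.targets, pipeline.sets,
            pipeline.profile, n_reps=10, seed=3,
            gene_universe=pipeline.expr.gene_ids)
        counts = np.asarray(summ["replicate_prioritized"])
        assert len(counts) == 10
        assert summ["empirical_p"] == pytest.approx(
            (counts >= summ["observed_prioritized"]).mean())
        assert summ["n_strictly_fewer"] == int(
            (counts < summ["observed_prioritized"]).sum())

    def test_tiny_gene_universe_rejected(self, pipeline):
        with pytest.raises(ValueError):
            permutation_robustness(pipeline.model, pipeline.pas,
                                   pipeline.targets, pipeline.sets,
                                   pipeline.profile, n_reps=1,
                                   gene_universe=["G00001"])


class TestWeightSweep:
    def test_one_row_per_weight_triple(self, pipeline):
        grid = [(10.0, 5.0, 10.0), (15.0, 5.0, 10.0), (20.0, 5.0, 10.0)]
        table = weight_sweep(pipeline.model, pipeline.pas, pipeline.targets,
                             pipeline.sets, pipeline.profile, grid, 0.8,
                             pipeline.truth, "synthetic")
        assert list(table["w1"]) == [10.0, 15.0, 20.0]
        assert len(table) == 3

    def test_empty_grid_rejected(self, pipeline):
        with pytest.raises(ValueError):
            weight_sweep(pipeline.model, pipeline.pas, pipeline.targets,
                         pipeline.sets, pipeline.profile, [], 0.8,
                         pipeline.truth, "synthetic")


class TestCombine:
    def _kwargs(self, pipeline):
        return dict(model=pipeline.model, pas=pipeline.pas,
                    targets=pipeline.targets, sets=pipeline.sets,
                    profile=pipeline.profile)

    def test_pair_is_symmetric(self, pipeline):
        a = combine("ORACLE00", "DECOY000", **self._kwargs(pipeline))
        b = combine("DECOY000", "ORACLE00", **self._kwargs(pipeline))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_self_pair_equals_single_drug_screen(self, pipeline):
        single = screen(pipeline.model, pipeline.pas, pipeline.targets,
                        pipeline.sets, pipeline.profile,
                        drug_ids=["ORACLE00"]).proportion_of("ORACLE00")
        pair = combine("ORACLE00", "ORACLE00", **self._kwargs(pipeline))
        assert pair.table["responder_proportion"].iloc[0] == single

    def test_complementary_half_oracles_beat_either_single(self, pipeline):
        """Two drugs each reactivating a disjoint half of the planted
        pathways: the pair outperforms both singles. Run at a calibration
        weight low enough that a partial correction cannot flip predictions
        on its own (at strong weights even one corrected pathway saturates
        the responder proportion and synergy is invisible)."""
        sc = pipeline.scenario
        dys = sc.dysregulated_pathway_ids
        rows = []
        for pid in dys[:2]:
            rows.append(("HALF_A", sorted(pipeline.sets[pid])[0], 1))
        for pid in dys[2:]:
            rows.append(("HALF_B", sorted(pipeline.sets[pid])[0], 1))
        lib = pc.DrugTargetSet(records=pd.concat(
            [pipeline.targets.records,
             pd.DataFrame(rows, columns=["drug_id", "target", "effect"])],
            ignore_index=True))
        w = Weights(1.5, 5, 10)
        kw = dict(model=pipeline.model, pas=pipeline.pas, targets=lib,
                  sets=pipeline.sets, profile=pipeline.profile, w=w)
        singles = screen(pipeline.model, pipeline.pas, lib, pipeline.sets,
                         pipeline.profile, w, drug_ids=["HALF_A", "HALF_B"])
        pair = combine("HALF_A", "HALF_B", **kw)
        best_single = max(singles.proportion_of("HALF_A"),
                          singles.proportion_of("HALF_B"))
        assert pair.table["responder_proportion"].iloc[0] > best_single

    def test_exactly_opposing_partner_cancels_the_effect(self, pipeline):
        """A partner drug whose effects negate drug A's on every shared
        pathway drives ES to 0 there, so the pair does no better than
        leaving those pathways untreated."""
        rec_a = pipeline.targets.targets_of("ORACLE00")
        anti = rec_a.assign(drug_id="ANTI", effect=-rec_a["effect"])
        lib = pc.DrugTargetSet(records=pd.concat(
            [pipeline.targets.records, anti], ignore_index=True))
        kw = dict(model=pipeline.model, pas=pipeline.pas, targets=lib,
                  sets=pipeline.sets, profile=pipeline.profile)
        single = screen(pipeline.model, pipeline.pas, lib, pipeline.sets,
                        pipeline.profile,
                        drug_ids=["ORACLE00"]).proportion_of("ORACLE00")
        pair = combine("ORACLE00", "ANTI", **kw)
        assert pair.table["responder_proportion"].iloc[0] <= single
        assert pair.table["responder_proportion"].iloc[0] == 0.0
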
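"""Library-scale simulate-predict-count screening and its validation.

For every drug in a library the disease samples' pathway scores are
calibrated, fed back through the trained classifier, and the fraction of
baseline-diseased samples now predicted normal (the responder proportion) is
recorded. Drugs whose proportion reaches the threshold (default 0.8, i.e. at
least 80% of patients change prediction) are prioritized. Validation counts
how many prioritized drugs are approved or clinically tested for the
indication, and a permutation analysis rebuilds the library with random
targets to check that the real library is not prioritized by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .classifier import TrainedClassifier, predict_labels
from .data_io import DISEASE, HEALTHY, DrugTargetSet, GeneSetCollection, GroundTruth
from .drug_simulation import (DysregulationProfile, Weights, calibrate,
                              effect_scores)
from .ssgsea import PathwayActivityMatrix

logger = logging.getLogger("pathcalib")

DEFAULT_THRESHOLD = 0.8


class ScreenError(RuntimeError):
    pass


@dataclass
class ScreenResult:
    """Per-drug responder accounting, ranked by responder proportion.

    ``table`` columns: drug_id, responder_count, eligible_count,
    responder_proportion, prioritized. Rows are sorted by proportion
    descending with drug id as tie-break.
    """

    table: pd.DataFrame
    threshold: float
    weights: Weights
    eligible_samples: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def prioritized(self) -> frozenset[str]:
        t = self.table
        return frozenset(t.loc[t["prioritized"], "drug_id"])

    @property
    def drug_universe(self) -> frozenset[str]:
        return frozenset(self.table["drug_id"])

    def proportion_of(self, drug_id: str) -> float:
        row = self.table[self.table["drug_id"] == drug_id]
        if row.empty:
            raise KeyError(drug_id)
        return float(row["responder_proportion"].iloc[0])


@dataclass
class ValidationReport:
    """True-positive accounting of a screen against a ground-truth list."""

    indication: str
    n_prioritized: int
    n_approved_hits: int
    n_trial_hits: int
    n_true_positives: int
    proportion_true_positives: float | None   # percent, None if no drug prioritized
    enrichment_p: float | None
    n_library: int
    n_positives_in_library: int
    n_approved_in_library: int
    n_trials_in_library: int
    approved_in_library_pct: float
    trials_in_library_pct: float
    permutation: dict | None = None


def _rank(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    table = table.sort_values(["responder_proportion", "drug_id"],
                              ascending=[False, True], kind="mergesort")
    table["prioritized"] = table["responder_proportion"] >= threshold
    return table.reset_index(drop=True)


def screen(model: TrainedClassifier,
           pas: PathwayActivityMatrix,
           targets: DrugTargetSet,
           sets: GeneSetCollection,
           profile: DysregulationProfile,
           w: Weights = Weights(),
           threshold: float = DEFAULT_THRESHOLD,
           drug_ids: list[str] | None = None) -> ScreenResult:
    """Simulate every drug in the library and count responders.

    Eligible samples are the disease samples the model predicts as diseased
    before any simulation; a responder is an eligible sample predicted
    healthy after calibration with the drug.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    disease = [s for s in pas.sample_ids if pas.labels[s] == DISEASE]
    pas_d = pas.restrict(disease)
    baseline = predict_labels(model, pas_d.scores)
    eligible = [s for s in disease if baseline[s] == DISEASE]
    if not eligible:
        raise ScreenError("model predicts no disease sample as diseased; "
                          "nothing to screen")
    pas_e = pas_d.restrict(eligible)

    rows = []
    for drug in sorted(drug_ids or targets.drug_ids):
        es = effect_scores(drug, targets, sets)
        if es.is_empty():
            logger.debug("drug %s has no pathway-mapped target", drug)
            responders = 0
        else:
            cs = calibrate(pas_e, es, profile, w)
            post = predict_labels(model, cs.scores)
            responders = int((post == HEALTHY).sum())
        rows.append((drug, responders, len(eligible),
                     responders / len(eligible)))
    table = pd.DataFrame(rows, columns=["drug_id", "responder_count",
                                        "eligible_count",
                                        "responder_proportion"])
    return ScreenResult(table=_rank(table, threshold), threshold=threshold,
                        weights=w, eligible_samples=eligible)


def combine(drug_a: str,
            drug_b: str,
            model: TrainedClassifier,
            pas: PathwayActivityMatrix,
            targets: DrugTargetSet,
            sets: GeneSetCollection,
            profile: DysregulationProfile,
            w: Weights = Weights(),
            threshold: float = DEFAULT_THRESHOLD) -> ScreenResult:
    """Screen the pair (drug_a, drug_b) as one virtual drug.

    The pair's interaction records are the multiset union of both drugs'
    records, so a pathway targeted by both drugs averages over the pooled
    effects (opposing effects can cancel to ES = 0, leaving the pathway
    untouched). ``combine(a, a)`` reduces exactly to the single-drug screen.
    """
    rec_a, rec_b = targets.targets_of(drug_a), targets.targets_of(drug_b)
    if rec_a.empty or rec_b.empty:
        raise KeyError(f"both drugs must be present ({drug_a}, {drug_b})")
    pair_id = "+".join(sorted((drug_a, drug_b)))
    pooled = pd.concat([rec_a, rec_b], ignore_index=True)

    disease = [s for s in pas.sample_ids if pas.labels[s] == DISEASE]
    pas_d = pas.restrict(disease)
    baseline = predict_labels(model, pas_d.scores)
    eligible = [s for s in disease if baseline[s] == DISEASE]
    if not eligible:
        raise ScreenError("model predicts no disease sample as diseased")
    pas_e = pas_d.restrict(eligible)

    es = effect_scores(pair_id, targets, sets, records=pooled)
    if es.is_empty():
        responders = 0
    else:
        cs = calibrate(pas_e, es, profile, w)
        post = predict_labels(model, cs.scores)
        responders = int((post == HEALTHY).sum())
    table = pd.DataFrame([(pair_id, responders, len(eligible),
                           responders / len(eligible))],
                         columns=["drug_id", "responder_count",
                                  "eligible_count", "responder_proportion"])
    return ScreenResult(table=_rank(table, threshold), threshold=threshold,
                        weights=w, eligible_samples=eligible,
                        metadata={"pair": tuple(sorted((drug_a, drug_b)))})


def combine_all(prioritized: list[str], **kwargs) -> pd.DataFrame:
    """Screen all unordered pairs from a prioritized list; one row per pair."""
    rows = []
    drugs = sorted(prioritized)
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            res = combine(a, b, **kwargs)
            rows.append(res.table.iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)


def validate(result: ScreenResult,
             truth: GroundTruth,
             indication: str) -> ValidationReport:
    """True-positive proportion among prioritized drugs plus a hypergeometric
    enrichment test against drawing the same number of drugs at random from
    the screened library."""
    library = result.drug_universe
    approved = truth.approved(indication) & library
    trials = truth.clinical_trials(indication) & library
    positives = approved | trials

    prioritized = result.prioritized
    tp = prioritized & positives
    n_pri = len(prioritized)
    if n_pri == 0:
        logger.warning("no drug prioritized; true-positive proportion undefined")
        proportion = None
        p = None
    else:
        proportion = 100.0 * len(tp) / n_pri
        # population = screened library, successes = positives in it,
        # draws = prioritized set, observed = true positives
        p = float(hypergeom.sf(len(tp) - 1, len(library), len(positives), n_pri))
    return ValidationReport(
        indication=indication,
        n_prioritized=n_pri,
        n_approved_hits=len(prioritized & approved),
        n_trial_hits=len(prioritized & trials),
        n_true_positives=len(tp),
        proportion_true_positives=proportion,
        enrichment_p=p,
        n_library=len(library),
        n_positives_in_library=len(positives),
        n_approved_in_library=len(approved),
        n_trials_in_library=len(trials),
        approved_in_library_pct=100.0 * len(approved) / len(library),
        trials_in_library_pct=100.0 * len(trials) / len(library),
    )


def _permuted_library(targets: DrugTargetSet,
                      gene_universe: list[str],
                      rng: np.random.Generator) -> DrugTargetSet:
    """Random-target replicate: same drugs and per-drug target counts,
    targets uniform over the gene universe, effect signs at the original
    activation:inhibition ratio."""
    p_act = targets.activation_ratio()
    rows = []
    for drug in targets.drug_ids:
        k = len(targets.targets_of(drug))
        picked = rng.choice(len(gene_universe), size=k, replace=False)
        effects = np.where(rng.random(k) < p_act, 1, -1)
        for idx, eff in zip(picked, effects):
            rows.append((drug, gene_universe[idx], int(eff)))
    return DrugTargetSet(records=pd.DataFrame(
        rows, columns=["drug_id", "target", "effect"]))


def permutation_robustness(model: TrainedClassifier,
                           pas: PathwayActivityMatrix,
                           targets: DrugTargetSet,
                           sets: GeneSetCollection,
                           profile: DysregulationProfile,
                           w: Weights = Weights(),
                           threshold: float = DEFAULT_THRESHOLD,
                           n_reps: int = 100,
                           seed: int = 0,
                           gene_universe: list[str] | None = None) -> dict:
    """Compare the real library's prioritized count against ``n_reps``
    random-target replicate libraries.

    ``gene_universe`` is the gene vocabulary targets are drawn from
    (typically all genes of the expression matrix). Returns a summary dict
    with the observed count, per-replicate counts and the empirical p-value
    (fraction of replicates prioritizing at least as many drugs).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if gene_universe is None:
        gene_universe = sorted({g for pid in sets.pathway_ids for g in sets[pid]})
    gene_universe = sorted(gene_universe)
    max_targets = max(len(targets.targets_of(d)) for d in targets.drug_ids)
    if len(gene_universe) < max_targets:
        raise ValueError("gene universe smaller than the largest target count")

    observed = len(screen(model, pas, targets, sets, profile, w, threshold)
                   .prioritized)
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_reps):
        perm = _permuted_library(targets, gene_universe, rng)
        counts.append(len(screen(model, pas, perm, sets, profile, w,
                                 threshold).prioritized))
    counts_arr = np.asarray(counts)
    return {
        "observed_prioritized": observed,
        "replicate_prioritized": counts,
        "n_reps": n_reps,
        "empirical_p": float((counts_arr >= observed).mean()),
        "n_strictly_fewer": int((counts_arr < observed).sum()),
        "seed": seed,
    }


def weight_sweep(model: TrainedClassifier,
                 pas: PathwayActivityMatrix,
                 targets: DrugTargetSet,
                 sets: GeneSetCollection,
                 profile: DysregulationProfile,
                 weight_grid: list[tuple[float, float, float]],
                 threshold: float,
                 truth: GroundTruth,
                 indication: str) -> pd.DataFrame:
    """One validation row per (w1, w2, w3) triple."""
    if not weight_grid:
        raise ValueError("empty weight grid")
    rows = []
    for w1, w2, w3 in weight_grid:
        w = Weights(w1, w2, w3)
        rep = validate(screen(model, pas, targets, sets, profile, w, threshold),
                       truth, indication)
        rows.append({"w1": w1, "w2": w2, "w3": w3,
                     "n_prioritized": rep.n_prioritized,
                     "n_true_positives": rep.n_true_positives,
                     "proportion_true_positives": rep.proportion_true_positives,
                     "enrichment_p": rep.enrichment_p})
    return pd.DataFrame(rows)
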
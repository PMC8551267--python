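"""Shared fixtures: synthetic cohorts and a trained end-to-end pipeline.

The session-scoped ``pipeline`` fixture runs the full default-scenario
pipeline once (generate -> ssGSEA -> dysregulation profile -> nested-CV
training) and is reused by the screening and acceptance tests. The CV
protocol is scaled to 3x5 folds to keep the suite fast; the scenario itself
is the package default.
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import pathcalib as pc


@dataclass
class Pipeline:
    scenario: pc.SyntheticScenario
    expr: pc.ExpressionMatrix
    sets: pc.GeneSetCollection
    targets: pc.DrugTargetSet
    truth: pc.GroundTruth
    pas: pc.PathwayActivityMatrix
    profile: pc.DysregulationProfile
    model: pc.TrainedClassifier


def build_pipeline(scenario: pc.SyntheticScenario,
                   repeats: int = 3, folds: int = 5,
                   seed: int = 1, grid: dict | None = None) -> Pipeline:
    expr, sets, targets, truth = pc.generate(scenario)
    pas = pc.ssgsea_scores(expr, sets)
    profile = pc.dysregulation_profile(pas)
    model = pc.train(pas, grid=grid, repeats=repeats, folds=folds, seed=seed)
    return Pipeline(scenario, expr, sets, targets, truth, pas, profile, model)


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    return build_pipeline(pc.SyntheticScenario())


def small_scenario(seed: int = 0, **over) -> pc.SyntheticScenario:
    """A miniature scenario for fast unit tests."""
    params = dict(n_genes=1000, n_pathways=20, genes_per_pathway=20,
                  n_healthy=30, n_disease=30, n_dysregulated=3,
                  n_drugs=12, n_oracle=2, seed=seed)
    params.update(over)
    return pc.SyntheticScenario(**params)


@pytest.fixture(scope="session")
def small_pas() -> pc.PathwayActivityMatrix:
    expr, sets, _, _ = pc.generate(small_scenario())
    return pc.ssgsea_scores(expr, sets)


# ---------------------------------------------------------------------------
# Independent oracles (brute-force re-implementations used only by tests)
# ---------------------------------------------------------------------------

def ssgsea_brute(values: pd.Series, gene_set: frozenset, alpha: float) -> float:
    """Position-by-position running-sum loop, independent of the vectorized
    implementation."""
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    tot_in = sum(abs(v) ** alpha for g, v in items if g in gene_set)
    n_out = sum(1 for g, _ in items if g not in gene_set)
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for g, v in items:
        if g in gene_set:
            cum_in += 1.0 if tot_in == 0 else abs(v) ** alpha
        else:
            cum_out += 1
        denom_in = tot_in if tot_in > 0 else sum(1 for g2, _ in items
                                                 if g2 in gene_set)
        score += cum_in / denom_in - cum_out / n_out
    return score


def calibrate_brute(pas_df: pd.DataFrame,
                    effect_sum: dict, n_targets: dict,
                    mu: pd.Series, q1: float, q2: float, q3: float,
                    w1: float, w2: float, w3: float) -> pd.DataFrame:
    """Naive nested loops over (pathway, sample) applying the scoring rule."""
    out = pas_df.copy()
    for p in pas_df.index:
        if p not in n_targets or effect_sum[p] == 0:
            continue
        sgn = 1 if effect_sum[p] > 0 else -1
        m = mu[p]
        if m > q3:
            wt = w1
        elif m >= q2:
            wt = w2
        else:
            wt = w3
        for d in pas_df.columns:
            out.loc[p, d] = abs(pas_df.loc[p, d]) * wt * sgn
    return out
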
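"""Drug-effect scoring and quartile-weighted calibration of pathway scores.

A drug's effect on a pathway is the mean of its signed (+1 activation, -1
inhibition) effects on the protein targets it has inside that pathway. The
calibration step then replaces each disease sample's activity score on a
targeted pathway p with

    CS(p, d) = |PAS(p, d)| * w * sign(ES(p))        if ES(p) != 0
    CS(p, d) = PAS(p, d)                            if ES(p) == 0

where the weight w is chosen by the quartile bin of the pathway's
dysregulation mu(p) = |mean PAS healthy - mean PAS disease|: w1 above Q3, w2
in the closed middle bin [Q2, Q3], w3 below Q2. Untargeted pathways are
copied unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DISEASE, HEALTHY, DrugTargetSet, GeneSetCollection
from .ssgsea import PathwayActivityMatrix

#: Calibration weights for the upper (>Q3), middle ([Q2, Q3]) and lower
#: (<Q2) dysregulation bins. Note the printed defaults are non-monotone:
#: the lowest bin weighs more than the middle one.
DEFAULT_WEIGHTS = (20.0, 5.0, 10.0)


@dataclass(frozen=True)
class Weights:
    """Calibration weights for the upper, middle and lower mu bins."""

    w1: float = DEFAULT_WEIGHTS[0]
    w2: float = DEFAULT_WEIGHTS[1]
    w3: float = DEFAULT_WEIGHTS[2]

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) <= 0:
            raise ValueError("weights must be positive")


@dataclass
class EffectScores:
    """Per-pathway mean signed drug effect.

    ``effect_sum`` and ``n_targets`` keep the integer numerator and
    denominator so the ES==0 test is exact (zero iff equally many +1 and -1
    effects), with no floating tolerance.
    """

    drug_id: str
    effect_sum: dict[str, int] = field(default_factory=dict)
    n_targets: dict[str, int] = field(default_factory=dict)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.n_targets)

    def es(self, pathway_id: str) -> float:
        return self.effect_sum[pathway_id] / self.n_targets[pathway_id]

    def sgn(self, pathway_id: str) -> int:
        return int(np.sign(self.effect_sum[pathway_id]))

    def is_empty(self) -> bool:
        return not self.n_targets


@dataclass
class DysregulationProfile:
    """Per-pathway |mean(healthy) - mean(disease)| and its quartiles."""

    mu: pd.Series
    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.q2 <= self.q3):
            raise ValueError("quartiles must be ordered")
        if not np.isfinite(self.mu.to_numpy()).all():
            raise ValueError("non-finite dysregulation values")

    def weight_of(self, pathway_id: str, w: Weights) -> float:
        m = self.mu[pathway_id]
        if m > self.q3:
            return w.w1
        if m >= self.q2:
            return w.w2
        return w.w3


@dataclass
class CalibratedScores:
    """Pathways x disease-samples scores after simulated drug treatment."""

    scores: pd.DataFrame
    drug_ids: tuple[str, ...]
    weights: Weights
    quartiles: tuple[float, float, float]


def effect_scores(drug_id: str,
                  targets: DrugTargetSet,
                  sets: GeneSetCollection,
                  records: pd.DataFrame | None = None) -> EffectScores:
    """Mean signed effect of ``drug_id`` on every pathway containing >=1 of
    its targets.

    ``records`` overrides the drug's interaction records (used by the
    combination screen, where a pair's pooled records are scored as one
    virtual drug; duplicates in the pool are kept and enter the mean).
    """
    if records is None:
        records = targets.targets_of(drug_id)
        if records.empty:
            raise KeyError(f"drug {drug_id} not present in the target set")
    es = EffectScores(drug_id=drug_id)
    for _, target, effect in records[["drug_id", "target", "effect"]].itertuples(index=False):
        for pid in sets.pathway_ids:
            if target in sets[pid]:
                es.effect_sum[pid] = es.effect_sum.get(pid, 0) + int(effect)
                es.n_targets[pid] = es.n_targets.get(pid, 0) + 1
    return es


def dysregulation_profile(pas: PathwayActivityMatrix) -> DysregulationProfile:
    """mu(p) = |mean PAS over healthy - mean PAS over disease| per pathway,
    with Q1-Q3 the 25/50/75th linear-interpolation percentiles of mu."""
    healthy = [s for s in pas.sample_ids if pas.labels[s] == HEALTHY]
    disease = [s for s in pas.sample_ids if pas.labels[s] == DISEASE]
    if not healthy or not disease:
        raise ValueError("both classes required to compute dysregulation")
    mu = (pas.scores[healthy].mean(axis=1) - pas.scores[disease].mean(axis=1)).abs()
    q1, q2, q3 = np.percentile(mu.to_numpy(), [25, 50, 75])
    return DysregulationProfile(mu=mu, q1=float(q1), q2=float(q2), q3=float(q3))


def calibrate(pas_disease: PathwayActivityMatrix,
              es: EffectScores,
              profile: DysregulationProfile,
              w: Weights = Weights()) -> CalibratedScores:
    """Apply the scoring algorithm to every disease sample.

    Pathways the drug does not touch are copied from the original scores;
    targeted pathways with ES == 0 are likewise passed through unchanged.
    """
    unknown = set(es.pathway_ids) - set(pas_disease.pathway_ids)
    if unknown:
        raise ValueError(f"effect scores refer to unknown pathways: {sorted(unknown)}")
    cs = pas_disease.scores.copy()
    for pid in es.pathway_ids:
        sgn = es.sgn(pid)
        if sgn == 0:        # exact: equal counts of +1 and -1
            continue
        weight = profile.weight_of(pid, w)
        cs.loc[pid] = cs.loc[pid].abs() * weight * sgn
    return CalibratedScores(scores=cs, drug_ids=(es.drug_id,), weights=w,
                            quartiles=(profile.q1, profile.q2, profile.q3))
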
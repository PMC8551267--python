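"""Synthetic cohorts with planted pathway dysregulation and drug libraries.

The generator emulates the statistical structure the pipeline needs without
any external download: a log-normal expression matrix over a transcriptome-
sized gene universe of which only a minority of genes carry pathway
annotation (as with curated pathway databases against the full genome);
a handful of planted "disease" pathways whose member genes are active in
normal tissue and suppressed in disease; a sparse signed drug-target
library in which a few oracle drugs reactivate exactly the planted
pathways while decoys draw targets uniformly at random.

Because pathway-annotated genes are a small fraction of the universe, random
drugs rarely hit a disease pathway with the right sign — the property the
permutation robustness analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (DISEASE, HEALTHY, DrugTargetSet, ExpressionMatrix,
                      GeneSetCollection, GroundTruth)


@dataclass(frozen=True)
class SyntheticScenario:
    """Generation parameters; defaults are the package's standard test-bed.

    ``effect_size`` is the additive log-scale suppression applied to planted
    pathway genes in disease samples; ``activity_boost`` elevates those
    genes' baseline log-mean so the pathways score positively in normal
    tissue and near zero after suppression.
    """

    n_genes: int = 20_000
    n_pathways: int = 50
    genes_per_pathway: int = 40
    n_healthy: int = 60
    n_disease: int = 60
    n_dysregulated: int = 5
    effect_size: float = 1.0
    noise_sd: float = 0.5
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    activity_boost: float = 1.5
    n_drugs: int = 100
    n_oracle: int = 5
    targets_per_drug: int = 3
    decoy_activation_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_pathways, self.genes_per_pathway,
                  self.n_healthy, self.n_disease, self.n_drugs,
                  self.targets_per_drug)
        if min(counts) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("pathways cannot cover more genes than exist")
        if self.n_dysregulated > self.n_pathways:
            raise ValueError("more dysregulated pathways than pathways")
        if self.n_oracle > self.n_drugs:
            raise ValueError("more oracle drugs than drugs")
        if self.targets_per_drug > self.n_genes:
            raise ValueError("targets_per_drug exceeds the gene universe")

    @property
    def pathway_ids(self) -> list[str]:
        return [f"PW{i:04d}" for i in range(self.n_pathways)]

    @property
    def dysregulated_pathway_ids(self) -> list[str]:
        return self.pathway_ids[: self.n_dysregulated]

    @property
    def oracle_drug_ids(self) -> list[str]:
        return [f"ORACLE{i:02d}" for i in range(self.n_oracle)]

    @property
    def decoy_drug_ids(self) -> list[str]:
        return [f"DECOY{i:03d}" for i in range(self.n_drugs - self.n_oracle)]


def generate(scenario: SyntheticScenario = SyntheticScenario()
             ) -> tuple[ExpressionMatrix, GeneSetCollection, DrugTargetSet,
                        GroundTruth]:
    """Generate the four standard inputs for one scenario, deterministically
    from its seed."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    genes = np.array([f"G{i:05d}" for i in range(sc.n_genes)])
    samples = ([f"H{i:03d}" for i in range(sc.n_healthy)]
               + [f"D{i:03d}" for i in range(sc.n_disease)])
    labels = pd.Series([HEALTHY] * sc.n_healthy + [DISEASE] * sc.n_disease,
                       index=samples)

    # pathway membership: a random subset of the universe, partitioned
    covered = rng.permutation(sc.n_genes)[: sc.n_pathways * sc.genes_per_pathway]
    sets = {}
    for k, pid in enumerate(sc.pathway_ids):
        block = covered[k * sc.genes_per_pathway:(k + 1) * sc.genes_per_pathway]
        sets[pid] = frozenset(genes[block])
    collection = GeneSetCollection(sets=sets)

    # log-scale means; planted pathways active at baseline, suppressed in disease
    log_mu = rng.normal(sc.baseline_log_mean, sc.baseline_log_sd, sc.n_genes)
    dys_gene_idx = covered[: sc.n_dysregulated * sc.genes_per_pathway]
    log_mu[dys_gene_idx] += sc.activity_boost
    shift = np.zeros(sc.n_genes)
    shift[dys_gene_idx] = -sc.effect_size            # suppression in disease

    log_expr = (log_mu[:, None]
                + rng.normal(0.0, sc.noise_sd, (sc.n_genes, len(samples))))
    log_expr[:, sc.n_healthy:] += shift[:, None]
    expr = ExpressionMatrix(
        values=pd.DataFrame(np.exp(log_expr), index=genes, columns=samples),
        labels=labels)

    # drug library: oracles reactivate one gene in every planted pathway
    rows = []
    for drug in sc.oracle_drug_ids:
        for pid in sc.dysregulated_pathway_ids:
            target = rng.choice(sorted(collection[pid]))
            rows.append((drug, target, +1))          # opposes the suppression
    for drug in sc.decoy_drug_ids:
        picked = rng.choice(sc.n_genes, size=sc.targets_per_drug, replace=False)
        effs = np.where(rng.random(sc.targets_per_drug)
                        < sc.decoy_activation_ratio, 1, -1)
        for idx, eff in zip(picked, effs):
            rows.append((drug, genes[idx], int(eff)))
    targets = DrugTargetSet(records=pd.DataFrame(
        rows, columns=["drug_id", "target", "effect"]))

    truth = GroundTruth(indications={
        "synthetic": {"approved": frozenset(sc.oracle_drug_ids),
                      "clinical_trials": frozenset()}})
    return expr, collection, targets, truth
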
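"""One-call orchestration of the simulated end-to-end study.

Convenience layer for experiments and tests: simulate a population with
planted causal structure, build TWAS p-values and per-TF evidence, fit the
model for every testable (TF, drug) pair, and rank associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evidence import build_evidence, scan_cis_features, twas_scan
from .model import EMConfig, PvalueVector, DEFAULT_CONFIG
from .ranking import rank_associations, run_association, testable_tfs, AssociationTable
from .simulate import (
    GroundTruth,
    PopulationData,
    PopulationSimConfig,
    simulate_population,
)


@dataclass
class StudyResult:
    """Everything produced by one simulated end-to-end run."""

    data: PopulationData
    truth: GroundTruth
    twas: dict[str, PvalueVector]
    evidence: dict
    evidence_details: pd.DataFrame
    tables: dict[str, AssociationTable] = field(default_factory=dict)


def run_simulated_study(
    config: PopulationSimConfig,
    modes: tuple[str, ...] = ("eQTL+M",),
    llr_threshold: float = 3.0,
    evidence_threshold: float = 0.05,
    em_config: EMConfig = DEFAULT_CONFIG,
) -> StudyResult:
    """Simulate, build evidence, fit and rank; one AssociationTable per mode."""
    data, truth = simulate_population(config)
    C = data.covariates.values.T
    twas = {
        drug: twas_scan(data.expression, data.phenotype.row(drug), C)
        for drug in data.phenotype.row_ids
    }
    scans = scan_cis_features(
        data.genes, data.features, data.expression, C, span=config.cis_span
    )
    matrices, details = build_evidence(
        data.genes, scans, data.peaks_by_tf, threshold=evidence_threshold
    )
    result = StudyResult(data, truth, twas, matrices, details)
    tfs = testable_tfs(matrices)
    for mode in modes:
        rows = []
        for tf in tfs:
            for drug, pvec in twas.items():
                rows.append(
                    run_association(tf, drug, mode, pvec, matrices[tf], em_config)
                )
        result.tables[mode] = rank_associations(
            rows, llr_threshold, metadata={"mode": mode, "seed": config.seed}
        )
    return result


def evidence_recovery(
    truth: GroundTruth, matrices: dict, details: pd.DataFrame
) -> tuple[float, float]:
    """Sensitivity and false-positive rate of evidence recovery.

    Sensitivity: fraction of (TF, gene, kind) slots whose peak covers a
    planted-effect feature (expected evidence) that were called r = 1.
    False-positive rate: among slots with at least one in-peak feature but
    no planted effect in a peak, the fraction called r = 1 — this should
    track the scan p-value threshold.
    """
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    kind_index = {"eQTL": 0, "eQTM": 1}
    tp = fn = fp = tn = 0
    for tf, mat in matrices.items():
        r_true = truth.r_by_tf[tf]
        det = details[details["tf"] == tf]
        observed = {}
        for row in det.itertuples(index=False):
            observed[(row.gene_id, row.evidence)] = row.r
        for (gene_id, kind), r_obs in observed.items():
            gi = gene_index[gene_id]
            ki = kind_index[kind]
            if r_true[gi, ki] == 1:
                tp += r_obs
                fn += 1 - r_obs
            else:
                fp += r_obs
                tn += 1 - r_obs
        # expected-evidence slots with no scan row at all are misses
        for gi in range(r_true.shape[0]):
            for kind, ki in kind_index.items():
                if r_true[gi, ki] == 1 and (truth.gene_ids[gi], kind) not in observed:
                    fn += 1
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    return sensitivity, fpr
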
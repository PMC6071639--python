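"""Per-(TF, drug, mode) model fits, ranking, baselines and set comparisons."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import model
from .evidence import AssayMatrix, twas_scan
from .model import EMConfig, EvidenceMatrix, FitResult, ModelParams, PvalueVector

logger = logging.getLogger(__name__)

#: General TFs excluded from ranking by default (polymerases and TBP bind
#: near most genes and carry no drug-specific signal).
GENERAL_TFS = ("POLR2A", "POLR3A", "POLR3G", "TBP")

DEFAULT_LLR_THRESHOLD = 3.0


@dataclass(frozen=True)
class AnalysisMode:
    """Which evidence channels enter the model (M = number of channels)."""

    name: str
    evidence_kinds: tuple[str, ...]

    def __post_init__(self):
        if len(self.evidence_kinds) < 1:
            raise ValueError("a mode needs at least one evidence kind")


MODES: dict[str, AnalysisMode] = {
    "eQTL": AnalysisMode("eQTL", ("eQTL",)),
    "eQTM": AnalysisMode("eQTM", ("eQTM",)),
    "eQTL+M": AnalysisMode("eQTL+M", ("eQTL", "eQTM")),
}


def resolve_mode(mode: AnalysisMode | str) -> AnalysisMode:
    if isinstance(mode, AnalysisMode):
        return mode
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; known: {sorted(MODES)}")
    return MODES[mode]


@dataclass(frozen=True)
class AssociationResult:
    """One (TF, drug, mode) association scored by the model."""

    tf_id: str
    drug_id: str
    mode: str
    llr: float
    chisq_p: float
    alt_params: ModelParams
    classification: str
    n_genes: int
    n_evidence: tuple[int, ...]
    loglik_alt: float
    loglik_null: float
    converged: bool


@dataclass
class AssociationTable:
    """Ranked association results for one mode plus run metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def testable_tfs(
    evidence_by_tf: Mapping[str, EvidenceMatrix],
    exclude: Sequence[str] | None = None,
) -> list[str]:
    """TFs that carry at least one evidence bit and are not excluded.

    TFs whose evidence is all-zero across genes for every kind cannot
    inform the model (their weights are unidentifiable) and are dropped,
    as are TFs on the exclusion list (default: general TFs) regardless of
    evidence.
    """
    excluded = set(GENERAL_TFS if exclude is None else exclude)
    out = []
    for tf in sorted(evidence_by_tf):
        if tf in excluded:
            continue
        if evidence_by_tf[tf].entries.any():
            out.append(tf)
        else:
            logger.info("TF %s has no evidence in any kind; not testable", tf)
    return out


def run_association(
    tf_id: str,
    drug_id: str,
    mode: AnalysisMode | str,
    pvals: PvalueVector,
    evidence: EvidenceMatrix,
    config: EMConfig = model.DEFAULT_CONFIG,
) -> AssociationResult:
    """Fit null and alternative models and score one (TF, drug, mode)."""
    mode = resolve_mode(mode)
    try:
        ev = evidence.select_kinds(mode.evidence_kinds)
        null = model.fit_null(pvals, config)
        alt = model.fit(pvals, ev, config, null=null)
        llr_value = model.llr(alt, null)
        chisq_p = model.llr_chisq_pvalue(llr_value, df=ev.n_kinds)
        classification = model.classify_fit(alt)
    except (model.InputError, model.ParameterError) as err:
        raise type(err)(f"(TF={tf_id}, drug={drug_id}): {err}") from err
    return AssociationResult(
        tf_id=tf_id,
        drug_id=drug_id,
        mode=mode.name,
        llr=llr_value,
        chisq_p=chisq_p,
        alt_params=alt.params,
        classification=classification,
        n_genes=len(pvals),
        n_evidence=tuple(int(c) for c in ev.entries.sum(axis=0)),
        loglik_alt=alt.loglik,
        loglik_null=null.loglik,
        converged=alt.converged and null.converged,
    )


def rank_associations(
    results: Sequence[AssociationResult],
    llr_threshold: float = DEFAULT_LLR_THRESHOLD,
    metadata: dict | None = None,
) -> AssociationTable:
    """Sort associations by LLR (descending), flagging those above threshold.

    Rows below the threshold are retained but flagged; ties are broken by
    (tf, drug) lexicographic order for reproducibility.
    """
    rows = []
    seen = set()
    for res in results:
        key = (res.tf_id, res.drug_id, res.mode)
        if key in seen:
            raise ValueError(f"duplicate association {key}")
        seen.add(key)
        w = res.alt_params.weights
        row = {
            "tf": res.tf_id,
            "drug": res.drug_id,
            "mode": res.mode,
            "llr": res.llr,
            "chisq_p": res.chisq_p,
            "alpha": res.alt_params.alpha,
            "classification": res.classification,
            "n_genes": res.n_genes,
            "converged": res.converged,
        }
        row["w0"] = w[0]
        for m in range(1, len(w)):
            row[f"w{m}"] = w[m]
        for m, count in enumerate(res.n_evidence, start=1):
            row[f"n_evidence_{m}"] = count
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["llr", "tf", "drug"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
        df["passes"] = df["llr"] >= llr_threshold
    else:
        df["passes"] = pd.Series(dtype=bool)
    meta = dict(metadata or {})
    meta["llr_threshold"] = llr_threshold
    return AssociationTable(df, meta)


def compare_sets(set_a, set_b, universe_size: int) -> dict:
    """Overlap, Jaccard coefficient and hypergeometric enrichment of two sets.

    The upper-tail probability P(X >= overlap) is computed for X
    hypergeometric with population ``universe_size``, ``|A|`` successes and
    ``|B|`` draws; it is symmetric under swapping the two sets.
    """
    A, B = set(set_a), set(set_b)
    union = A | B
    if universe_size < len(union):
        raise ValueError(
            f"universe_size={universe_size} smaller than |A ∪ B|={len(union)}"
        )
    overlap = len(A & B)
    jaccard = overlap / len(union) if union else 0.0
    p = float(hypergeom.sf(overlap - 1, universe_size, len(A), len(B)))
    return {"overlap": overlap, "jaccard": jaccard, "hypergeom_p": p}


def baseline_tf_expression(
    tf_expression: AssayMatrix,
    phenotypes: AssayMatrix,
    covariates=None,
    fdr: float = 0.1,
    per_drug: bool = False,
) -> pd.DataFrame:
    """Baseline: TF expression correlated directly with drug cytotoxicity.

    One covariate-adjusted partial regression per (TF, drug), with
    Benjamini-Hochberg FDR control across all pairs (or per drug).
    """
    tables = []
    for drug in phenotypes.row_ids:
        _, tab = twas_scan(
            tf_expression, phenotypes.row(drug), covariates, return_table=True
        )
        tab = tab.rename(columns={"gene_id": "tf"})
        tab["drug"] = drug
        tables.append(tab)
    out = pd.concat(tables, ignore_index=True)
    if len(out) == 0:
        out["qvalue"] = []
        out["flagged"] = []
        return out
    if per_drug:
        parts = []
        for _, grp in out.groupby("drug", sort=False):
            grp = grp.copy()
            rej, qv, _, _ = multipletests(grp["pvalue"], alpha=max(fdr, 1e-300), method="fdr_bh")
            grp["qvalue"] = qv
            grp["flagged"] = qv <= fdr
            parts.append(grp)
        out = pd.concat(parts, ignore_index=True)
    else:
        _, qv, _, _ = multipletests(out["pvalue"], alpha=max(fdr, 1e-300), method="fdr_bh")
        out["qvalue"] = qv
        out["flagged"] = qv <= fdr
    return out.sort_values(["drug", "pvalue", "tf"]).reset_index(drop=True)


def _top_k_ids(ids: np.ndarray, scores: np.ndarray, k: int, largest: bool) -> set:
    """Deterministic top-k by score, ties broken by id (ascending)."""
    order = np.lexsort((ids, -scores if largest else scores))
    return set(ids[order[:k]])


def baseline_chip_enrichment(
    chip_scores: pd.DataFrame,
    twas_by_drug: Mapping[str, PvalueVector],
    top_k: int = 500,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Baseline: hypergeometric overlap of top ChIP-target and top TWAS genes.

    ``chip_scores`` is a gene x TF DataFrame of the maximum ChIP peak score
    in each gene's cis window (NaN where the TF has no peak near the gene).
    For each (TF, drug) the top ``top_k`` genes by ChIP score are tested for
    overlap with the top ``top_k`` genes by TWAS significance in the shared
    gene universe; BH correction is applied per drug.
    """
    rows = []
    for drug, pvec in twas_by_drug.items():
        shared = np.intersect1d(np.asarray(chip_scores.index), pvec.gene_ids)
        universe = len(shared)
        pmap = pd.Series(pvec.values, index=pvec.gene_ids).loc[shared]
        k_drug = min(top_k, universe)
        top_twas = _top_k_ids(
            shared.astype(str), pmap.to_numpy(), k_drug, largest=False
        )
        for tf in chip_scores.columns:
            scores = chip_scores.loc[shared, tf]
            scored = scores.dropna()
            k_tf = min(top_k, len(scored))
            if k_tf < top_k:
                logger.info(
                    "baseline_chip_enrichment: TF %s has %d scored genes (< %d)",
                    tf, len(scored), top_k,
                )
            if k_tf == 0:
                continue
            top_chip = _top_k_ids(
                scored.index.to_numpy(dtype=str),
                scored.to_numpy(),
                k_tf,
                largest=True,
            )
            overlap = len(top_chip & top_twas)
            p = float(hypergeom.sf(overlap - 1, universe, k_tf, k_drug))
            rows.append((tf, drug, overlap, k_tf, k_drug, universe, p))
    out = pd.DataFrame(
        rows, columns=["tf", "drug", "overlap", "k_tf", "k_drug", "universe", "pvalue"]
    )
    if len(out) == 0:
        out["qvalue"] = []
        out["flagged"] = []
        return out
    parts = []
    for _, grp in out.groupby("drug", sort=False):
        grp = grp.copy()
        _, qv, _, _ = multipletests(grp["pvalue"], alpha=max(fdr, 1e-300), method="fdr_bh")
        grp["qvalue"] = qv
        grp["flagged"] = qv <= fdr
        parts.append(grp)
    return (
        pd.concat(parts, ignore_index=True)
        .sort_values(["drug", "pvalue", "tf"])
        .reset_index(drop=True)
    )


def max_chip_score_per_gene(
    genes,
    peaks_by_tf: Mapping[str, Sequence],
    span: int = 50_000,
    include_tss: bool = True,
) -> pd.DataFrame:
    """Gene x TF matrix of the maximum peak score in each gene's cis window."""
    from .evidence import cis_window  # local import to avoid cycle

    gene_ids = [g.gene_id for g in genes]
    out = pd.DataFrame(np.nan, index=gene_ids, columns=sorted(peaks_by_tf))
    windows = [(g, cis_window(g, span, include_tss)) for g in genes]
    for tf in sorted(peaks_by_tf):
        for g, win in windows:
            best = np.nan
            for peak in peaks_by_tf[tf]:
                if peak.chrom != win.chrom:
                    continue
                if peak.start < win.end and win.start < peak.end:
                    score = 0.0 if peak.score is None else peak.score
                    if np.isnan(best) or score > best:
                        best = score
            out.loc[g.gene_id, tf] = best
    return out
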
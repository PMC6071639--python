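"""From per-individual omic matrices to TWAS p-values and binary evidence.

Covers the association scans (TWAS, cis-eQTL, cis-eQTM as covariate-adjusted
partial regressions), the strand-relative 50-kb upstream window, HOT-region
peak filtering, the variant-in-peak intersection that yields the binary
evidence matrix per TF, and a plain genotype-PCA helper for population
covariates.

Coordinates are BED-style 0-based half-open throughout.  Scans are computed
two ways internally: an exact per-unit OLS (``partial_regression_pvalue``)
and a vectorised Frisch-Waugh residualisation used by the genome-wide
drivers; the two agree to numerical precision and are cross-checked in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .model import EvidenceMatrix, PvalueVector

logger = logging.getLogger(__name__)

#: Map from feature kind to the evidence channel it supports.
KIND_TO_EVIDENCE = {"SNP": "eQTL", "CpG": "eQTM"}
EVIDENCE_KINDS = ("eQTL", "eQTM")

DEFAULT_CIS_SPAN = 50_000
DEFAULT_EVIDENCE_THRESHOLD = 0.05


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class DegenerateFitError(ValueError):
    """Residual variance is zero; the t-test is undefined."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's transcription start site; strand decides what 'upstream' means."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


class FeatureTrack:
    """A set of positioned molecular features with per-individual values.

    ``table`` is indexed by feature_id with columns (chrom, pos, kind);
    ``values`` is a feature x individual DataFrame aligned on feature_id.
    SNP values are allelic dosages in [0, 2] (mean-imputed reals allowed);
    CpG values are methylation beta values in [0, 1].
    """

    def __init__(self, table: pd.DataFrame, values: pd.DataFrame):
        required = {"chrom", "pos", "kind"}
        if not required.issubset(table.columns):
            raise ValueError(f"feature table needs columns {sorted(required)}")
        if table.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if not table.index.equals(values.index):
            values = values.loc[table.index]
        bad_kinds = set(table["kind"]) - set(KIND_TO_EVIDENCE)
        if bad_kinds:
            raise ValueError(f"unknown feature kinds {sorted(bad_kinds)}")
        v = values.to_numpy(dtype=float)
        snp_mask = (table["kind"] == "SNP").to_numpy()
        if snp_mask.any():
            snp_vals = v[snp_mask]
            ok = np.isnan(snp_vals) | ((snp_vals >= 0) & (snp_vals <= 2))
            if not ok.all():
                raise ValueError("SNP dosages must lie in [0, 2]")
        cpg_mask = (table["kind"] == "CpG").to_numpy()
        if cpg_mask.any():
            cpg_vals = v[cpg_mask]
            ok = np.isnan(cpg_vals) | ((cpg_vals >= 0) & (cpg_vals <= 1))
            if not ok.all():
                raise ValueError("CpG beta values must lie in [0, 1]")
        self.table = table
        self.values = values

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index

    @property
    def individual_ids(self) -> pd.Index:
        return self.values.columns

    def subset_kind(self, kind: str) -> "FeatureTrack":
        mask = self.table["kind"] == kind
        return FeatureTrack(self.table.loc[mask], self.values.loc[mask])

    def __len__(self) -> int:
        return len(self.table)


class AssayMatrix:
    """Real-valued matrix of rows (genes / drugs / covariates) x individuals."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("duplicate row ids in AssayMatrix")
        if data.columns.has_duplicates:
            raise ValueError("duplicate individual ids in AssayMatrix")
        self.data = data.astype(float)

    @property
    def row_ids(self) -> pd.Index:
        return self.data.index

    @property
    def individual_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def row(self, row_id: str) -> np.ndarray:
        return self.data.loc[row_id].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ScanResult:
    """One covariate-adjusted association test."""

    unit_id: str
    beta_hat: float
    t_stat: float
    pvalue: float
    n_used: int


def _covariate_array(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError(f"covariates have {C.shape[0]} rows, expected {n}")
    return C


def partial_regression_pvalue(
    response,
    predictor,
    covariates=None,
    unit_id: str = "",
) -> ScanResult:
    """Two-sided t-test of the predictor coefficient in an OLS fit.

    The design is [intercept, predictor, covariates]; the test has
    n - (k + 2) degrees of freedom for k covariates.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    n = len(y)
    if len(x) != n:
        raise ValueError("response and predictor lengths differ")
    C = _covariate_array(covariates, n)
    X = np.column_stack([np.ones(n), x, C])
    k = X.shape[1]
    dof = n - k
    if dof < 1:
        raise ValueError(
            f"insufficient observations: n={n} for {k} coefficients"
        )

    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    deficient = np.where(diag <= tol)[0]
    if deficient.size:
        names = ["intercept", "predictor"] + [
            f"covariate {j}" for j in range(C.shape[1])
        ]
        raise CollinearityError(
            f"design matrix is rank deficient at column {names[deficient[0]]!r}"
        )

    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    yvar = float(np.var(y)) * n
    if rss <= 1e-12 * max(yvar, 1.0):
        raise DegenerateFitError("degenerate fit: zero residual variance")
    sigma2 = rss / dof
    rinv = np.linalg.inv(r)
    xtx_inv = rinv @ rinv.T
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t_stat = float(beta[1] / se)
    pvalue = float(2.0 * stats.t.sf(abs(t_stat), dof))
    return ScanResult(unit_id, float(beta[1]), t_stat, pvalue, n)


def _residual_basis(covariates, n: int) -> np.ndarray:
    """Orthonormal basis of [1 | covariates], for Frisch-Waugh projection."""
    C = _covariate_array(covariates, n)
    X = np.column_stack([np.ones(n), C])
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if np.any(diag <= max(X.shape) * np.finfo(float).eps * diag.max()):
        raise CollinearityError("covariate block is rank deficient")
    return q


def _residualize_rows(M: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residualise each row of M against the column space of q."""
    return M - (M @ q) @ q.T


def _corr_to_tp(r: np.ndarray, dof: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.clip(r, -1.0, 1.0)
    denom = np.sqrt(np.maximum(1.0 - r * r, 1e-300))
    t = r * np.sqrt(dof) / denom
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p


def twas_scan(
    expression: AssayMatrix,
    phenotype,
    covariates=None,
    return_table: bool = False,
):
    """Per-gene partial regression of the phenotype on expression.

    Returns a :class:`PvalueVector` keyed by gene (and optionally the full
    table with effect sizes and t statistics).  Genes with constant
    expression or a perfect fit are dropped with a log message rather than
    failing the whole scan.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if len(expression.individual_ids) != n:
        raise ValueError("phenotype length does not match expression individuals")
    E = expression.values
    q = _residual_basis(covariates, n)
    n_cov = q.shape[1] - 1
    dof = n - (n_cov + 2)
    if dof < 1:
        raise ValueError("insufficient degrees of freedom for the TWAS scan")

    Er = _residualize_rows(E, q)
    yr = y - q @ (q.T @ y)
    ess = np.einsum("ij,ij->i", Er, Er)
    yss = float(yr @ yr)
    keep = ess > 1e-12 * n
    if yss <= 1e-12 * n:
        raise DegenerateFitError("phenotype is constant after covariate adjustment")
    num = Er @ yr
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(keep, num / np.sqrt(np.maximum(ess * yss, 1e-300)), 0.0)
    perfect = keep & (np.abs(r) > 1.0 - 1e-12)
    keep &= ~perfect
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("twas_scan: dropped %d degenerate gene(s)", n_dropped)
    t, p = _corr_to_tp(r[keep], dof)
    beta = num[keep] / ess[keep]
    gene_ids = np.asarray(expression.row_ids)[keep]
    pvec = PvalueVector(p, gene_ids)
    if not return_table:
        return pvec
    table = pd.DataFrame(
        {"gene_id": gene_ids, "beta": beta, "t": t, "pvalue": p, "n_used": n}
    )
    return pvec, table


def cis_window(
    gene: GeneAnnotation,
    span: int = DEFAULT_CIS_SPAN,
    include_tss: bool = True,
) -> GenomicInterval:
    """Strand-relative upstream window of ``span`` bases, clipped at 0.

    On '+' the window is [tss - span, tss + 1); on '-' it is
    [tss, tss + span + 1).  The TSS base itself is included unless
    ``include_tss`` is False.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if gene.strand == "+":
        start = max(0, gene.tss - span)
        end = gene.tss + 1 if include_tss else gene.tss
    else:
        start = gene.tss if include_tss else gene.tss + 1
        end = gene.tss + span + 1
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def _interval_trees(
    intervals: Iterable[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _merged_intervals(
    intervals: Iterable[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (starts, ends) arrays for fast point membership."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def filter_peaks(
    peaks_by_tf: Mapping[str, Sequence[GenomicInterval]],
    exclusion: Sequence[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    """Drop peaks overlapping any exclusion interval by >= 1 bp.

    Used to remove ChIP peaks in high-occupancy-target (HOT) regions, which
    are bound promiscuously and treated as artifacts.
    """
    trees = _interval_trees(exclusion)
    out: dict[str, list[GenomicInterval]] = {}
    for tf, peaks in peaks_by_tf.items():
        kept = []
        for peak in peaks:
            tree = trees.get(peak.chrom)
            if tree is not None and tree.overlaps(peak.start, peak.end):
                continue
            kept.append(peak)
        out[tf] = kept
    return out


def cis_feature_scan(
    gene: GeneAnnotation,
    features: FeatureTrack,
    expression_row,
    covariates=None,
    span: int = DEFAULT_CIS_SPAN,
    include_tss: bool = True,
) -> list[ScanResult]:
    """Partial regression of a gene's expression on each cis feature.

    Features (SNP dosage or CpG beta) within the gene's upstream window are
    tested one at a time; monomorphic features are skipped with a log line.
    """
    window = cis_window(gene, span, include_tss)
    tab = features.table
    in_win = (
        (tab["chrom"] == window.chrom)
        & (tab["pos"] >= window.start)
        & (tab["pos"] < window.end)
    )
    results = []
    expr = np.asarray(expression_row, dtype=float)
    for fid in tab.index[in_win]:
        x = features.values.loc[fid].to_numpy(dtype=float)
        if np.var(x) <= 1e-12:
            logger.info("cis scan %s: feature %s is monomorphic, skipped", gene.gene_id, fid)
            continue
        results.append(
            partial_regression_pvalue(expr, x, covariates, unit_id=str(fid))
        )
    return results


def scan_cis_features(
    genes: Sequence[GeneAnnotation],
    features: FeatureTrack,
    expression: AssayMatrix,
    covariates=None,
    span: int = DEFAULT_CIS_SPAN,
    include_tss: bool = True,
) -> pd.DataFrame:
    """Vectorised cis scan over all genes; one row per (gene, in-window feature).

    Equivalent (to numerical precision) to mapping
    :func:`partial_regression_pvalue` over windows, via Frisch-Waugh
    residualisation against the shared covariate block.
    """
    n = len(expression.individual_ids)
    if len(features.individual_ids) != n:
        raise ValueError("feature and expression individuals differ in number")
    q = _residual_basis(covariates, n)
    n_cov = q.shape[1] - 1
    dof = n - (n_cov + 2)
    if dof < 1:
        raise ValueError("insufficient degrees of freedom for the cis scan")

    F = features.values.to_numpy(dtype=float)
    Fr = _residualize_rows(F, q)
    fss = np.einsum("ij,ij->i", Fr, Fr)
    E = expression.values
    Er = _residualize_rows(E, q)
    ess = np.einsum("ij,ij->i", Er, Er)

    tab = features.table
    pos = tab["pos"].to_numpy()
    chroms = tab["chrom"].to_numpy()
    kinds = tab["kind"].to_numpy()
    fids = tab.index.to_numpy()
    expr_index = {g: i for i, g in enumerate(expression.row_ids)}

    rows = []
    for gene in genes:
        gi = expr_index.get(gene.gene_id)
        if gi is None:
            logger.info("scan_cis_features: no expression for %s, skipped", gene.gene_id)
            continue
        window = cis_window(gene, span, include_tss)
        mask = (chroms == window.chrom) & (pos >= window.start) & (pos < window.end)
        idx = np.where(mask)[0]
        if idx.size == 0:
            continue
        ok = fss[idx] > 1e-12 * n
        idx = idx[ok]
        if idx.size == 0:
            continue
        if ess[gi] <= 1e-12 * n:
            logger.info("scan_cis_features: %s expression constant, skipped", gene.gene_id)
            continue
        num = Fr[idx] @ Er[gi]
        r = num / np.sqrt(fss[idx] * ess[gi])
        t, p = _corr_to_tp(r, dof)
        beta = num / fss[idx]
        for j, fi in enumerate(idx):
            rows.append(
                (
                    gene.gene_id,
                    fids[fi],
                    kinds[fi],
                    chroms[fi],
                    int(pos[fi]),
                    float(beta[j]),
                    float(t[j]),
                    float(p[j]),
                    n,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "feature_id",
            "kind",
            "chrom",
            "pos",
            "beta",
            "t",
            "pvalue",
            "n_used",
        ],
    )


def build_evidence(
    genes: Sequence[GeneAnnotation],
    scans: pd.DataFrame,
    peaks_by_tf: Mapping[str, Sequence[GenomicInterval]],
    threshold: float = DEFAULT_EVIDENCE_THRESHOLD,
    best_variant: str = "per_tf",
) -> tuple[dict[str, EvidenceMatrix], pd.DataFrame]:
    """Binary evidence per TF: significant in-peak cis feature per (gene, kind).

    For each (TF, gene, evidence kind), the most significant feature of that
    kind lying inside one of the TF's peaks within the gene's cis window is
    taken; the evidence bit is 1 iff its p-value is <= ``threshold``.  With
    ``best_variant='global'`` the per-(gene, kind) best feature across the
    whole window is chosen first and evidence requires that single feature
    to fall inside a peak (an alternative reading of the best-variant rule).

    Returns the per-TF evidence matrices (all sharing the gene order of
    ``genes``) and a long details table with the minimising feature.
    """
    if best_variant not in ("per_tf", "global"):
        raise ValueError("best_variant must be 'per_tf' or 'global'")
    gene_ids = np.asarray([g.gene_id for g in genes])
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    scans = scans.copy()
    scans["evidence"] = scans["kind"].map(KIND_TO_EVIDENCE)
    if scans["evidence"].isna().any():
        bad = scans.loc[scans["evidence"].isna(), "kind"].unique()
        raise ValueError(f"unknown feature kinds in scans: {list(bad)}")

    if best_variant == "global":
        # deterministic: smallest p, ties by feature_id
        scans = (
            scans.sort_values(["gene_id", "evidence", "pvalue", "feature_id"])
            .groupby(["gene_id", "evidence"], as_index=False)
            .head(1)
        )

    kinds = EVIDENCE_KINDS
    matrices: dict[str, EvidenceMatrix] = {}
    detail_rows = []
    scan_pos = scans["pos"].to_numpy()
    scan_chrom = scans["chrom"].to_numpy()
    for tf in sorted(peaks_by_tf):
        peaks = peaks_by_tf[tf]
        if len(peaks) == 0:
            logger.warning("TF %s has zero peaks; evidence is all-zero", tf)
        in_peak = np.zeros(len(scans), dtype=bool)
        for chrom, (starts, ends) in _merged_intervals(peaks).items():
            sel = scan_chrom == chrom
            pos = scan_pos[sel]
            idx = np.searchsorted(starts, pos, side="right") - 1
            hit = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
            in_peak[sel] = hit
        sub = scans.loc[in_peak]
        entries = np.zeros((len(gene_ids), len(kinds)), dtype=np.int8)
        best = (
            sub.sort_values(["gene_id", "evidence", "pvalue", "feature_id"])
            .groupby(["gene_id", "evidence"], as_index=False)
            .head(1)
        )
        for row in best.itertuples(index=False):
            gi = gene_index.get(row.gene_id)
            if gi is None:
                continue
            ki = kinds.index(row.evidence)
            hit = int(row.pvalue <= threshold)
            entries[gi, ki] = hit
            detail_rows.append(
                (tf, row.gene_id, row.evidence, row.feature_id, row.pvalue, hit)
            )
        matrices[tf] = EvidenceMatrix(entries, gene_ids, kinds)
    details = pd.DataFrame(
        detail_rows,
        columns=["tf", "gene_id", "evidence", "feature_id", "min_pvalue", "r"],
    )
    return matrices, details


def genotype_pcs(genotypes: FeatureTrack | np.ndarray, k: int) -> np.ndarray:
    """Top-k principal components of the column-standardised dosage matrix.

    A plain-PCA stand-in for dedicated population-structure tools: returns an
    (individuals x k) matrix of PC scores with a deterministic sign convention
    (the largest-magnitude variant loading of each component is positive).
    Zero-variance variants are excluded before standardisation.
    """
    if isinstance(genotypes, FeatureTrack):
        G = genotypes.values.to_numpy(dtype=float)
    else:
        G = np.asarray(genotypes, dtype=float)
    n = G.shape[1]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_individuals={n}")
    if k == 0:
        return np.empty((n, 0))
    X = G.T  # individuals x variants
    sd = X.std(axis=0)
    keep = sd > 1e-12
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs
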
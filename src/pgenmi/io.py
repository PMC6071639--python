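"""Readers and writers for the pipeline's plain-text dialects.

Matrices are TSV with the id in the first column and one column per
individual; genomic annotations are BED (0-based half-open) or simple TSV.
Every command writes a JSON manifest with input hashes, configuration and
seed so runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .evidence import AssayMatrix, FeatureTrack, GeneAnnotation, GenomicInterval
from .model import PvalueVector


class DataError(ValueError):
    """Malformed input data (reported with file and line context)."""


def read_assay_tsv(path: str | Path) -> AssayMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as err:  # pragma: no cover - pandas error text varies
        raise DataError(f"{path}: cannot parse TSV matrix: {err}") from err
    if df.shape[1] == 0:
        raise DataError(f"{path}: matrix has no individual columns")
    try:
        return AssayMatrix(df)
    except ValueError as err:
        raise DataError(f"{path}: {err}") from err


def write_assay_tsv(matrix: AssayMatrix, path: str | Path, index_label: str) -> None:
    matrix.data.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_feature_track(
    positions_path: str | Path, values_paths: Mapping[str, str | Path]
) -> FeatureTrack:
    """Feature positions TSV (feature_id, chrom, pos, kind) + per-kind value TSVs."""
    positions_path = Path(positions_path)
    table = pd.read_csv(positions_path, sep="\t", index_col=0)
    missing = {"chrom", "pos", "kind"} - set(table.columns)
    if missing:
        raise DataError(f"{positions_path}: missing columns {sorted(missing)}")
    frames = []
    for kind, vpath in values_paths.items():
        df = pd.read_csv(vpath, sep="\t", index_col=0)
        frames.append(df)
    values = pd.concat(frames)
    missing_ids = table.index.difference(values.index)
    if len(missing_ids):
        raise DataError(
            f"{positions_path}: {len(missing_ids)} feature(s) lack values, "
            f"e.g. {list(missing_ids[:3])}"
        )
    try:
        return FeatureTrack(table, values.loc[table.index])
    except ValueError as err:
        raise DataError(f"{positions_path}: {err}") from err


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Gene TSV (gene_id, chrom, tss, strand) or BED6 (TSS from strand-aware end)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t")
        genes = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                genes.append(
                    GeneAnnotation(str(row.gene_id), str(row.chrom), int(row.tss), str(row.strand))
                )
            except (ValueError, AttributeError) as err:
                raise DataError(f"{path}:{i}: {err}") from err
    else:
        genes = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise DataError(f"{path}:{i}: BED6 needs 6 columns, got {len(parts)}")
                chrom, start, end, name, _score, strand = parts[:6]
                try:
                    start, end = int(start), int(end)
                except ValueError as err:
                    raise DataError(f"{path}:{i}: non-integer coordinates") from err
                if start >= end:
                    raise DataError(f"{path}:{i}: start {start} >= end {end}")
                tss = start if strand == "+" else end - 1
                try:
                    genes.append(GeneAnnotation(name, chrom, tss, strand))
                except ValueError as err:
                    raise DataError(f"{path}:{i}: {err}") from err
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicate gene ids")
    return genes


def _parse_bed_line(path: Path, i: int, line: str, need_name: bool):
    parts = line.split("\t")
    if len(parts) < (4 if need_name else 3):
        raise DataError(
            f"{path}:{i}: expected at least {4 if need_name else 3} BED columns"
        )
    chrom = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as err:
        raise DataError(f"{path}:{i}: non-integer coordinates") from err
    if start >= end:
        raise DataError(f"{path}:{i}: start {start} >= end {end}")
    name = parts[3] if len(parts) > 3 else None
    score = None
    if len(parts) > 4 and parts[4] not in (".", ""):
        try:
            score = float(parts[4])
        except ValueError as err:
            raise DataError(f"{path}:{i}: non-numeric score {parts[4]!r}") from err
    return chrom, start, end, name, score


def read_peaks_bed(path: str | Path) -> dict[str, list[GenomicInterval]]:
    """ChIP peaks: one BED with the TF in column 4, or a directory of per-TF BEDs."""
    path = Path(path)
    peaks: dict[str, list[GenomicInterval]] = {}
    if path.is_dir():
        for bed in sorted(path.glob("*.bed")):
            tf = bed.stem
            peaks[tf] = []
            with open(bed) as fh:
                for i, line in enumerate(fh, start=1):
                    line = line.rstrip("\n")
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    chrom, start, end, _name, score = _parse_bed_line(
                        bed, i, line, need_name=False
                    )
                    peaks[tf].append(GenomicInterval(chrom, start, end, score=score))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, tf, score = _parse_bed_line(
                    path, i, line, need_name=True
                )
                peaks.setdefault(tf, []).append(
                    GenomicInterval(chrom, start, end, score=score)
                )
    return peaks


def read_exclusion_bed(path: str | Path) -> list[GenomicInterval]:
    """A plain BED3+ of regions to exclude (e.g. HOT regions)."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, _name, _score = _parse_bed_line(
                path, i, line, need_name=False
            )
            out.append(GenomicInterval(chrom, start, end))
    return out


def write_twas_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_twas_table(path: str | Path) -> dict[str, tuple[PvalueVector, pd.DataFrame]]:
    """TWAS TSV (gene_id, drug, beta, t, pvalue) -> per-drug p-value vectors."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "drug", "pvalue"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for drug, grp in df.groupby("drug", sort=True):
        out[str(drug)] = (
            PvalueVector(grp["pvalue"].to_numpy(), grp["gene_id"].to_numpy()),
            grp.reset_index(drop=True),
        )
    return out


def write_evidence_tsv(details: pd.DataFrame, matrices, path: str | Path) -> None:
    """Wide per-TF evidence table: gene, r and min-p per kind, minimising feature."""
    rows = []
    for tf, mat in matrices.items():
        det = details[details["tf"] == tf]
        lookup = {
            (r.gene_id, r.evidence): (r.min_pvalue, r.feature_id)
            for r in det.itertuples(index=False)
        }
        for gi, gene in enumerate(mat.gene_ids):
            row = {"tf": tf, "gene_id": gene}
            for ki, kind in enumerate(mat.evidence_names):
                row[f"r_{kind}"] = int(mat.entries[gi, ki])
                minp, fid = lookup.get((gene, kind), (np.nan, ""))
                row[f"min_p_{kind}"] = minp
                row[f"feature_{kind}"] = fid
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_evidence_tsv(path: str | Path):
    """Inverse of :func:`write_evidence_tsv`: per-TF EvidenceMatrix objects."""
    from .model import EvidenceMatrix

    df = pd.read_csv(path, sep="\t")
    kinds = tuple(
        c[len("r_"):] for c in df.columns if c.startswith("r_")
    )
    if not kinds:
        raise DataError(f"{path}: no evidence columns (r_*) found")
    out = {}
    for tf, grp in df.groupby("tf", sort=True):
        entries = grp[[f"r_{k}" for k in kinds]].to_numpy()
        out[str(tf)] = EvidenceMatrix(entries, grp["gene_id"].to_numpy(), kinds)
    return out


def write_association_table(table, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    inputs: Mapping[str, str | Path] | None = None,
    outputs: Mapping[str, str | Path] | None = None,
    seed: int | None = None,
) -> None:
    from . import __version__

    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (inputs or {}).items()
        },
        "outputs": {name: str(p) for name, p in (outputs or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
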
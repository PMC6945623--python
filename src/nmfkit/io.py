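"""Matrix readers/writers and run manifests.

Delimited files (CSV/TSV) may carry an optional header row and label
column, which are auto-detected and preserved through round trips.  Empty
cells and the markers NA/NaN mark unobserved entries.  MatrixMarket files
are read through scipy and are taken as fully observed unless a companion
observed-pattern file is supplied.  Files are 1-based and labeled;
in-memory indices are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

from .driver import FactorizationConfig, FactorizationResult, factorize
from .losses import TargetMatrix

__all__ = ["read_matrix", "write_matrix", "write_result",
           "read_manifest", "run_from_manifest"]

DEFAULT_MISSING = ("", "NA", "NaN", "nan", "N/A")

_SEPS = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("csv", "tsv", "mtx"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def _is_value(cell: str, missing: tuple[str, ...]) -> bool:
    cell = cell.strip()
    if cell in missing:
        return True
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_matrix(path, fmt: str | None = None,
                missing_markers: tuple[str, ...] = DEFAULT_MISSING,
                observed_path=None) -> TargetMatrix:
    """Read a non-negative matrix; unparseable-as-number markers become
    unobserved entries.  Negative values are rejected with their (1-based)
    coordinates.  For MTX input, ``observed_path`` may point to a 0/1
    matrix of the same shape marking the observed pattern."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        mat = mmread(path)  # sparse for coordinate files, ndarray for array files
        if hasattr(mat, "todense"):
            mat = mat.todense()
        values = np.asarray(mat, dtype=float)
        observed = None
        if observed_path is not None:
            obs = read_matrix(observed_path)
            observed = obs.filled.astype(bool)
        return TargetMatrix(values, observed)

    sep = "," if fmt == "csv" else "\t"
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                      keep_default_na=False, skip_blank_lines=True)
    cells = raw.to_numpy()
    if cells.size == 0:
        raise ValueError(f"{path}: empty file")
    # label sniffing: a header row / label column is one whose cells are
    # not parseable as numbers (the corner cell is ignored)
    has_header = not all(_is_value(c, missing_markers) for c in cells[0, 1:]) \
        if cells.shape[1] > 1 else not _is_value(cells[0, 0], missing_markers)
    first_col = cells[1:, 0] if has_header else cells[:, 0]
    has_index = cells.shape[1] > 1 and first_col.size > 0 and \
        not all(_is_value(c, missing_markers) for c in first_col)
    col_names = list(cells[0, 1 if has_index else 0:]) if has_header else None
    row_names = list(cells[1 if has_header else 0:, 0]) if has_index else None
    body = cells[1 if has_header else 0:, 1 if has_index else 0:]
    n, m = body.shape
    values = np.empty((n, m), dtype=float)
    marker_set = set(missing_markers)
    for i in range(n):
        for j in range(m):
            cell = body[i, j].strip()
            if cell in marker_set:
                values[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: cannot parse {cell!r} at row {i + 1}, "
                    f"column {j + 1}") from exc
            if np.isfinite(v) and v < 0:
                raise ValueError(
                    f"{path}: negative value {v} at row {i + 1}, column "
                    f"{j + 1}: the target matrix must be non-negative")
            values[i, j] = v
    return TargetMatrix(values, row_names=row_names, col_names=col_names)


def write_matrix(A, path, fmt: str | None = None,
                 missing_marker: str = "NA") -> None:
    """Write a TargetMatrix or plain array; unobserved entries become the
    missing marker.  The write -> read round trip is lossless for values
    and observed pattern."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if isinstance(A, TargetMatrix):
        values = np.where(A.observed, A.values, np.nan)
        row_names, col_names = A.row_names, A.col_names
    else:
        values = np.asarray(A, dtype=float)
        row_names = col_names = None
    if fmt == "mtx":
        if np.isnan(values).any():
            raise ValueError("MatrixMarket cannot carry missing entries; "
                             "write CSV/TSV or supply an observed-pattern file")
        mmwrite(str(path), np.asarray(values))
        return
    sep = "," if fmt == "csv" else "\t"
    df = pd.DataFrame(values, index=row_names, columns=col_names)
    df.to_csv(path, sep=sep, na_rep=missing_marker,
              index=row_names is not None, header=col_names is not None,
              float_format="%.17g")


def write_result(result: FactorizationResult, out_dir,
                 config: FactorizationConfig | None = None) -> dict:
    """Write W, H, the loss trace and a JSON run manifest to ``out_dir``.

    The manifest records every scalar config field (seed, algorithm, loss,
    penalty weights, tolerances) plus the run outcome, so a run without
    custom init/mask can be reproduced bit-for-bit from it.  Returns the
    mapping of artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "W": out / "W.tsv",
        "H": out / "H.tsv",
        "loss_trace": out / "loss_trace.tsv",
        "manifest": out / "manifest.json",
    }
    write_matrix(result.W, paths["W"])
    write_matrix(result.H, paths["H"])
    trace = pd.DataFrame({
        "epoch": np.arange(1, result.epochs_run + 1),
        "loss": result.loss_trace,
        "penalized_objective": result.objective_trace,
    })
    trace.to_csv(paths["loss_trace"], sep="\t", index=False)
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "epochs_run": result.epochs_run,
        "converged": result.converged,
        "final_rel_change": result.final_rel_change,
        "final_loss": result.final_loss,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def run_from_manifest(path, A: TargetMatrix) -> FactorizationResult:
    """Re-run the factorization described by a manifest on ``A``.

    Refuses manifests of runs that used a custom mask or initialization
    (those are not serialized)."""
    manifest = read_manifest(path)
    cd = manifest.get("config")
    if cd is None:
        raise ValueError("manifest carries no config")
    if cd.get("has_mask") or cd.get("has_init"):
        raise ValueError("manifest describes a run with a custom mask or "
                         "initialization, which is not serialized; rerun "
                         "through the API")
    return factorize(A, FactorizationConfig.from_dict(cd))
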
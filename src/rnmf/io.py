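"""Readers and writers for expression matrices and fitted models.

Supported table formats: plain TSV/CSV (first column = feature IDs, header
row = sample IDs) and GCT 1.2. Fitted models are written as labeled TSV
tables (components in strength order) plus a ``run.json`` with the complete
solver configuration, so every run is reproducible from its output folder.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    FactorModel,
    FitTrace,
    RegularizerSpec,
    SolverConfig,
)
from .solver import order_components

__all__ = [
    "read_expression",
    "write_expression",
    "write_model",
    "read_model",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".gct":
        return "gct"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def _validate_frame(df: pd.DataFrame, path: Path) -> ExpressionMatrix:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature ID {dup!r}")
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: missing values (ragged or unparseable rows)")
    values = df.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative value {values[i, j]:g} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r} "
            f"(NMF assumes an additive, non-negative model)"
        )
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def _read_gct(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n, m = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    elif df.shape[1] == m + 1:
        df = df.drop(columns=df.columns[0])
    if df.shape != (n, m):
        raise ValueError(
            f"{path}: GCT header declares {n} x {m} but body is "
            f"{df.shape[0]} x {df.shape[1]}"
        )
    return _validate_frame(df, path)


def read_expression(path, format: str = "auto") -> ExpressionMatrix:
    """Load a labeled non-negative expression matrix (TSV, CSV or GCT 1.2)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "gct":
        return _read_gct(path)
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    return _validate_frame(df, path)


def write_expression(em: ExpressionMatrix, path, format: str = "auto") -> None:
    """Write an expression matrix; round-trips through read_expression exactly."""
    path = Path(path)
    fmt = _detect_format(path, format)
    df = pd.DataFrame(em.values, index=em.row_ids, columns=em.col_ids)
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", em.row_ids)
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)
        return
    sep = "," if fmt == "csv" else "\t"
    df.index.name = "id"
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def write_model(
    model: FactorModel,
    trace: FitTrace,
    out_dir,
    row_ids=None,
    col_ids=None,
    config: SolverConfig | None = None,
    reg: RegularizerSpec | None = None,
    extra: dict | None = None,
) -> dict:
    """Write W.tsv, A.tsv, trace.tsv and run.json into ``out_dir``.

    Components are relabeled comp_1..comp_k in descending strength order
    (Euclidean norm of the base vector) in both tables. Returns the
    run-metadata dict that was written.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = order_components(model)
    k = model.n_components
    comp_names = [f"comp_{i + 1}" for i in range(k)]
    n, m = model.W.shape[0], model.A.shape[0]
    row_ids = list(row_ids) if row_ids is not None else [f"gene_{i+1}" for i in range(n)]
    col_ids = list(col_ids) if col_ids is not None else [f"sample_{j+1}" for j in range(m)]

    dfW = pd.DataFrame(model.W[:, order], index=row_ids, columns=comp_names)
    dfW.index.name = "id"
    dfW.to_csv(out / "W.tsv", sep="\t", float_format=_FLOAT_FMT)
    dfA = pd.DataFrame(model.A[:, order], index=col_ids, columns=comp_names)
    dfA.index.name = "id"
    dfA.to_csv(out / "A.tsv", sep="\t", float_format=_FLOAT_FMT)

    dft = pd.DataFrame(
        {
            "sweep": np.arange(1, trace.sweeps + 1),
            "objective": trace.objective,
            "kkt_w": trace.kkt_w,
            "kkt_a": trace.kkt_a,
            "sparsity_w": trace.sparsity_w,
        }
    )
    dft.to_csv(out / "trace.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    config = config if config is not None else SolverConfig(k=k, alpha=model.alpha)
    reg = reg if reg is not None else RegularizerSpec("none")
    meta = {
        "software": "rnmf",
        "version": __version__,
        "k": config.k,
        "alpha": config.alpha,
        "tau_a": config.tau_a,
        "tau_w": config.tau_w,
        "tol": config.tol,
        "max_iter": config.max_iter,
        "seed": config.seed,
        "init": config.init,
        "regularizer": reg.kind,
        "lam": reg.lam,
        "pairs": [list(p) for p in reg.pairs] if reg.pairs else None,
        "converged": bool(trace.converged),
        "objective_converged": bool(trace.objective_converged),
        "sweeps": int(trace.sweeps),
    }
    if extra:
        meta.update(extra)
    with open(out / "run.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return meta


def read_model(model_dir) -> tuple[FactorModel, dict]:
    """Read back a model written by :func:`write_model`."""
    model_dir = Path(model_dir)
    dfW = pd.read_csv(model_dir / "W.tsv", sep="\t", index_col=0, float_precision="round_trip")
    dfA = pd.read_csv(model_dir / "A.tsv", sep="\t", index_col=0, float_precision="round_trip")
    with open(model_dir / "run.json") as fh:
        meta = json.load(fh)
    model = FactorModel(dfW.to_numpy(float), dfA.to_numpy(float), meta["alpha"])
    return model, meta
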
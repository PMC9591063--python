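"""Reading and writing matrices, whitening models, and run outputs.

Delimited text (CSV/TSV/whitespace) is the canonical interchange format;
NumPy ``.npy`` is accepted as a simple binary container for large sample
sizes. On-disk orientation (channels in rows vs columns) is selectable and
normalized to channels-in-rows in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ordering import SeparationResult
from .preprocessing import SignalMatrix, WhiteningModel

__all__ = [
    "DataFormatError",
    "EmptyInputError",
    "RaggedMatrixError",
    "NonNumericError",
    "read_matrix",
    "write_matrix",
    "write_result",
    "read_result",
]


class DataFormatError(ValueError):
    """Base class for malformed input files."""


class EmptyInputError(DataFormatError):
    """The input file contains no data."""


class RaggedMatrixError(DataFormatError):
    """Rows of the input table have inconsistent lengths."""


class NonNumericError(DataFormatError):
    """The input table contains cells that do not parse as numbers."""


def _delimiter_for(path: Path, line: str) -> str | None:
    if path.suffix.lower() == ".csv" or "," in line:
        return ","
    if path.suffix.lower() == ".tsv" or "\t" in line:
        return "\t"
    return None  # any whitespace


def _load_text_table(path: Path) -> np.ndarray:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: no data found")
    delim = _delimiter_for(path, lines[0])
    rows = [ln.split(delim) if delim else ln.split() for ln in lines]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise RaggedMatrixError(
            f"{path}: rows have inconsistent lengths {sorted(widths)}"
        )
    try:
        return np.array(rows, dtype=float)
    except ValueError as exc:
        raise NonNumericError(f"{path}: non-numeric cell ({exc})") from exc


def read_matrix(path, orientation: str = "rows") -> SignalMatrix:
    """Read a signal matrix, normalizing to channels-in-rows.

    Parameters
    ----------
    path
        CSV/TSV/whitespace-delimited text, or ``.npy``.
    orientation
        ``"rows"`` if channels are rows on disk, ``"columns"`` if channels
        are columns (the table is transposed on read).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if orientation not in ("rows", "columns"):
        raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    if p.suffix.lower() == ".npy":
        arr = np.load(p)
        if arr.size == 0:
            raise EmptyInputError(f"{p}: empty array")
    else:
        arr = _load_text_table(p)
    if orientation == "columns":
        arr = arr.T
    return SignalMatrix(arr)


def write_matrix(arr, path) -> None:
    """Write a matrix as delimited text (delimiter chosen by extension)."""
    p = Path(path)
    data = arr.data if isinstance(arr, SignalMatrix) else np.asarray(arr, dtype=float)
    if p.suffix.lower() == ".npy":
        np.save(p, data)
        return
    delim = "\t" if p.suffix.lower() == ".tsv" else ","
    np.savetxt(p, np.atleast_2d(data), delimiter=delim, fmt="%.17g")


def write_whitening_model(model: WhiteningModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), sort_keys=True) + "\n")


def read_whitening_model(path) -> WhiteningModel:
    return WhiteningModel.from_dict(json.loads(Path(path).read_text()))


def write_result(result: SeparationResult, out_dir) -> None:
    """Write a separation result as delimited text plus JSON metadata.

    Produces ``W.csv`` (separating matrix, whitened space), ``A_est.csv``
    (mixing estimate in the original space), ``stats.csv`` (per-component
    kurtosis alpha and Upsilon(alpha)), ``meta.json``, and, when the run
    whitened internally, ``whitening.json``. Formatting is deterministic:
    identical results produce byte-identical files.
    """
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_matrix(result.w_matrix, d / "W.csv")
    write_matrix(result.mixing_estimate, d / "A_est.csv")
    stats = np.column_stack([result.alphas, result.upsilons])
    np.savetxt(
        d / "stats.csv",
        stats,
        delimiter=",",
        fmt="%.17g",
        header="alpha,upsilon",
        comments="",
    )
    (d / "meta.json").write_text(
        json.dumps(result.run_meta, sort_keys=True, indent=2) + "\n"
    )
    if result.whitening is not None:
        write_whitening_model(result.whitening, d / "whitening.json")


def read_result(run_dir) -> SeparationResult:
    """Read back a run directory written by :func:`write_result`."""
    d = Path(run_dir)
    w = _load_text_table(d / "W.csv")
    a_est = _load_text_table(d / "A_est.csv")
    stats = np.loadtxt(d / "stats.csv", delimiter=",", skiprows=1, ndmin=2)
    meta = json.loads((d / "meta.json").read_text())
    model = None
    if (d / "whitening.json").exists():
        model = read_whitening_model(d / "whitening.json")
    return SeparationResult(
        w_matrix=np.atleast_2d(w),
        alphas=stats[:, 0],
        upsilons=stats[:, 1],
        mixing_estimate=np.atleast_2d(a_est),
        run_meta=meta,
        whitening=model,
    )
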
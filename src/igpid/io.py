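"""Reading covariance/data tables and writing decomposition results.

Matrix files are headerless delimited text (comma or tab, sniffed), full
square, with block sizes always supplied separately so the format stays
unambiguous.  Data files are samples-as-rows tables with columns ordered
(X1 block, X2 block, X3 block).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import BlockSpec, PartitionedCovariance
from .decomposition import PIDResult, as_percentages

__all__ = [
    "read_matrix",
    "read_covariance",
    "read_data",
    "write_matrix",
    "result_to_dict",
    "write_results_json",
    "write_results_tsv",
]


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().lstrip().splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a headerless delimited numeric matrix (CSV or TSV)."""
    path = Path(path)
    frame = pd.read_csv(path, header=None, sep=_sniff_delimiter(path))
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"malformed matrix in {path}: non-numeric or ragged rows")
    return values


def read_covariance(path: str | Path, blocks: BlockSpec) -> PartitionedCovariance:
    """Read a covariance matrix and attach the block specification."""
    sigma = read_matrix(path)
    if sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"covariance in {path} is not square: {sigma.shape}")
    return PartitionedCovariance(sigma=sigma, blocks=blocks)


def read_data(path: str | Path, blocks: BlockSpec) -> np.ndarray:
    """Read a samples x variables table and check it conforms to the blocks."""
    data = read_matrix(path)
    if data.shape[1] != blocks.m:
        raise ValueError(
            f"block sizes do not match matrix dimension: data has {data.shape[1]} "
            f"columns, blocks sum to {blocks.m}"
        )
    return data


def write_matrix(path: str | Path, matrix: np.ndarray) -> None:
    """Write a matrix as headerless CSV at full double precision."""
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt="%.17g")


def result_to_dict(res: PIDResult) -> dict[str, Any]:
    """JSON-ready representation of a decomposition result."""
    unq1, unq2, shd, syn = as_percentages(res) if res.mi.joint > 0 else (0.0,) * 4
    diagnostics = {
        k: v for k, v in res.diagnostics.items() if k in ("at_endpoint", "feasible_interval", "degenerate")
    }
    residuals = res.diagnostics.get("residuals")
    if residuals:
        diagnostics["residuals"] = {k: float(v) for k, v in residuals.items()}
    return {
        "method": res.method,
        "units": res.units,
        "components": {k: float(v) for k, v in res.components.items()},
        "percentages": {"unq1": unq1, "unq2": unq2, "shd": shd, "syn": syn},
        "t_star": res.t_star,
        "mi": {
            "i13": res.mi.i13,
            "i23": res.mi.i23,
            "cond13": res.mi.i13_given_2,
            "cond23": res.mi.i23_given_1,
            "joint": res.mi.joint,
            "interaction": res.mi.interaction,
        },
        "diagnostics": diagnostics,
    }


def write_results_json(path: str | Path, results: list[PIDResult]) -> None:
    Path(path).write_text(json.dumps([result_to_dict(r) for r in results], indent=2) + "\n")


_TSV_COLUMNS = (
    "method", "units", "syn", "unq1", "unq2", "shd",
    "pct_unq1", "pct_unq2", "pct_shd", "pct_syn", "t_star", "joint_mi",
)


def write_results_tsv(path: str | Path, results: list[PIDResult]) -> None:
    """Flat one-row-per-method table for batch runs."""
    rows = []
    for res in results:
        d = result_to_dict(res)
        rows.append({
            "method": d["method"],
            "units": d["units"],
            **{k: d["components"][k] for k in ("syn", "unq1", "unq2", "shd")},
            **{f"pct_{k}": v for k, v in d["percentages"].items()},
            "t_star": d["t_star"] if d["t_star"] is not None else "",
            "joint_mi": d["mi"]["joint"],
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
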
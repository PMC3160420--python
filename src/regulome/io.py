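"""Reading and writing regulome matrices as TSV layers plus metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import CountMatrix, RegulomeMatrix

LAYERS = ("observed", "expected", "variance", "z", "p_over", "p_under")

__all__ = ["write_regulome", "read_regulome"]


def _frame(matrix: RegulomeMatrix, values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(values, index=matrix.row_names, columns=matrix.col_names)


def write_regulome(matrix: RegulomeMatrix, out_dir: str | Path) -> Path:
    """One TSV per layer (rows = TFs, columns = diseases) + metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for layer in LAYERS:
        values = getattr(matrix, layer) if layer != "observed" else matrix.counts.observed
        _frame(matrix, values).to_csv(out / f"{layer}.tsv", sep="\t", index_label="tf")
    if matrix.sig_over is not None:
        flags = np.where(matrix.sig_over, "over", np.where(matrix.sig_under, "under", "-"))
        _frame(matrix, flags).to_csv(out / "flags.tsv", sep="\t", index_label="tf")
    meta = {
        "null_model": matrix.null_model,
        "mode": matrix.counts.mode,
        "alpha": matrix.alpha,
        "correction": matrix.correction,
        "N": int(matrix.counts.N),
        "n_t": {t: int(v) for t, v in zip(matrix.row_names, matrix.counts.n_t)},
        "m_d": {d: int(v) for d, v in zip(matrix.col_names, matrix.counts.m_d)},
        **{k: v for k, v in matrix.meta.items() if k != "N"},
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out


def read_regulome(in_dir: str | Path) -> RegulomeMatrix:
    """Load a regulome previously written by :func:`write_regulome`."""
    src = Path(in_dir)
    meta = json.loads((src / "metadata.json").read_text())
    frames = {
        layer: pd.read_csv(src / f"{layer}.tsv", sep="\t", index_col="tf")
        for layer in LAYERS
    }
    obs = frames["observed"]
    row_names = [str(r) for r in obs.index]
    col_names = [str(c) for c in obs.columns]
    counts = CountMatrix(
        row_names,
        col_names,
        obs.to_numpy(dtype=np.int64),
        np.array([meta["n_t"][t] for t in row_names], dtype=np.int64),
        int(meta["N"]),
        np.array([meta["m_d"][d] for d in col_names], dtype=np.int64),
        meta["mode"],
    )
    matrix = RegulomeMatrix(
        counts,
        meta["null_model"],
        frames["expected"].to_numpy(float),
        frames["variance"].to_numpy(float),
        frames["z"].to_numpy(float),
        frames["p_over"].to_numpy(float),
        frames["p_under"].to_numpy(float),
        alpha=meta.get("alpha"),
        correction=meta.get("correction"),
        meta={k: meta[k] for k in meta if k not in ("n_t", "m_d")},
    )
    flags_path = src / "flags.tsv"
    if flags_path.exists():
        flags = pd.read_csv(flags_path, sep="\t", index_col="tf")
        matrix.sig_over = (flags == "over").to_numpy()
        matrix.sig_under = (flags == "under").to_numpy()
    return matrix
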
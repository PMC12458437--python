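"""Readers and writers for the tabular interchange formats.

All formats are plain text: a taxa-by-sample count matrix (TSV or CSV,
first column taxon id), sample metadata (``sample_id``, ``condition``),
per-sample loads (``sample_id``, ``value``, optional ``modality``),
one-identifier-per-line feature lists, and result tables. Loads may be
supplied on a linear, log10 or log2 scale and are converted to the caller's
requested internal scale (log2 inside the engine, log10 for prediction
metrics). Every CLI run also writes a JSON manifest with the resolved
parameters, package version and input checksums, sufficient to re-run the
command exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CountTable, SimulationConfig, SyntheticDataset

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_loads",
    "write_loads",
    "read_feature_list",
    "read_method_results",
    "write_dataset",
    "write_manifest",
]

_LOG2_PER_LOG10 = np.log2(10.0)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", index_col=0)
    except Exception as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"empty table: {path}")
    return df


def read_count_table(path: str | Path) -> CountTable:
    """Read a taxa-by-sample count matrix (TSV or CSV, ``#`` comments).

    Rows are taxa (first column the identifier), columns are samples.
    Duplicate identifiers, negative cells and non-integer cells are
    rejected with coordinates.
    """
    df = _read_table(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(counts=df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.Series:
    """Read sample metadata with columns ``sample_id`` and ``condition``."""
    df = _read_table(path).reset_index()
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "condition" not in cols:
        raise ValueError(f"metadata {path} must have columns sample_id and condition")
    cond = pd.Series(
        df[cols["condition"]].to_numpy(),
        index=df[cols["sample_id"]].astype(str),
        name="condition",
    )
    if cond.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in metadata {path}")
    if not set(pd.unique(cond)) <= {0, 1}:
        raise ValueError("condition must be binary (0/1)")
    return cond.astype(np.int64)


def write_metadata(condition: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": condition.index, "condition": condition.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_loads(
    path: str | Path,
    scale: str = "log2",
    input_scale: str | None = None,
    value_column: str = "value",
) -> pd.Series:
    """Read per-sample loads and convert them to the requested scale.

    The file needs columns ``sample_id`` and ``value`` (configurable), with
    an optional ``scale`` column or ``input_scale`` argument declaring the
    scale the values are on (``linear``, ``log10`` or ``log2``; default
    ``linear``). ``scale`` is the internal scale to convert to. Non-positive
    linear values are rejected.
    """
    if scale not in ("linear", "log10", "log2"):
        raise ValueError("scale must be linear, log10 or log2")
    df = _read_table(path).reset_index()
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValueError(f"loads file {path} must have a sample_id column")
    vcol = cols.get(value_column.lower())
    if vcol is None:
        raise ValueError(f"loads file {path} has no column {value_column!r}")
    values = df[vcol].to_numpy(dtype=float)
    ids = df[cols["sample_id"]].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate sample ids in loads file {path}")

    declared = input_scale
    if declared is None and "scale" in cols:
        uniq = set(df[cols["scale"]].astype(str).str.lower())
        if len(uniq) > 1:
            raise ValueError(f"mixed scale declarations in {path}: {sorted(uniq)}")
        declared = uniq.pop()
    declared = declared or "linear"
    if declared not in ("linear", "log10", "log2"):
        raise ValueError(f"unknown input scale {declared!r}")

    if declared == "linear":
        if np.any(values <= 0):
            bad = ids[values <= 0].tolist()
            raise ValueError(f"non-positive linear load for samples {bad}; log undefined")
        log2_vals = np.log2(values)
    elif declared == "log10":
        log2_vals = values * _LOG2_PER_LOG10
    else:
        log2_vals = values

    if scale == "log2":
        out = log2_vals
    elif scale == "log10":
        out = log2_vals / _LOG2_PER_LOG10
    else:
        out = np.exp2(log2_vals)
    return pd.Series(out, index=pd.Index(ids, name="sample_id"), name=f"load_{scale}")


def write_loads(dataset: SyntheticDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": dataset.samples,
            "log2_true": dataset.true_loads_log2.to_numpy(),
            "log2_measured": dataset.measured_loads_log2.to_numpy(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_list(path: str | Path) -> list[str]:
    """Read a plain-text feature list, one identifier per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    features = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not features:
        raise ValueError(f"empty feature list: {path}")
    return features


def read_method_results(path: str | Path, alpha: float = 0.05):
    """Read an external tool's exported results for scoring.

    Expects columns ``taxon``, ``direction`` (``+``/``-``/``0``) and
    ``p_adj``. Returns a :class:`~sridiff.engine.DAResult` usable by
    :func:`~sridiff.benchmark.score_against_truth`; theta columns are NaN
    since the external tool's effect sizes are not on the engine's scale.
    """
    from .engine import DAResult  # local import to avoid a cycle

    df = _read_table(path).reset_index()
    cols = {c.lower(): c for c in df.columns}
    for required in ("taxon", "direction", "p_adj"):
        if required not in cols:
            raise ValueError(f"results file {path} must have a {required} column")
    p_adj = df[cols["p_adj"]].to_numpy(dtype=float)
    if np.any((p_adj < 0) | (p_adj > 1)):
        raise ValueError("p_adj values must lie in [0, 1]")
    direction = df[cols["direction"]].astype(str)
    if not set(direction) <= {"+", "-", "0"}:
        raise ValueError("direction must be one of +, -, 0")
    table = pd.DataFrame(
        {
            "theta": np.nan,
            "theta_par": np.nan,
            "theta_perp": np.nan,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "direction": direction.to_numpy(),
        },
        index=pd.Index(df[cols["taxon"]].astype(str), name="taxon"),
    )
    return DAResult(
        table=table,
        alpha=alpha,
        n_replicates=0,
        scale_model="external-tool",
        seed=-1,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write counts, metadata and loads TSVs for a synthetic dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "loads": outdir / "loads.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_count_table(dataset.counts, paths["counts"])
    write_metadata(dataset.counts.condition, paths["metadata"])
    write_loads(dataset, paths["loads"])
    pd.DataFrame(
        {
            "taxon": dataset.taxa,
            "true_effect_log2": dataset.true_effects_log2.to_numpy(),
            "truth_flag": dataset.truth_flags.to_numpy(),
        }
    ).to_csv(paths["truth"], sep="\t", index=False, float_format="%.12g")
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    params: dict,
    input_paths: dict[str, str | Path] | None = None,
) -> Path:
    """Write a JSON manifest that makes the run exactly reproducible."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "sridiff",
        "version": __version__,
        "command": command,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (input_paths or {}).items()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a parsed config-file mapping."""
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
    return SimulationConfig(**d)
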
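"""Tabular I/O, run configuration and manifests.

All matrices travel as TSV with a header row of sample / cell-type ids
and a first column of gene ids; gene weights as a two-column TSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gene_weights",
    "write_gene_weights",
    "RunConfig",
    "load_config",
    "write_manifest",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a genes-x-columns TSV matrix; errors name the file and line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas already reports the line where possible
        raise ValueError(f"{path}: failed to parse TSV ({exc})") from exc
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbers
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in "
                f"column {col!r} at line {line}"
            )
        df[col] = converted
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    """Write a matrix TSV; round-trips through read_matrix_tsv to 1e-12."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_weights(path) -> pd.Series:
    df = read_matrix_tsv(path)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: gene-weight file must have exactly one "
                         f"value column, found {df.shape[1]}")
    return df.iloc[:, 0]


def write_gene_weights(weights, gene_ids, path) -> None:
    s = pd.Series(np.asarray(weights, dtype=float), index=list(gene_ids),
                  name="weight")
    s.index.name = "gene_id"
    write_matrix_tsv(s.to_frame(), path)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Simulation defaults follow the reference study conditions: 5000
    mixtures of 100 cells, ~15% hidden cells, regulation factors from
    {-1, -0.5, 1, 2} on 30 specific plus 30 unspecific genes, and
    penalties lambda1 = 0.1, lambda2 = 1e-8.
    """

    # hyperparameters
    lambda1: float = 0.1
    lambda2: float = 1e-8
    max_iter: int = 1000
    tol: float = 1e-7
    # simulation block
    p: int = 1000
    q: int = 6
    n: int = 5000
    n_train: int = 5000
    cells_per_mixture: int = 100
    cells_per_type: int = 100
    hidden_fraction: float = 0.15
    separation: float = 4.0
    noise_dispersion: float = 0.5
    type_jitter: float = 1.5
    housekeeping_fraction: float = 0.2
    n_specific: int = 30
    n_unspecific: int = 30
    top_per_type: int = 20
    unspecific_pool_size: int = 120
    factors: tuple = (-1.0, -0.5, 1.0, 2.0)
    # bookkeeping
    seed: int = 0
    out_dir: str = "adtd_run"
    # optional explicit inputs (skip simulation when all given)
    reference: str | None = None
    bulks: str | None = None
    compositions: str | None = None
    weights: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["factors"] = list(self.factors)
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "factors" in raw:
        raw["factors"] = tuple(float(a) for a in raw["factors"])
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Record config, its hash, seed and library versions next to artifacts."""
    import scipy
    import sklearn

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "adtd": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
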
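"""TSV input/output, run manifests and fixture generation.

Payoff matrices and mutation kernels travel as tab-separated tables with a
header row of strategy labels and a leading label column.  Kernel rows are
validated as stochastic (tolerance 1e-9) and strongly connected on load.
Stationary distributions are written as two-column TSV with 12 significant
digits.  Every CLI invocation writes a JSON manifest (command, parameters,
seed, package version, timestamp) alongside its outputs so results are
reproducible from the manifest alone.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MutationKernel, PayoffMatrix, StationaryDistribution

__all__ = [
    "load_payoff_matrix",
    "load_kernel",
    "save_matrix",
    "save_stationary",
    "write_manifest",
    "make_fixtures",
]


def _read_table(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = tuple(str(c) for c in df.columns)
    row_labels = tuple(str(r) for r in df.index)
    if labels != row_labels:
        raise ValueError(
            f"{path}: row labels {row_labels} do not match column labels {labels}"
        )
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: table contains non-finite values")
    return values, labels


def load_payoff_matrix(path: str | Path) -> PayoffMatrix:
    """Read a payoff matrix from labelled TSV."""
    values, labels = _read_table(path)
    return PayoffMatrix(values=values, labels=labels)


def load_kernel(path: str | Path, rate: float | None = None) -> MutationKernel:
    """Read and validate a mutation kernel from labelled TSV.

    Row stochasticity (1e-9) and strong connectivity of the off-diagonal
    support are enforced; errors name the offending row.
    """
    values, labels = _read_table(path)
    return MutationKernel(matrix=values, labels=labels, rate=rate)


def save_matrix(
    obj: PayoffMatrix | MutationKernel, path: str | Path
) -> None:
    """Write a payoff matrix or kernel as labelled TSV at full precision."""
    values = obj.values if isinstance(obj, PayoffMatrix) else obj.matrix
    df = pd.DataFrame(values, index=list(obj.labels), columns=list(obj.labels))
    df.to_csv(path, sep="\t", float_format="%.17g")


def save_stationary(dist: StationaryDistribution, path: str | Path) -> None:
    """Write a stationary distribution as two-column TSV (12 significant digits)."""
    df = pd.DataFrame({"strategy": dist.labels, "probability": dist.pi})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_manifest(
    out_path: str | Path, command: str, params: dict, seed: int | None = None
) -> Path:
    """Write a JSON manifest next to an output file."""
    from . import __version__

    out_path = Path(out_path)
    manifest = {
        "command": command,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    return v


def make_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Generate seeded random games and connected kernels for property suites.

    Writes payoff matrices of sizes 2..8 (entries in [0, 10]) and matching
    random connected kernels; the same seed reproduces the identical set.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for n in range(2, 9):
        labels = tuple(f"S{i}" for i in range(n))
        game = PayoffMatrix(values=rng.uniform(0, 10, size=(n, n)), labels=labels)
        gpath = out_dir / f"game_{n}.tsv"
        save_matrix(game, gpath)
        written.append(gpath)

        mu = float(rng.uniform(0.01, 0.2))
        weights = rng.uniform(0.1, 1.0, size=(n, n))
        np.fill_diagonal(weights, 0.0)
        M = mu * weights / weights.sum(axis=1, keepdims=True)
        np.fill_diagonal(M, 1.0 - M.sum(axis=1))
        kernel = MutationKernel(matrix=M, labels=labels, rate=mu)
        kpath = out_dir / f"kernel_{n}.tsv"
        save_matrix(kernel, kpath)
        written.append(kpath)
    return written
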
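"""File formats: YAML network specs, CSV snapshots, TSV edge lists.

The canonical network spec is a YAML document with a ``genes`` list (one
kinetics block per gene) and optional ``theta`` / ``hill_m`` / ``hill_s``
matrices, row-major with row index = regulated gene and column = regulator.
Snapshots are cells × genes CSV with a header row of gene names; missing
values are empty fields (or a configurable sentinel) and become the mask.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .data import SnapshotData
from .network import (
    DEFAULT_HILL_COEF,
    DEFAULT_HILL_THRESHOLD,
    GeneKinetics,
    InteractionParams,
    NetworkModel,
)

__all__ = [
    "read_network_spec",
    "write_network_spec",
    "read_snapshot_csv",
    "write_snapshot_csv",
    "edge_list",
    "write_edge_list",
]

_KINETIC_FIELDS = ("k0", "k1", "koff", "d0", "d1", "s0", "s1")


def read_network_spec(path) -> NetworkModel:
    """Parse and validate a YAML network spec into a :class:`NetworkModel`.

    Collects *all* violated invariants into one error message rather than
    stopping at the first.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "genes" not in doc:
        raise ValueError(f"{path}: spec must be a mapping with a 'genes' list")
    problems: list[str] = []
    genes = doc["genes"]
    if not isinstance(genes, list) or not genes:
        raise ValueError(f"{path}: 'genes' must be a non-empty list")
    n = len(genes)
    kinetics, names = [], []
    for idx, g in enumerate(genes):
        name = g.get("name", f"gene{idx + 1}")
        names.append(str(name))
        missing = [f for f in ("k0", "k1", "koff", "d0", "d1") if f not in g]
        if missing:
            problems.append(f"gene {name}: missing fields {missing}")
            continue
        try:
            kinetics.append(GeneKinetics(**{f: float(g[f]) for f in _KINETIC_FIELDS if f in g}))
        except (ValueError, TypeError) as exc:
            problems.append(f"gene {name}: {exc}")

    def matrix(key: str, default: float) -> np.ndarray:
        if key not in doc:
            return np.full((n, n), default)
        arr = np.asarray(doc[key], dtype=float)
        if arr.shape != (n, n):
            problems.append(f"{key}: expected {n}x{n} matrix, got shape {arr.shape}")
            return np.full((n, n), default)
        return arr

    theta = matrix("theta", 0.0)
    hill_m = matrix("hill_m", DEFAULT_HILL_COEF)
    hill_s = matrix("hill_s", DEFAULT_HILL_THRESHOLD)
    form = doc.get("interaction_form", "chromatin_hill")
    if problems:
        raise ValueError(f"{path}: invalid network spec:\n  " + "\n  ".join(problems))
    try:
        interactions = InteractionParams(theta=theta, hill_m=hill_m, hill_s=hill_s)
        return NetworkModel(
            kinetics=tuple(kinetics),
            interactions=interactions,
            interaction_form=form,
            gene_names=tuple(names),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: invalid network spec: {exc}") from exc


def write_network_spec(model: NetworkModel, path) -> None:
    doc = {
        "genes": [
            {"name": name, **{f: float(getattr(kin, f)) for f in _KINETIC_FIELDS}}
            for name, kin in zip(model.gene_names, model.kinetics)
        ],
        "theta": model.interactions.theta.tolist(),
        "hill_m": model.interactions.hill_m.tolist(),
        "hill_s": model.interactions.hill_s.tolist(),
        "interaction_form": model.interaction_form,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_hash(path) -> str:
    """Short content hash of a spec file, for output provenance headers."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def write_snapshot_csv(data: SnapshotData, path, missing_sentinel: str = "") -> None:
    """Write cells × genes CSV; masked entries become the sentinel/empty."""
    df = pd.DataFrame(data.X, columns=list(data.gene_names))
    df = df.mask(~data.mask, other=np.nan)
    df.to_csv(path, index=False, na_rep=missing_sentinel)


def read_snapshot_csv(path, missing_sentinel: str = "", rescale: bool = False) -> SnapshotData:
    """Read a snapshot CSV; empty/sentinel fields become masked entries.

    Values must lie on the normalized [0, 1] scale; columns exceeding 1
    are rejected unless ``rescale`` is set, in which case they are divided
    by their column maximum (a crude count-normalization hook, off by
    default and announced with a warning).
    """
    na = [missing_sentinel] if missing_sentinel else None
    df = pd.read_csv(path, na_values=na, keep_default_na=True)
    X = df.to_numpy(dtype=float)
    mask = ~np.isnan(X)
    over = np.nanmax(X, axis=0) > 1.0
    if np.any(over):
        cols = [c for c, o in zip(df.columns, over) if o]
        if rescale:
            warnings.warn(f"rescaling columns {cols} by their maxima", stacklevel=2)
            colmax = np.nanmax(X, axis=0)
            X = X / np.where(over, colmax, 1.0)
        else:
            raise ValueError(
                f"{path}: columns {cols} contain values > 1; pass rescale=True to "
                "normalize by column maxima or pre-normalize the data"
            )
    X = np.where(mask, X, 0.0)
    return SnapshotData(X=X, mask=mask, gene_names=list(df.columns))


def edge_list(model: NetworkModel, zero_tol: float = 0.0) -> pd.DataFrame:
    """Directed edges (source regulator j → target gene i) with θ and sign."""
    theta = model.interactions.theta
    rows = []
    for i in range(model.n):
        for j in range(model.n):
            if i == j or abs(theta[i, j]) <= zero_tol:
                continue
            rows.append(
                {
                    "source": model.gene_names[j],
                    "target": model.gene_names[i],
                    "theta": theta[i, j],
                    "sign": int(np.sign(theta[i, j])),
                }
            )
    return pd.DataFrame(rows, columns=["source", "target", "theta", "sign"])


def write_edge_list(model: NetworkModel, path, zero_tol: float = 0.0) -> None:
    edge_list(model, zero_tol).to_csv(path, sep="\t", index=False)
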
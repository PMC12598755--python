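"""CSV/JSON input-output helpers.

All tables are RFC-4180 CSV, UTF-8, with a header row.  Connectivity
matrices are stored in long format (id, node_i, node_j, r) over the upper
triangle; the parcellation is a two-column (node_id, network_label) table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import Parcellation
from .synthetic import Cohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_features",
    "read_features",
    "write_parcellation",
    "read_parcellation",
    "write_connectivity_long",
    "read_connectivity_long",
]


def write_cohort(cohort: Cohort | pd.DataFrame, path: str | Path) -> None:
    table = cohort.table if isinstance(cohort, Cohort) else cohort
    table.to_csv(path, index=False)


def read_cohort(path: str | Path, seed: int = 0) -> Cohort:
    return Cohort(table=pd.read_csv(path), rng_seed=seed)


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    pd.DataFrame(
        {"node_id": parcellation.node_ids, "network_label": parcellation.labels}
    ).to_csv(path, index=False)


def read_parcellation(path: str | Path) -> Parcellation:
    frame = pd.read_csv(path)
    return Parcellation(
        node_ids=tuple(frame["node_id"].astype(str)),
        labels=tuple(frame["network_label"].astype(str)),
    )


def write_connectivity_long(
    matrices: dict[str, np.ndarray], path: str | Path
) -> None:
    frames = []
    for pid, mat in matrices.items():
        iu, ju = np.triu_indices(mat.shape[0], k=1)
        frames.append(
            pd.DataFrame(
                {"id": pid, "node_i": iu, "node_j": ju, "r": mat[iu, ju]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_connectivity_long(path: str | Path) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path)
    n = int(max(frame["node_i"].max(), frame["node_j"].max())) + 1
    out: dict[str, np.ndarray] = {}
    for pid, grp in frame.groupby("id", sort=False):
        mat = np.eye(n)
        mat[grp["node_i"], grp["node_j"]] = grp["r"]
        mat[grp["node_j"], grp["node_i"]] = grp["r"]
        out[str(pid)] = mat
    return out
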
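"""Plain-text readers/writers for connectomes, parcellations and results.

Connectomes travel as tab-separated square matrices with a node-id header
row and index column; parcellations and cohort manifests as tab-separated
tables; criticality profiles as a TSV of per-threshold curves plus a JSON
sidecar of scalar indexes.  State trajectories may optionally be persisted
to HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from neurocrit.connectome import RawConnectome
from neurocrit.dynamics import CriticalityProfile
from neurocrit.synthetic import Parcellation

PathLike = Union[str, Path]


def write_matrix_tsv(path: PathLike, W: np.ndarray, node_ids=None) -> None:
    n = W.shape[0]
    ids = np.arange(n) if node_ids is None else node_ids
    pd.DataFrame(W, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix_tsv(path: PathLike) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy()


def write_parcellation_tsv(path: PathLike, parc: Parcellation) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False)


def read_parcellation_tsv(path: PathLike) -> Parcellation:
    return Parcellation.from_frame(pd.read_csv(path, sep="\t"))


def write_connectome(
    path: PathLike, conn: RawConnectome, parcellation_path: Optional[PathLike] = None
) -> None:
    write_matrix_tsv(path, conn.W, conn.parcellation.node_id)
    if parcellation_path is not None:
        write_parcellation_tsv(parcellation_path, conn.parcellation)


def read_connectome(
    path: PathLike,
    parcellation: Union[Parcellation, PathLike],
    subject_id: str = "unknown",
    timepoint: str = "t1",
) -> RawConnectome:
    if not isinstance(parcellation, Parcellation):
        parcellation = read_parcellation_tsv(parcellation)
    W = read_matrix_tsv(path).astype(np.int64)
    return RawConnectome(
        W=W, parcellation=parcellation, subject_id=subject_id, timepoint=timepoint
    )


def write_profile(path: PathLike, profile: CriticalityProfile) -> None:
    """Write the per-threshold curves as TSV plus a JSON sidecar of indexes."""
    path = Path(path)
    pd.DataFrame(
        {
            "T": profile.T_grid,
            "mean_A": profile.mean_A,
            "sd_A": profile.sd_A,
            "S1": profile.S1,
            "S2": profile.S2,
        }
    ).to_csv(path, sep="\t", index=False)
    sidecar = {
        "subject_id": profile.subject_id,
        "timepoint": profile.timepoint,
        "n_nodes": profile.n_nodes,
        "T_c": None if np.isnan(profile.T_c) else profile.T_c,
        "I1": profile.I1,
        "I2": profile.I2,
        "monotonic_s2": bool(profile.monotonic_s2),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_profile(path: PathLike) -> CriticalityProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    profile = CriticalityProfile(
        T_grid=df["T"].to_numpy(),
        mean_A=df["mean_A"].to_numpy(),
        sd_A=df["sd_A"].to_numpy(),
        S1=df["S1"].to_numpy(),
        S2=df["S2"].to_numpy(),
    )
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        profile.T_c = meta["T_c"] if meta["T_c"] is not None else float("nan")
        profile.I1 = meta["I1"]
        profile.I2 = meta["I2"]
        profile.monotonic_s2 = meta["monotonic_s2"]
        profile.subject_id = meta.get("subject_id", "unknown")
        profile.timepoint = meta.get("timepoint", "t1")
        profile.n_nodes = meta.get("n_nodes", 0)
    return profile


def write_trajectory_h5(path: PathLike, states: np.ndarray, **attrs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("states", data=states.astype(np.uint8))
        for key, value in attrs.items():
            d.attrs[key] = value


def read_trajectory_h5(path: PathLike) -> tuple[np.ndarray, dict]:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["states"]
        return d[...], dict(d.attrs)


def write_manifest(path: PathLike, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
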
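"""On-disk formats: HDF5 recording corpora and CSV tables.

A corpus file holds one group per material with one subgroup per trial
(``material_<id>/trial_<j>/touch|slide`` cell-trace arrays) and the
simulation config as root attributes. Tabular artifacts (material
manifest, decision matrices, histograms, evaluation reports) are plain
CSV via pandas.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .psychophysics import DecisionMatrix
from .simulator import Recording, SimulationConfig

__all__ = [
    "write_corpus",
    "read_corpus",
    "write_manifest",
    "read_manifest",
    "write_decision_matrices",
    "read_decision_matrices",
    "write_histograms",
]


def write_corpus(
    path, recordings: Iterable[Recording], config: SimulationConfig
) -> int:
    """Write recordings to an HDF5 corpus file; returns the count written."""
    n = 0
    trial_counter: dict[int, int] = {}
    with h5py.File(path, "w") as f:
        for key, value in asdict(config).items():
            f.attrs[key] = value
        for rec in recordings:
            trial = trial_counter.get(rec.material_id, 0)
            trial_counter[rec.material_id] = trial + 1
            grp = f.require_group(f"material_{rec.material_id:03d}").create_group(
                f"trial_{trial:04d}"
            )
            grp.create_dataset("touch", data=rec.touch_traces, compression="gzip")
            grp.create_dataset("slide", data=rec.slide_traces, compression="gzip")
            grp.attrs["material_id"] = rec.material_id
            grp.attrs["contact_force_n"] = rec.contact_force_n
            grp.attrs["sliding_velocity_cm_s"] = rec.sliding_velocity_cm_s
            grp.attrs["sample_rate"] = rec.sample_rate
            n += 1
    return n


def read_corpus(path) -> tuple[list[Recording], SimulationConfig]:
    """Read a corpus file back into recordings + its config."""
    recordings = []
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        config = SimulationConfig(
            **{k: type(getattr(SimulationConfig, k))(v) for k, v in attrs.items()}
        )
        for mat_key in sorted(f.keys()):
            for trial_key in sorted(f[mat_key].keys()):
                grp = f[mat_key][trial_key]
                recordings.append(
                    Recording(
                        material_id=int(grp.attrs["material_id"]),
                        touch_traces=grp["touch"][()],
                        slide_traces=grp["slide"][()],
                        contact_force_n=float(grp.attrs["contact_force_n"]),
                        sliding_velocity_cm_s=float(
                            grp.attrs["sliding_velocity_cm_s"]
                        ),
                        sample_rate=float(grp.attrs["sample_rate"]),
                    )
                )
    return recordings, config


def write_manifest(path, library) -> None:
    from .simulator import material_manifest

    material_manifest(library).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_decision_matrices(path, matrices: Sequence[DecisionMatrix]) -> None:
    """Long-format CSV: participant, trial, material, rank."""
    rows = []
    for mx in matrices:
        for i in range(mx.n_trials):
            for m in range(mx.n_materials):
                rows.append(
                    {
                        "participant": mx.participant_id,
                        "trial": i,
                        "material": m + 1,
                        "rank": int(mx.ranks[i, m]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decision_matrices(path) -> list[DecisionMatrix]:
    df = pd.read_csv(path)
    matrices = []
    for pid, sub in df.groupby("participant", sort=True):
        wide = sub.pivot(index="trial", columns="material", values="rank")
        matrices.append(
            DecisionMatrix(
                participant_id=int(pid),
                ranks=wide.sort_index().to_numpy(dtype=int),
            )
        )
    return matrices


def write_histograms(path, histograms: np.ndarray) -> None:
    """Wide CSV of per-material histograms: rows material, columns rank."""
    m = histograms.shape[1]
    df = pd.DataFrame(
        histograms,
        index=pd.RangeIndex(1, histograms.shape[0] + 1, name="material"),
        columns=[f"rank_{r}" for r in range(1, m + 1)],
    )
    df.to_csv(path)
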
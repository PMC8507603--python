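"""On-disk container formats and the external-trajectory adapter.

Native trajectories are HDF5 files with the layout

    /frames/time        (T,)      ps
    /frames/com         (T, 3)    nm
    /frames/quaternion  (T, 4)    x, y, z, w
    /frames/lipid_xy    (T, N, 2) nm (explicit-lipid mode only)
    /body/...           bead positions, charges, labels
    /meta               composition, params, metadata as JSON attrs

Round-trips are lossless (float64 end to end).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .errors import MembindError
from .orientation import DensityMap
from .toysim.bilayer import BilayerModel
from .toysim.body import ProteinBody
from .toysim.state import Frame, Trajectory

FORMAT_VERSION = 1


def write_trajectory(path, traj: Trajectory) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        fr = h5.create_group("frames")
        fr.create_dataset("time", data=traj.times)
        fr.create_dataset("com", data=traj.coms)
        fr.create_dataset("quaternion", data=traj.quaternions)
        explicit = traj.bilayer.mode == "explicit-lipids"
        if explicit:
            lipid_xy = np.array(
                [
                    f.lipid_xy if f.lipid_xy is not None else traj.bilayer.lipid_xy
                    for f in traj.frames
                ]
            )
            fr.create_dataset("lipid_xy", data=lipid_xy)
        body = h5.create_group("body")
        body.create_dataset("bead_positions", data=traj.body.bead_positions)
        body.create_dataset("bead_charges", data=traj.body.bead_charges)
        body.create_dataset(
            "bead_labels",
            data=np.array(traj.body.bead_labels, dtype=h5py.string_dtype()),
        )
        meta = h5.create_group("meta")
        meta.attrs["frame_interval"] = traj.frame_interval
        meta.attrs["metadata"] = json.dumps(traj.metadata, sort_keys=True)
        meta.attrs["bilayer"] = json.dumps(
            {
                "box_xy": list(traj.bilayer.box_xy),
                "species_counts": traj.bilayer.species_counts,
                "species_charges": traj.bilayer.species_charges,
                "plane_z": traj.bilayer.plane_z,
                "mode": traj.bilayer.mode,
                "lipid_species": traj.bilayer.lipid_species,
            },
            sort_keys=True,
        )


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as h5:
            times = h5["frames/time"][:]
            coms = h5["frames/com"][:]
            quats = h5["frames/quaternion"][:]
            lipid_xy = (
                h5["frames/lipid_xy"][:] if "lipid_xy" in h5["frames"] else None
            )
            body = ProteinBody(
                bead_positions=h5["body/bead_positions"][:],
                bead_charges=h5["body/bead_charges"][:],
                bead_labels=[s.decode() for s in h5["body/bead_labels"][:]],
            )
            meta = h5["meta"]
            frame_interval = float(meta.attrs["frame_interval"])
            metadata = json.loads(meta.attrs["metadata"])
            bl = json.loads(meta.attrs["bilayer"])
    except OSError as exc:
        raise MembindError(f"cannot parse trajectory container {path}: {exc}") from exc
    bilayer = BilayerModel(
        box_xy=np.array(bl["box_xy"]),
        species_counts={k: int(v) for k, v in bl["species_counts"].items()},
        species_charges={k: float(v) for k, v in bl["species_charges"].items()},
        lipid_xy=lipid_xy[-1] if lipid_xy is not None else None,
        lipid_species=bl["lipid_species"],
        plane_z=float(bl["plane_z"]),
        mode=bl["mode"],
    )
    frames = [
        Frame(
            time=float(times[i]),
            body_com=coms[i],
            body_orientation=quats[i],
            lipid_xy=lipid_xy[i] if lipid_xy is not None else None,
        )
        for i in range(len(times))
    ]
    return Trajectory(
        body=body,
        bilayer=bilayer,
        frames=frames,
        frame_interval=frame_interval,
        metadata=metadata,
    )


def read_trajectory_adapter(
    path, fmt: str = "native", mapping: dict | None = None
) -> Trajectory:
    """Normalize an on-disk trajectory to the package Trajectory type.

    ``fmt='native'`` reads the package container.  Other formats go
    through MDAnalysis (optional dependency) and require a ``mapping``
    dict with bead charges/labels and bilayer composition; this path is
    a bridge for externally produced MD data.
    """
    if fmt == "native":
        return read_trajectory(path)
    try:
        import MDAnalysis  # noqa: F401
    except ImportError as exc:
        raise MembindError(
            "reading non-native trajectories requires the optional "
            "dependency MDAnalysis (pip install membind[md])"
        ) from exc
    raise MembindError(
        f"adapter for format {fmt!r} is not implemented; convert to the "
        "native container instead"
    )


def save_lambda_set(path, lset) -> None:
    """Serialize a LambdaWindowSet (states x states x samples) to .npz."""
    np.savez(
        path,
        lambdas=lset.lambdas,
        reduced_potentials=lset.reduced_potentials,
        temperature=np.array([lset.temperature]),
        metadata=np.array(
            [
                json.dumps(
                    {
                        k: v
                        for k, v in lset.metadata.items()
                        if not isinstance(v, np.ndarray)
                    },
                    sort_keys=True,
                )
            ]
        ),
    )


def load_lambda_set(path):
    from .toysim.sampling import LambdaWindowSet

    with np.load(path) as npz:
        u = npz["reduced_potentials"]
        return LambdaWindowSet(
            lambdas=npz["lambdas"],
            reduced_potentials=u,
            samples_per_state=u.shape[2],
            temperature=float(npz["temperature"][0]),
            metadata=json.loads(str(npz["metadata"][0])),
        )


def save_density_map(path, dmap: DensityMap) -> None:
    np.savez(
        path,
        distance_edges=dmap.distance_edges,
        rzz_edges=dmap.rzz_edges,
        density=dmap.density,
        log_floor=np.array([dmap.log_floor]),
    )


def load_density_map(path) -> DensityMap:
    with np.load(path) as npz:
        return DensityMap(
            distance_edges=npz["distance_edges"],
            rzz_edges=npz["rzz_edges"],
            density=npz["density"],
            log_floor=float(npz["log_floor"][0]),
        )
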
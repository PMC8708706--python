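"""File formats: sparse flow CSV, labels CSV, Middlebury .flo, HDF5 models.

Sparse flow sequences are one CSV per sequence with columns
(frame, x_px, y_px, direction_rad, speed_deg_s); a dataset-level labels CSV
carries (sample_id, azimuth_deg, elevation_deg, pitch_dps, yaw_dps,
roll_dps).  Dense externally-computed flow is read from Middlebury ``.flo``
files and converted to the sparse representation by sampling every pixel.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .flow import CameraModel, EgoMotion, FlowFrame, FlowSequence, labels_frame
from .fuzzy_art import FuzzyARTModule, FuzzyARTParams
from .mt import MTPopulation
from .network import ARTFLOWNetwork, LayerConfig

__all__ = [
    "write_sequence_csv",
    "read_sequence_csv",
    "write_dataset",
    "read_dataset",
    "read_flo",
    "write_flo",
    "flo_to_frame",
    "save_population",
    "load_population",
    "save_network",
    "load_network",
]

_FLO_MAGIC = 202021.25  # Middlebury sanity-check float ("PIEH")


# -- sparse flow CSV --------------------------------------------------------

def write_sequence_csv(seq: FlowSequence, path) -> None:
    rows = []
    for k, fr in enumerate(seq.frames):
        rows.append(
            pd.DataFrame(
                dict(frame=k, x_px=fr.x, y_px=fr.y,
                     direction_rad=fr.direction, speed_deg_s=fr.speed)
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_sequence_csv(path, labels: EgoMotion | None = None) -> FlowSequence:
    df = pd.read_csv(path)
    frames = []
    for k in sorted(df["frame"].unique()):
        g = df[df["frame"] == k]
        frames.append(
            FlowFrame(
                x=g["x_px"].to_numpy(), y=g["y_px"].to_numpy(),
                direction=g["direction_rad"].to_numpy(),
                speed=g["speed_deg_s"].to_numpy(),
            )
        )
    return FlowSequence(frames=frames, labels=labels or EgoMotion())


def write_dataset(sequences: list[FlowSequence], out_dir, prefix: str = "sample") -> None:
    """One CSV per sequence plus a labels.csv for the split."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, seq in enumerate(sequences):
        write_sequence_csv(seq, out / f"{prefix}_{i:05d}.csv")
    labels_frame(sequences).to_csv(out / "labels.csv", index=False)


def read_dataset(in_dir, prefix: str = "sample") -> list[FlowSequence]:
    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "labels.csv")
    seqs = []
    for _, row in labels.iterrows():
        ego = EgoMotion(
            heading_azimuth=row["azimuth_deg"],
            heading_elevation=row["elevation_deg"],
            rotation_rates=(row["pitch_dps"], row["yaw_dps"], row["roll_dps"]),
        )
        path = in_dir / f"{prefix}_{int(row['sample_id']):05d}.csv"
        seqs.append(read_sequence_csv(path, labels=ego))
    return seqs


# -- Middlebury .flo --------------------------------------------------------

def read_flo(path) -> np.ndarray:
    """Dense flow (h, w, 2) in px/frame from a Middlebury .flo file."""
    with open(path, "rb") as fh:
        magic = np.fromfile(fh, np.float32, 1)
        if len(magic) == 0 or magic[0] != np.float32(_FLO_MAGIC):
            raise ValueError(f"{path}: not a .flo file")
        w, h = np.fromfile(fh, np.int32, 2)
        data = np.fromfile(fh, np.float32, int(2 * w * h))
    return data.reshape(int(h), int(w), 2)


def write_flo(flow: np.ndarray, path) -> None:
    flow = np.asarray(flow, dtype=np.float32)
    h, w, _ = flow.shape
    with open(path, "wb") as fh:
        np.array([_FLO_MAGIC], np.float32).tofile(fh)
        np.array([w, h], np.int32).tofile(fh)
        flow.tofile(fh)


def flo_to_frame(flow: np.ndarray, camera: CameraModel) -> FlowFrame:
    """Convert a dense (h, w, 2) px/frame field to the sparse representation.

    Every pixel becomes one flow vector; .flo rows run top-to-bottom with
    v positive downward, so v is negated for the y-up convention.
    Zero-speed pixels are dropped.
    """
    h, w, _ = flow.shape
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx.ravel() + 0.5 - w / 2
    y = h / 2 - (yy.ravel() + 0.5)
    u = flow[..., 0].ravel()
    v = -flow[..., 1].ravel()
    speed = np.hypot(u, v) * camera.deg_per_px * camera.fps
    keep = speed > 0
    return FlowFrame(
        x=x[keep], y=y[keep],
        direction=np.arctan2(v[keep], u[keep]), speed=speed[keep],
    )


# -- HDF5 model container ---------------------------------------------------

def save_population(pop: MTPopulation, h5: h5py.Group) -> None:
    g = h5.create_group("mt")
    for name in ("x", "y", "theta_pref", "sigma_nu", "s0", "nu_pref"):
        g.create_dataset(name, data=getattr(pop, name))
    g.attrs["rf_radius"] = pop.rf_radius
    g.attrs["sigma_theta"] = pop.sigma_theta
    g.attrs["seed"] = -1 if pop.seed is None else pop.seed
    cam = pop.camera
    g.attrs["camera"] = (cam.width, cam.height, cam.fov, cam.fps)


def load_population(h5: h5py.Group) -> MTPopulation:
    g = h5["mt"]
    w, h, fov, fps = g.attrs["camera"]
    cam = CameraModel(width=int(w), height=int(h), fov=float(fov), fps=float(fps))
    seed = int(g.attrs["seed"])
    return MTPopulation(
        x=g["x"][:], y=g["y"][:], theta_pref=g["theta_pref"][:],
        sigma_nu=g["sigma_nu"][:], s0=g["s0"][:], nu_pref=g["nu_pref"][:],
        camera=cam, rf_radius=float(g.attrs["rf_radius"]),
        sigma_theta=float(g.attrs["sigma_theta"]),
        seed=None if seed < 0 else seed,
    )


def save_network(net: ARTFLOWNetwork, path) -> None:
    net._check_trained()
    with h5py.File(path, "w") as fh:
        save_population(net.population, fh)
        for l, (cfg, modules) in enumerate(zip(net.configs, net.layers)):
            lg = fh.create_group(f"layer{l + 1}")
            lg.attrs["grid"] = cfg.grid
            lg.attrs["rho"] = cfg.rho
            lg.attrs["output_mode"] = cfg.output_mode
            p = net.params[l]
            lg.attrs["alpha"] = p.alpha
            lg.attrs["beta_commit"] = p.beta_commit
            lg.attrs["beta_recode"] = p.beta_recode
            lg.attrs["c_max"] = p.c_max
            for (r, c), mod in modules.items():
                mg = lg.create_group(f"module_{r}_{c}")
                mg.attrs["M"] = mod.M
                mg.attrs["C"] = mod.C
                mg.create_dataset("weights", data=mod.weights)


def load_network(path) -> ARTFLOWNetwork:
    with h5py.File(path, "r") as fh:
        pop = load_population(fh)
        configs, layers, params = [], [], []
        l = 1
        while f"layer{l}" in fh:
            lg = fh[f"layer{l}"]
            cfg = LayerConfig(
                grid=tuple(int(v) for v in lg.attrs["grid"]),
                rho=float(lg.attrs["rho"]),
                output_mode=str(lg.attrs["output_mode"]),
            )
            configs.append(cfg)
            params.append(
                FuzzyARTParams(
                    alpha=float(lg.attrs["alpha"]), rho=cfg.rho,
                    beta_commit=float(lg.attrs["beta_commit"]),
                    beta_recode=float(lg.attrs["beta_recode"]),
                    c_max=int(lg.attrs["c_max"]),
                )
            )
            modules = {}
            for name in lg:
                _, r, c = name.split("_")
                mg = lg[name]
                mod = FuzzyARTModule(M=int(mg.attrs["M"]), params=params[-1])
                mod.C = int(mg.attrs["C"])
                mod.W[:, : mod.C] = mg["weights"][:]
                modules[(int(r), int(c))] = mod
            layers.append(modules)
            l += 1
        net = ARTFLOWNetwork(pop, configs)
        net.params = params
        net.layers = layers
        net.trained = True
        return net
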
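"""HDF5 caches, PNG export and model bundles."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import scipy.sparse as sparse
from PIL import Image

from .filters import get_filter
from .networks import ConvEncoderDecoder, LinearNetwork
from .models import RegNetModel
from .phantoms import Sinogram
from .radon import ProjectionGeometry
from .spectral import SpectralSystem

__all__ = [
    "save_system",
    "load_system",
    "save_sinogram",
    "load_sinogram",
    "save_model",
    "load_model",
    "save_png",
    "geometry_hash",
]


def geometry_hash(geometry: ProjectionGeometry) -> str:
    payload = json.dumps(geometry.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_matrix(grp: h5py.Group, matrix) -> None:
    if sparse.issparse(matrix):
        m = matrix.tocsr()
        grp.create_dataset("data", data=m.data)
        grp.create_dataset("indices", data=m.indices)
        grp.create_dataset("indptr", data=m.indptr)
        grp.attrs["format"] = "csr"
        grp.attrs["shape"] = m.shape
    else:
        grp.create_dataset("dense", data=np.asarray(matrix))
        grp.attrs["format"] = "dense"


def _read_matrix(grp: h5py.Group):
    if grp.attrs["format"] == "csr":
        return sparse.csr_matrix(
            (grp["data"][...], grp["indices"][...], grp["indptr"][...]),
            shape=tuple(grp.attrs["shape"]),
        )
    return grp["dense"][...]


def save_system(
    system: SpectralSystem,
    path,
    geometry: Optional[ProjectionGeometry] = None,
) -> None:
    with h5py.File(path, "w") as fh:
        _write_matrix(fh.create_group("matrix"), system.matrix)
        fh.create_dataset("singular_values", data=system.singular_values)
        fh.create_dataset("domain_basis", data=system.domain_basis)
        fh.create_dataset("range_basis", data=system.range_basis)
        fh.attrs["rank_tol"] = system.rank_tol
        if geometry is not None:
            fh.attrs["geometry"] = json.dumps(geometry.to_dict())
            fh.attrs["geometry_hash"] = geometry_hash(geometry)


def load_system(path) -> SpectralSystem:
    with h5py.File(path, "r") as fh:
        return SpectralSystem(
            matrix=_read_matrix(fh["matrix"]),
            singular_values=fh["singular_values"][...],
            domain_basis=fh["domain_basis"][...],
            range_basis=fh["range_basis"][...],
            rank_tol=float(fh.attrs["rank_tol"]),
        )


def save_sinogram(sino: Sinogram, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=sino.data)
        if sino.clean_reference is not None:
            fh.create_dataset("clean_reference", data=sino.clean_reference)
        fh.attrs["noise_level"] = sino.noise_level
        fh.attrs["noise_seed"] = sino.noise_seed
        if sino.n_angles:
            fh.attrs["n_angles"] = sino.n_angles
            fh.attrs["n_offsets"] = sino.n_offsets


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as fh:
        return Sinogram(
            data=fh["data"][...],
            noise_level=float(fh.attrs["noise_level"]),
            noise_seed=int(fh.attrs["noise_seed"]),
            clean_reference=fh["clean_reference"][...] if "clean_reference" in fh else None,
            n_angles=int(fh.attrs["n_angles"]) if "n_angles" in fh.attrs else None,
            n_offsets=int(fh.attrs["n_offsets"]) if "n_offsets" in fh.attrs else None,
        )


def save_model(model: RegNetModel, path, geometry: Optional[ProjectionGeometry] = None):
    """Serialize a model bundle (filter, alpha, mode, network parameters)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["filter"] = model.filter.name
        fh.attrs["alpha"] = model.alpha
        fh.attrs["mode"] = model.mode
        fh.attrs["kernel_band"] = model.kernel_band
        if geometry is not None:
            fh.attrs["geometry_hash"] = geometry_hash(geometry)
        net = model.network
        if net is not None and net.trainable:
            grp = fh.create_group("network")
            grp.attrs["architecture"] = net.architecture
            if isinstance(net, ConvEncoderDecoder):
                grp.attrs["kind"] = "conv"
                grp.attrs["scales"] = net.scales
                grp.attrs["base_channels"] = net.base_channels
            elif isinstance(net, LinearNetwork):
                grp.attrs["kind"] = "linear"
                grp.attrs["grid_n"] = net.grid_n
            else:
                raise ValueError(f"cannot serialize network {net.architecture}")
            for i, p in enumerate(net.get_params()):
                grp.create_dataset(f"p{i}", data=p)


def load_model(path, system: SpectralSystem) -> RegNetModel:
    with h5py.File(path, "r") as fh:
        network = None
        if "network" in fh:
            grp = fh["network"]
            if grp.attrs["kind"] == "conv":
                network = ConvEncoderDecoder(
                    scales=int(grp.attrs["scales"]),
                    base_channels=int(grp.attrs["base_channels"]),
                )
            else:
                network = LinearNetwork(grid_n=int(grp.attrs["grid_n"]))
            params = [grp[f"p{i}"][...] for i in range(len(network.get_params()))]
            network.set_params(params)
        return RegNetModel(
            system=system,
            filter=get_filter(str(fh.attrs["filter"])),
            alpha=float(fh.attrs["alpha"]),
            network=network,
            mode=str(fh.attrs["mode"]),
            kernel_band=str(fh.attrs["kernel_band"]),
        )


def save_png(image: np.ndarray, path) -> None:
    """Export an image as 8-bit grayscale PNG (min-max scaled)."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(Path(path))
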
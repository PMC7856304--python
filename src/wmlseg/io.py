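"""File I/O: NIfTI volumes, atlas bundles, shape-model weights, configs.

The tool requires co-registered inputs on one grid; no resampling is ever
performed here.  Atlas bundles are directories of ``.npy`` arrays plus a
JSON manifest; shape models are a single ``.npz`` weights file plus a JSON
manifest.  Both round-trip bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .atlas import MeshAtlas
from .geometry import ImageGeometry, MultiContrastImage
from .infer import SegmentationResult
from .metrics import mask_volume
from .shape_vae import LesionShapeModel


@dataclass
class RunConfig:
    """End-to-end segmentation run configuration (YAML-loadable)."""

    inputs: list                     # [{"path": ..., "role": ...}, ...]
    atlas_path: str = None
    shape_model_path: str = None
    gamma: float = 0.5
    n_samples: int = 50
    burn_in: int = 20
    nu: float = 500.0
    kappa: float = 50.0
    covariance_mode: str = "diagonal"
    bias_order: int = 3
    output_dir: str = "out"
    seed: int = 0
    verbosity: int = 1
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.inputs) < 1:
            raise ValueError("at least one input channel required")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in data.items() if k in known}
    kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volumes(paths, roles=None) -> MultiContrastImage:
    """Stack co-registered NIfTI volumes into one multi-contrast image.

    All volumes must share grid dimensions and voxel size (the caller is
    responsible for co-registration and resampling beforehand); trailing
    singleton axes are squeezed.  Non-finite voxels are a hard error.
    """
    paths = [Path(p) for p in (paths if np.iterable(paths) and
                               not isinstance(paths, (str, Path)) else [paths])]
    if roles is None:
        roles = ["other"] * len(paths)
    if len(roles) != len(paths):
        raise ValueError("one role per volume required")
    arrays, zooms, affine, shape = [], None, None, None
    for p in paths:
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj, dtype=float)
        z = img.header.get_zooms()[:data.ndim]
        if shape is None:
            shape, zooms, affine = data.shape, z, img.affine
        elif data.shape != shape or not np.allclose(z, zooms):
            raise ValueError(
                f"{p}: grid {data.shape}@{z} differs from {shape}@{zooms}; "
                "co-register and resample all contrasts to one grid first")
        bad = np.count_nonzero(~np.isfinite(data))
        if bad:
            raise ValueError(f"{p}: {bad} non-finite voxels")
        arrays.append(data)
    stacked = np.stack(arrays, axis=-1)
    # squeeze trailing singleton spatial axes (2-D data stored as 3-D NIfTI)
    sq = [i for i, s in enumerate(shape) if s == 1 and i >= 2]
    if sq:
        stacked = stacked.reshape([s for i, s in enumerate(shape)
                                   if i not in sq] + [len(paths)])
        zooms = tuple(z for i, z in enumerate(zooms) if i not in sq)
        shape = stacked.shape[:-1]
    geom = ImageGeometry(shape, zooms, affine)
    return MultiContrastImage(stacked, geom, roles=tuple(roles))


def write_volume(array: np.ndarray, geometry: ImageGeometry, path,
                 dtype=None) -> None:
    data = np.asarray(array)
    if dtype is not None:
        data = data.astype(dtype)
    while data.ndim < 3:
        data = data[..., None]
    affine = geometry.affine
    if affine.shape[0] < 4:      # promote 2-D affine to the NIfTI 4x4 form
        a = np.eye(4)
        a[:2, :2] = affine[:2, :2]
        a[:2, 3] = affine[:2, -1]
        affine = a
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _config_hash(provenance: dict) -> str:
    clean = {k: v for k, v in provenance.items()
             if isinstance(v, (int, float, str, bool, type(None)))}
    return hashlib.sha256(
        json.dumps(clean, sort_keys=True).encode()).hexdigest()[:16]


def write_outputs(result: SegmentationResult, geometry: ImageGeometry,
                  outdir, label_names=None) -> dict:
    """Write label map, lesion posterior/mask, volume table and provenance.

    Returns the mapping of artifact name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    write_volume(result.label_map, geometry, outdir / "labels.nii.gz",
                 dtype=np.int16)
    files["labels"] = outdir / "labels.nii.gz"
    write_volume(result.lesion_posterior, geometry,
                 outdir / "lesion_posterior.nii.gz", dtype=np.float64)
    files["lesion_posterior"] = outdir / "lesion_posterior.nii.gz"
    write_volume(result.lesion_mask.astype(np.uint8), geometry,
                 outdir / "lesion_mask.nii.gz", dtype=np.uint8)
    files["lesion_mask"] = outdir / "lesion_mask.nii.gz"

    K = result.soft_weights.shape[-1]
    if label_names is None:
        label_names = [f"label{k}" for k in range(K)]
    rows = ["structure,volume_mm3"]
    for k, name in enumerate(label_names):
        vol = mask_volume(result.label_map == k, geometry.voxel_size)
        rows.append(f"{name},{vol}")
    rows.append(
        f"lesions,{mask_volume(result.lesion_mask, geometry.voxel_size)}")
    (outdir / "volumes.csv").write_text("\n".join(rows) + "\n")
    files["volumes"] = outdir / "volumes.csv"

    prov = {k: v for k, v in result.provenance.items()
            if isinstance(v, (int, float, str, bool, type(None)))}
    prov["config_hash"] = _config_hash(result.provenance)
    prov["python"] = sys.version.split()[0]
    prov["numpy"] = np.__version__
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")
    files["provenance"] = outdir / "provenance.json"
    return files


# ---------------------------------------------------------------------------
# Atlas bundle
# ---------------------------------------------------------------------------

def save_atlas(atlas: MeshAtlas, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "vertices.npy", atlas.reference_vertex_positions)
    np.save(outdir / "simplices.npy", atlas.simplices)
    np.save(outdir / "alpha.npy", atlas.label_probs)
    np.save(outdir / "beta.npy", atlas.lesion_probs)
    manifest = {"n_labels": atlas.n_labels,
                "label_names": list(atlas.label_names),
                "stiffness": atlas.stiffness,
                "mesh_spacing": atlas.mesh_spacing}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_atlas(indir) -> MeshAtlas:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    return MeshAtlas(
        reference_vertex_positions=np.load(indir / "vertices.npy"),
        simplices=np.load(indir / "simplices.npy"),
        label_probs=np.load(indir / "alpha.npy"),
        lesion_probs=np.load(indir / "beta.npy"),
        stiffness=manifest["stiffness"],
        label_names=tuple(manifest["label_names"]),
        mesh_spacing=manifest["mesh_spacing"])


# ---------------------------------------------------------------------------
# Shape model
# ---------------------------------------------------------------------------

def save_shape_model(model: LesionShapeModel, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = dict(model.weights)
    if model.elbo_trace is not None:
        arrays["__elbo_trace__"] = model.elbo_trace
    np.savez(outdir / "weights.npz", **arrays)
    manifest = {"latent_dim": model.latent_dim,
                "input_shape": list(model.input_shape),
                "hidden": list(model.hidden),
                "training_meta": model.training_meta}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_shape_model(indir) -> LesionShapeModel:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    with np.load(indir / "weights.npz") as npz:
        weights = {k: npz[k] for k in npz.files if k != "__elbo_trace__"}
        trace = npz["__elbo_trace__"] if "__elbo_trace__" in npz.files else None
    return LesionShapeModel(weights=weights,
                            latent_dim=int(manifest["latent_dim"]),
                            input_shape=tuple(manifest["input_shape"]),
                            hidden=tuple(manifest["hidden"]),
                            training_meta=manifest.get("training_meta", {}),
                            elbo_trace=trace)
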
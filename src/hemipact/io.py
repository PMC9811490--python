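"""Readers/writers for on-disk formats and the YAML-configured pipeline.

Volumes go to NIfTI (voxel size in the affine), TIFF stacks (voxel size
in a JSON sidecar, since plain TIFF has no 3D spacing metadata) or HDF5;
signal frames and dynamic sequences go to HDF5.  Arrays are stored as
float32; internal accumulation stays float64.  The pipeline driver runs
phantom -> simulate -> reconstruct -> metrics from a single config with
one global seed and writes a manifest with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from hemipact.core import GridSpec, Volume, VolumeSequence
from hemipact.forward import SignalFrame, impulse_response, simulate_signals
from hemipact.geometry import ArrayGeometry, ElementSubset, SubsetMode, build_array, select_subset

__all__ = [
    "save_volume",
    "load_volume",
    "save_signals",
    "load_signals",
    "save_geometry",
    "load_geometry",
    "save_sequence",
    "load_sequence",
    "PipelineConfig",
    "run_pipeline",
]


# ----------------------------------------------------------------------------
# volumes


def _nifti_affine(volume: Volume) -> np.ndarray:
    aff = np.diag([volume.voxel_mm] * 3 + [1.0])
    aff[:3, 3] = volume.origin_mm
    return aff


def save_volume(volume: Volume, path, fmt: str | None = None) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz), TIFF (.tif) or HDF5 (.h5)."""
    path = Path(path)
    fmt = fmt or _volume_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.Nifti1Image(volume.values.astype(np.float32), _nifti_affine(volume))
        nib.save(img, str(path))
    elif fmt == "tiff":
        import tifffile

        # TIFF keeps no 3D voxel spacing; sidecar JSON carries the metadata.
        tifffile.imwrite(str(path), volume.values.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"voxel_mm": volume.voxel_mm, "origin_mm": list(volume.origin_mm)})
        )
        warnings.warn(f"TIFF stores no voxel size; wrote sidecar {sidecar.name}")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("volume", data=volume.values.astype(np.float32))
            d.attrs["voxel_mm"] = volume.voxel_mm
            d.attrs["origin_mm"] = volume.origin_mm
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return path


def _volume_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if name.endswith((".h5", ".hdf5")):
        return "hdf5"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def load_volume(path, fmt: str | None = None) -> Volume:
    path = Path(path)
    fmt = fmt or _volume_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        voxel = float(aff[0, 0])
        origin = tuple(float(v) for v in aff[:3, 3])
        return Volume(np.asarray(img.dataobj, dtype=np.float32), voxel, origin)
    if fmt == "tiff":
        import tifffile

        values = tifffile.imread(str(path))
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            return Volume(values, meta["voxel_mm"], tuple(meta["origin_mm"]))
        return Volume(values, 1.0)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            d = f["volume"]
            return Volume(d[()], float(d.attrs["voxel_mm"]), tuple(d.attrs["origin_mm"]))
    raise ValueError(f"unknown volume format {fmt!r}")


# ----------------------------------------------------------------------------
# signal frames


def save_signals(frame: SignalFrame, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=frame.samples.astype(np.float32))
        f.create_dataset("indices", data=frame.subset.indices)
        f.attrs["mode"] = frame.subset.mode.value
        f.attrs["sample_rate_hz"] = frame.sample_rate_hz
        f.attrs["t0_s"] = frame.t0_s
        f.attrs["speed_of_sound_m_s"] = frame.speed_of_sound_m_s
        if frame.wavelength_nm is not None:
            f.attrs["wavelength_nm"] = frame.wavelength_nm
    return path


def load_signals(path) -> SignalFrame:
    with h5py.File(path, "r") as f:
        required = ["sample_rate_hz", "t0_s", "speed_of_sound_m_s", "mode"]
        missing = [k for k in required if k not in f.attrs]
        if "samples" not in f or "indices" not in f:
            missing.append("samples/indices")
        if missing:
            raise KeyError(f"signal file {path} is missing required fields: {missing}")
        subset = ElementSubset(SubsetMode(f.attrs["mode"]), f["indices"][()])
        return SignalFrame(
            samples=f["samples"][()].astype(np.float64),
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            t0_s=float(f.attrs["t0_s"]),
            subset=subset,
            speed_of_sound_m_s=float(f.attrs["speed_of_sound_m_s"]),
            wavelength_nm=float(f.attrs["wavelength_nm"]) if "wavelength_nm" in f.attrs else None,
        )


# ----------------------------------------------------------------------------
# geometry


def save_geometry(geom: ArrayGeometry, path) -> Path:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        payload = {
            "radius_mm": geom.radius_mm,
            "n_elements": geom.n_elements,
            "element_area_mm2": geom.element_area_mm2,
            "cap_half_angle_deg": geom.cap_half_angle_deg,
            "element_angular_radius_rad": geom.element_angular_radius_rad,
            "element_positions": geom.element_positions.tolist(),
            "element_order": geom.element_order.tolist(),
        }
        path.write_text(yaml.safe_dump(payload))
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("element_positions", data=geom.element_positions)
            f.create_dataset("element_order", data=geom.element_order)
            for key in ("radius_mm", "n_elements", "element_area_mm2",
                        "cap_half_angle_deg", "element_angular_radius_rad"):
                f.attrs[key] = getattr(geom, key)
    return path


def load_geometry(path) -> ArrayGeometry:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        payload = yaml.safe_load(path.read_text())
        return ArrayGeometry(
            radius_mm=payload["radius_mm"],
            n_elements=payload["n_elements"],
            element_area_mm2=payload["element_area_mm2"],
            element_positions=np.asarray(payload["element_positions"]),
            element_order=np.asarray(payload["element_order"]),
            cap_half_angle_deg=payload["cap_half_angle_deg"],
            element_angular_radius_rad=payload["element_angular_radius_rad"],
        )
    with h5py.File(path, "r") as f:
        return ArrayGeometry(
            radius_mm=float(f.attrs["radius_mm"]),
            n_elements=int(f.attrs["n_elements"]),
            element_area_mm2=float(f.attrs["element_area_mm2"]),
            element_positions=f["element_positions"][()],
            element_order=f["element_order"][()],
            cap_half_angle_deg=float(f.attrs["cap_half_angle_deg"]),
            element_angular_radius_rad=float(f.attrs["element_angular_radius_rad"]),
        )


# ----------------------------------------------------------------------------
# sequences


def save_sequence(seq: VolumeSequence, path, ground_truth: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        first = seq[0]
        f.create_dataset("frames", data=seq.as_array().astype(np.float32))
        f.attrs["frame_rate_hz"] = seq.frame_rate_hz
        f.attrs["voxel_mm"] = first.voxel_mm
        f.attrs["origin_mm"] = first.origin_mm
        if seq.wavelength_nm is not None:
            f.create_dataset("wavelength_nm", data=np.asarray(seq.wavelength_nm))
        if ground_truth:
            g = f.create_group("ground_truth")
            for key, value in ground_truth.items():
                g.create_dataset(key, data=np.asarray(value))
    return path


def load_sequence(path) -> tuple[VolumeSequence, dict]:
    with h5py.File(path, "r") as f:
        arr = f["frames"][()]
        voxel = float(f.attrs["voxel_mm"])
        origin = tuple(f.attrs["origin_mm"])
        frames = [Volume(a.astype(np.float64), voxel, origin) for a in arr]
        wl = f["wavelength_nm"][()].tolist() if "wavelength_nm" in f else None
        gt = {}
        if "ground_truth" in f:
            gt = {k: f["ground_truth"][k][()] for k in f["ground_truth"]}
        return VolumeSequence(frames, float(f.attrs["frame_rate_hz"]), wl), gt


# ----------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Stage list plus per-stage parameter blocks and the global seed."""

    stages: list[str]
    params: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            stages=payload["stages"],
            params=payload.get("params", {}),
            seed=payload.get("seed", 0),
            output_dir=payload.get("output_dir", "."),
        )


_KNOWN_STAGES = ("phantom", "simulate", "reconstruct", "metrics")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order and return the artifact manifest.

    Stage outputs chain: phantom -> simulate -> reconstruct -> metrics.
    Validation happens before any compute; any referenced input file
    must exist up front.
    """
    unknown = [s for s in config.stages if s not in _KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stages: {unknown}")
    for stage in config.stages:
        block = config.params.get(stage, {})
        for key in ("phantom_path", "frame_path", "reference_path"):
            if key in block and not Path(block[key]).exists():
                raise FileNotFoundError(f"stage {stage!r} references missing file {block[key]}")

    from hemipact.metrics import quality_report
    from hemipact.phantom import make_point_phantom, make_vessel_phantom
    from hemipact.reconstruction import ReconGrid, das_reconstruct

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    state: dict = {}

    for stage in config.stages:
        block = dict(config.params.get(stage, {}))
        if stage == "phantom":
            g = GridSpec(
                tuple(block.get("shape", (32, 32, 32))), block.get("voxel_mm", 0.1)
            )
            kind = block.get("kind", "point")
            if kind == "point":
                vol = make_point_phantom(
                    g, tuple(block.get("center_mm", (0, 0, 0))),
                    block.get("diameter_um", 50.0), block.get("amplitude", 1.0),
                )
            elif kind == "vessel":
                vol = make_vessel_phantom(g, seed=config.seed,
                                          n_branches=block.get("n_branches", 4))
            else:
                raise ValueError(f"unknown phantom kind {kind!r}")
            path = save_volume(vol, out_dir / "phantom.nii")
            state["phantom"] = vol
            manifest["outputs"]["phantom"] = str(path)
        elif stage == "simulate":
            if "phantom_path" in block:
                state["phantom"] = load_volume(block["phantom_path"])
            geom = build_array(n_elements=block.get("n_elements", 256),
                               element_area_mm2=block.get("element_area_mm2", 48.0))
            subset = select_subset(geom, block.get("subset", "full"))
            ir = impulse_response()
            frame = simulate_signals(state["phantom"], geom, subset, ir)
            path = save_signals(frame, out_dir / "frame.h5")
            state["frame"], state["geom"] = frame, geom
            manifest["outputs"]["frame"] = str(path)
        elif stage == "reconstruct":
            grid = ReconGrid(
                tuple(block.get("shape", state["phantom"].shape)),
                block.get("voxel_mm", state["phantom"].voxel_mm),
            )
            vol = das_reconstruct(state["frame"], state["geom"], grid)
            path = save_volume(vol, out_dir / "reconstruction.nii")
            state["reconstruction"] = vol
            manifest["outputs"]["reconstruction"] = str(path)
        elif stage == "metrics":
            recon = np.abs(state["reconstruction"].values)
            recon = recon / recon.max() if recon.max() > 0 else recon
            gt = state["phantom"].values
            gt = gt / gt.max() if gt.max() > 0 else gt
            from hemipact.metrics import psnr, rmse

            report = {"rmse": rmse(recon, gt), "psnr_db": psnr(recon, gt)}
            path = out_dir / "metrics.json"
            path.write_text(json.dumps(report, indent=2))
            manifest["outputs"]["metrics"] = str(path)
        manifest["stages"].append(stage)

    manifest["checksums"] = {k: _sha256(Path(v)) for k, v in manifest["outputs"].items()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
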
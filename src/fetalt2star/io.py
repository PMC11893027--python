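"""NIfTI and manifest I/O plus the serializable pipeline configuration.

Volumes are stored as gzipped NIfTI-1, float32 on disk (computation stays
float64 in memory). Slice stacks are written one NIfTI per echo with the
slices as volume planes over a (dynamic * slice) fourth axis, plus a JSON
sidecar holding the per-slice rigid transforms, dynamic indices and
acquisition geometry.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import (
    AcquisitionSpec,
    LabelVolume,
    MultiEchoVolume,
    PhantomSpec,
    SliceStack,
)
from .reconstruction import ReconConfig

__all__ = [
    "read_nifti",
    "write_nifti",
    "write_label_volume",
    "read_label_volume",
    "write_multiecho",
    "read_multiecho",
    "write_slice_stacks",
    "read_slice_stacks",
    "FitConfig",
    "NormativeConfig",
    "CohortSimConfig",
    "PipelineConfig",
]


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))
    return path


def read_nifti(path):
    """Load a NIfTI volume; returns (float64 data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine, dtype=float)
    except (nib.filebasedimages.ImageFileError, OSError) as exc:
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc


def write_label_volume(labels: LabelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine)
    nib.save(img, str(path))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in labels.label_names.items()}, indent=1))
    return path


def read_label_volume(path) -> LabelVolume:
    data, affine = read_nifti(path)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json")
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        values = np.unique(data.astype(int))
        names = {int(v): f"label_{int(v)}" for v in values}
        names[0] = "background"
    return LabelVolume(labels=data.astype(np.int16), affine=affine, label_names=names)


def write_multiecho(volume: MultiEchoVolume, path) -> Path:
    path = write_nifti(volume.data, volume.affine, path)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_echoes.json")
    sidecar.write_text(json.dumps({"echo_times_ms": list(volume.echo_times)}))
    return path


def read_multiecho(path) -> MultiEchoVolume:
    data, affine = read_nifti(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D multi-echo volume, got shape {data.shape}")
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_echoes.json")
    if not sidecar.exists():
        raise ValueError(f"missing echo-time sidecar for {path}")
    te = json.loads(sidecar.read_text())["echo_times_ms"]
    return MultiEchoVolume(
        data=data, echo_times=tuple(float(t) for t in te), affine=affine,
        voxel_size=float(np.abs(affine[0, 0])),
    )


def write_slice_stacks(stacks: list, out_dir, prefix: str = "stack") -> list:
    """One NIfTI per echo (planes stacked over dynamic*slice) + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for stack in stacks:
        nd, ns, ny, nx = stack.data.shape
        arr = stack.data.reshape(nd * ns, ny, nx).transpose(2, 1, 0)  # (x, y, plane)
        img = nib.Nifti1Image(arr.astype(np.float32), np.eye(4))
        path = out_dir / f"{prefix}_echo{stack.echo_index + 1}.nii.gz"
        nib.save(img, str(path))
        sidecar = out_dir / f"{prefix}_echo{stack.echo_index + 1}.json"
        sidecar.write_text(
            json.dumps(
                {
                    "echo_index": stack.echo_index,
                    "echo_time_ms": stack.echo_time,
                    "n_dynamics": nd,
                    "n_slices": ns,
                    "slice_z_mm": stack.slice_z.tolist(),
                    "pixel_x_mm": stack.pixel_x.tolist(),
                    "pixel_y_mm": stack.pixel_y.tolist(),
                    "thickness_mm": stack.thickness,
                    "in_plane_resolution_mm": stack.in_plane_resolution,
                    "transforms": stack.transforms.reshape(nd * ns, 6).tolist(),
                },
                indent=1,
            )
        )
        paths.append(path)
    return paths


def read_slice_stacks(paths: list) -> list:
    stacks = []
    for path in paths:
        path = Path(path)
        sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
        if not sidecar.exists():
            raise ValueError(f"missing sidecar for stack {path}")
        meta = json.loads(sidecar.read_text())
        data, _ = read_nifti(path)
        nd, ns = meta["n_dynamics"], meta["n_slices"]
        arr = data.transpose(2, 1, 0).reshape(nd, ns, len(meta["pixel_y_mm"]), len(meta["pixel_x_mm"]))
        stacks.append(
            SliceStack(
                data=arr,
                transforms=np.asarray(meta["transforms"]).reshape(nd, ns, 6),
                echo_index=int(meta["echo_index"]),
                echo_time=float(meta["echo_time_ms"]),
                slice_z=np.asarray(meta["slice_z_mm"]),
                pixel_x=np.asarray(meta["pixel_x_mm"]),
                pixel_y=np.asarray(meta["pixel_y_mm"]),
                thickness=float(meta["thickness_mm"]),
                in_plane_resolution=float(meta["in_plane_resolution_mm"]),
            )
        )
    return stacks


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FitConfig:
    method: str = "loglinear"
    t2_min: float = 1.0
    t2_max: float = 1000.0
    min_first_echo_signal: float = 0.0


@dataclass(frozen=True)
class NormativeConfig:
    degree: int = 2
    make_plots: bool = False


@dataclass(frozen=True)
class CohortSimConfig:
    """Normative-stage cohort source: tabular synthesis from the reference table."""

    n_scans: int = 92
    synthesize_tabular: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    reconstruction: ReconConfig = field(default_factory=ReconConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    normative: NormativeConfig = field(default_factory=NormativeConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    seed: int = 0

    _SECTIONS = {
        "phantom": PhantomSpec,
        "acquisition": AcquisitionSpec,
        "reconstruction": ReconConfig,
        "fit": FitConfig,
        "normative": NormativeConfig,
        "cohort": CohortSimConfig,
    }

    def to_dict(self) -> dict:
        out = {}
        for name in self._SECTIONS:
            section = dataclasses.asdict(getattr(self, name))
            out[name] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in section.items()
            }
        out["seed"] = self.seed
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        kwargs = {}
        seed = raw.pop("seed", 0)
        unknown = set(raw) - set(cls._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for name, section_cls in cls._SECTIONS.items():
            section = dict(raw.get(name) or {})
            valid = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(bad)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            kwargs[name] = section_cls(**coerced)
        return cls(seed=int(seed), **kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def write_regional_csv(rows: list, path) -> Path:
    """Per-scan regional statistics CSV (one row per scan x region)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
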
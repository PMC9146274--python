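"""File formats, configuration, and deterministic dataset fixtures.

Frames travel as 32-bit float single- or multi-page grayscale TIFF on the
[0, 255] scale (no quantization); ground truth, detections, and training
history as CSV; dataset manifests and evaluation reports as JSON; pipeline
configuration as YAML mirroring the dataclass field names (unknown keys are
errors).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .evaluate import DEFAULT_D_MATCH, DEFAULT_MIN_AREA, DEFAULT_R_LINK, DEFAULT_THRESHOLD
from .simulate import (
    BackgroundParams,
    Dataset,
    DatasetSpec,
    FramePair,
    NoiseParams,
    TruthDisc,
    VolumeSpec,
)
from .train import TrainConfig
from .model import UpUNetSpec


class FormatError(ValueError):
    """Unreadable or non-grayscale image file."""


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def read_tiff_stack(path) -> list[np.ndarray]:
    """Read a single- or multi-page grayscale TIFF as a list of 2D arrays."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # corrupt file
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        return [data.astype(np.float64)]
    if data.ndim == 3 and data.shape[-1] not in (3, 4):
        return [page.astype(np.float64) for page in data]
    raise FormatError(f"{path}: expected grayscale pages, got shape {data.shape}")


def write_tiff_stack(frames, path) -> None:
    """Write frames as grayscale TIFF, one page per frame.

    Float input is stored as 32-bit float on the [0, 255] scale (no
    quantization); uint8 input (display export) is stored as-is.
    """
    frames = [np.asarray(f) for f in frames]
    if not all(f.dtype == np.uint8 for f in frames):
        frames = [f.astype(np.float32) for f in frames]
    arr = frames[0] if len(frames) == 1 else np.stack(frames)
    tifffile.imwrite(Path(path), arr)


# ---------------------------------------------------------------------------
# Truth / detection CSV
# ---------------------------------------------------------------------------

def write_truth_csv(truth, path) -> None:
    rows = [{"id": t.particle_id, "cx_px": t.cx_px, "cy_px": t.cy_px,
             "radius_px": t.radius_px, "z_um": t.z_um} for t in truth]
    pd.DataFrame(rows, columns=["id", "cx_px", "cy_px", "radius_px", "z_um"]).to_csv(
        path, index=False)


def read_truth_csv(path) -> tuple[TruthDisc, ...]:
    df = pd.read_csv(path)
    return tuple(
        TruthDisc(particle_id=int(r.id), cx_px=float(r.cx_px), cy_px=float(r.cy_px),
                  radius_px=float(r.radius_px), z_um=float(r.z_um))
        for r in df.itertuples()
    )


# ---------------------------------------------------------------------------
# Dataset on disk
# ---------------------------------------------------------------------------

def save_dataset(dataset: Dataset, outdir) -> Path:
    """Write frame pairs + truth sidecars + a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = []
    counter = 0
    for split in ("train", "val", "test"):
        for pair in getattr(dataset, split):
            iid = f"img_{counter:04d}"
            counter += 1
            write_tiff_stack([pair.input_frame], outdir / f"{iid}_input.tif")
            write_tiff_stack([pair.target_frame], outdir / f"{iid}_target.tif")
            write_truth_csv(pair.truth, outdir / f"{iid}_truth.csv")
            items.append({"id": iid, "split": split, "slice_index": pair.slice_index,
                          "seeds": pair.seeds})
    manifest = {"spec": asdict(dataset.spec), "items": items}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def _spec_from_dict(d: dict) -> DatasetSpec:
    d = dict(d)
    d["volume"] = VolumeSpec(**d["volume"])
    d["background"] = BackgroundParams(**d["background"])
    d["noise"] = NoiseParams(**d["noise"])
    d["split"] = tuple(d["split"])
    d["count_range"] = tuple(d["count_range"])
    if isinstance(d["radius"], list):
        d["radius"] = tuple(d["radius"])
    return DatasetSpec(**d)


def load_dataset(directory) -> Dataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = _spec_from_dict(manifest["spec"])
    splits: dict[str, list[FramePair]] = {"train": [], "val": [], "test": []}
    for item in manifest["items"]:
        iid = item["id"]
        pair = FramePair(
            input_frame=read_tiff_stack(directory / f"{iid}_input.tif")[0],
            target_frame=read_tiff_stack(directory / f"{iid}_target.tif")[0],
            truth=read_truth_csv(directory / f"{iid}_truth.csv"),
            slice_index=item["slice_index"],
            seeds=item["seeds"],
        )
        splits[item["split"]].append(pair)
    return Dataset(spec=spec, **splits)


# ---------------------------------------------------------------------------
# YAML pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorParams:
    threshold: float = DEFAULT_THRESHOLD
    min_area: int = DEFAULT_MIN_AREA
    d_match: float = DEFAULT_D_MATCH
    r_link: float = DEFAULT_R_LINK


@dataclass(frozen=True)
class PipelineConfig:
    dataset: DatasetSpec = dc_field(default_factory=DatasetSpec)
    model: UpUNetSpec = dc_field(default_factory=UpUNetSpec)
    train: TrainConfig = dc_field(default_factory=TrainConfig)
    detector: DetectorParams = dc_field(default_factory=DetectorParams)
    seed: int = 0
    outdir: str = "."


def _build(dc_cls, data: dict, path: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        nested = {"volume": VolumeSpec, "background": BackgroundParams,
                  "noise": NoiseParams}.get(name)
        if nested is not None and isinstance(value, dict):
            value = _build(nested, value, f"{path}.{name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return dc_cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("top-level config must be a mapping")
    known = {"dataset", "model", "train", "detector", "seed", "outdir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    return PipelineConfig(
        dataset=_build(DatasetSpec, raw.get("dataset", {}), "dataset"),
        model=_build(UpUNetSpec, raw.get("model", {}), "model"),
        train=_build(TrainConfig, raw.get("train", {}), "train"),
        detector=_build(DetectorParams, raw.get("detector", {}), "detector"),
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", ".")),
    )


def resolved_config_dict(cfg: PipelineConfig) -> dict:
    return asdict(cfg)


# ---------------------------------------------------------------------------
# Fixtures: named dataset presets
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("unit", "smoke", "table1-128", "table1-256", "table1-512",
                 "radii-0.5-4", "volume-22")


def make_fixture(kind: str, seed: int = 0) -> DatasetSpec:
    """Deterministic dataset presets.

    ``unit`` and ``smoke`` are miniature specs for fast tests; the
    ``table1-*`` kinds reproduce the full study settings at 128/256/512 px
    (500 images, 76x76x5 um volume, 10-15 beads of 2 um radius, PSF sigma 2,
    read-noise level 0.03); ``radii-0.5-4`` is the variable-radius variant
    (0-15 beads, radius 0.5-4 um at 256 px) and ``volume-22`` the 512x512x22
    voxel z-stack scenario over 76x76x6 um.
    """
    if kind == "unit":
        return DatasetSpec(
            n_images=6, split=(2 / 3, 1 / 6, 1 / 6), count_range=(1, 3), radius=2.0,
            volume=VolumeSpec(Dx=19.0, Dy=19.0, Dz=5.0, n=32, nz=8), seed=seed)
    if kind == "smoke":
        return DatasetSpec(
            n_images=8, split=(0.75, 0.125, 0.125), count_range=(2, 5), radius=2.0,
            volume=VolumeSpec(Dx=38.0, Dy=38.0, Dz=5.0, n=64, nz=12), seed=seed)
    if kind in ("table1-128", "table1-256", "table1-512"):
        n = int(kind.rsplit("-", 1)[1])
        return DatasetSpec(volume=VolumeSpec(n=n), seed=seed)
    if kind == "radii-0.5-4":
        return DatasetSpec(count_range=(0, 15), radius=(0.5, 4.0),
                           volume=VolumeSpec(n=256), seed=seed)
    if kind == "volume-22":
        return DatasetSpec(n_images=1, volume=VolumeSpec(Dx=76.0, Dy=76.0, Dz=6.0,
                                                         n=512, nz=22), seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
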
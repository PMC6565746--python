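"""Readers and writers: OME-TIFF stacks, CSV event tables, MTX count
triplets, and the validated YAML/JSON run configuration.

All writers round-trip losslessly with their readers for the values and
metadata the corresponding types define.  CSV is the canonical
flow-cytometry event format (desk-scale, text, diffable); count matrices
use the CellRanger-style ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``
triplet.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import io as sio
from scipy import sparse

from .imaging import ImageStack
from .synth import CountMatrix


# --------------------------------------------------------------------------
# image stacks
# --------------------------------------------------------------------------

def write_stack(
    path,
    stack: ImageStack,
    labels: np.ndarray | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a multi-channel stack (and optional label volume as a second
    series) to OME-TIFF. Channel names, voxel sizes and any metadata dict
    are stored in the OME annotation."""
    path = Path(path)
    names = sorted(stack.channels)
    arr = np.stack([stack.channels[n] for n in names], axis=0).astype(np.float32)
    desc = {
        "channel_names": names,
        "voxel_size_um": list(stack.voxel_size_um),
        **(metadata or {}),
    }
    with tifffile.TiffWriter(path, ome=True) as tif:
        tif.write(
            arr,
            metadata={
                "axes": "CZYX",
                "Name": "image",
                "Description": json.dumps(desc),
            },
        )
        if labels is not None:
            tif.write(
                labels.astype(np.int32), metadata={"axes": "ZYX", "Name": "labels"}
            )


def read_stack(path) -> tuple[ImageStack, np.ndarray | None, dict]:
    """Read an OME-TIFF written by :func:`write_stack`.

    Returns (stack, labels-or-None, metadata dict)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series
        arr = series[0].asarray()
        try:
            desc = json.loads(tif.ome_metadata and _ome_description(tif) or "{}")
        except (json.JSONDecodeError, TypeError):
            desc = {}
        labels = series[1].asarray() if len(series) > 1 else None
    names = desc.get("channel_names") or [f"ch{i}" for i in range(arr.shape[0])]
    voxel = tuple(desc.get("voxel_size_um", (0.426, 0.071, 0.071)))
    channels = {n: arr[i].astype(float) for i, n in enumerate(names)}
    meta = {k: v for k, v in desc.items() if k not in ("channel_names", "voxel_size_um")}
    return ImageStack(channels=channels, voxel_size_um=voxel), labels, meta


def _ome_description(tif) -> str:
    import xml.etree.ElementTree as ET

    root = ET.fromstring(tif.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    el = root.find(".//ome:Image/ome:Description", ns)
    return el.text if el is not None and el.text else "{}"


# --------------------------------------------------------------------------
# flow event tables
# --------------------------------------------------------------------------

def write_events(path, events: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write an event table to CSV; metadata goes into '#'-prefixed header
    comment lines (ignored on read)."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        events.to_csv(fh, index=False)


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas names the line
        raise ValueError(f"malformed event CSV {path}: {exc}") from exc
    if "area" not in df.columns:
        raise ValueError(f"event table {path} lacks required 'area' column")
    return df


# --------------------------------------------------------------------------
# count matrices
# --------------------------------------------------------------------------

def write_counts(directory, matrix: CountMatrix) -> None:
    """Write a CellRanger-style triplet: matrix.mtx, features.tsv,
    barcodes.tsv (plus groups.tsv when ploidy-group labels are present)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(directory / "matrix.mtx"), matrix.counts.astype(np.int64))
    (directory / "features.tsv").write_text("\n".join(matrix.genes) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(matrix.barcodes) + "\n")
    if matrix.groups is not None:
        (directory / "groups.tsv").write_text(
            "\n".join(str(g) for g in matrix.groups) + "\n"
        )


def read_counts(directory) -> CountMatrix:
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(mtx)
    counts = sparse.csr_matrix(sio.mmread(str(mtx)))
    genes = (directory / "features.tsv").read_text().splitlines()
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    groups = None
    if (directory / "groups.tsv").exists():
        groups = pd.Series((directory / "groups.tsv").read_text().splitlines())
    return CountMatrix(counts=counts, genes=genes, barcodes=barcodes, groups=groups)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_CONFIG_SCHEMA: dict[str, set[str] | None] = {
    "seed": None,
    "input": None,
    "output": None,
    "log_level": None,
    "synth": {
        "photon_scale", "background_rate", "read_noise_sd", "marker_scale",
        "signal_model", "n_events", "fractions", "mean_2n", "cv",
        "doublet_rate", "debris_rate", "n_cells", "n_genes", "marker_fold",
        "lib_size_mean", "lowq_fraction",
    },
    "imaging": {"dapi_channel", "min_volume_um3", "rule", "k", "shell_radius_px"},
    "ploidy": {"windows", "calib"},
    "flow": {"anchor", "debris_fraction", "doublet_t", "windows"},
    "scrna": {
        "min_genes_per_cell", "max_mito_fraction", "min_cells_per_gene",
        "mito_prefix", "n_variable_genes", "n_components", "markers",
        "min_logfc", "alpha",
    },
}
_CALIB_KEYS = {"method", "anchor"}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    input: str | None = None
    output: str | None = None
    log_level: str = "INFO"
    blocks: dict[str, dict] = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "input": self.input, "output": self.output,
             "blocks": self.blocks},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(raw: dict) -> RunConfig:
    for key, val in raw.items():
        if key not in _CONFIG_SCHEMA:
            raise ValueError(f"unknown config key: {key!r}")
        allowed = _CONFIG_SCHEMA[key]
        if allowed is not None:
            if not isinstance(val, dict):
                raise ValueError(f"config block {key!r} must be a mapping")
            for sub in val:
                if sub not in allowed:
                    raise ValueError(f"unknown config key: {key}.{sub}")
            if key == "ploidy" and "calib" in val:
                for sub in val["calib"]:
                    if sub not in _CALIB_KEYS:
                        raise ValueError(f"unknown config key: ploidy.calib.{sub}")
    blocks = {k: dict(raw[k]) for k in raw if _CONFIG_SCHEMA[k] is not None}
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        input=raw.get("input"),
        output=raw.get("output"),
        log_level=str(raw.get("log_level", "INFO")),
        blocks=blocks,
    )


def read_config(path) -> RunConfig:
    """Read and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root of {path} must be a mapping")
    return validate_config(raw)


def write_json_report(path, payload: dict, config: RunConfig | None = None) -> None:
    """Write a JSON report stamped with the seed and config hash."""
    payload = dict(payload)
    if config is not None:
        payload["_meta"] = {"seed": config.seed, "config_hash": config.hash()}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
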
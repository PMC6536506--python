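"""Image and table I/O: multi-page TIFF stacks, ground-truth CSV, JSON sidecars."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass(eq=False)
class ImageStack:
    """A 3D intensity array (planes, y, x) with acquisition metadata.

    ``data`` is ordered (z, y, x) for focal stacks and (t, y, x) for
    time series; ``meta`` carries free-form acquisition information.
    """

    data: np.ndarray
    pixel_size_um: float | None = None
    z_spacing_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3D, got shape {self.data.shape}")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def z_range_um(self) -> float | None:
        """Focal range covered by the stack: (n_planes - 1) * z_spacing."""
        if self.z_spacing_um is None:
            return None
        return (self.n_planes - 1) * self.z_spacing_um


def read_stack(path: str | Path, axis_order: str = "zyx") -> ImageStack:
    """Read a multi-page TIFF as an ImageStack.

    A single-page TIFF is promoted to a depth-1 stack with a warning.
    Pixel size and z-spacing are taken from a ``<name>.json`` sidecar next
    to the file when present.
    """
    path = Path(path)
    if axis_order not in ("zyx", "tyx"):
        raise ValueError("axis_order must be 'zyx' or 'tyx'")
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shapes in {path.name}: {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:
        warnings.warn(f"{path.name}: single page read as depth-1 stack", stacklevel=2)
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected 2D or 3D TIFF, got shape {data.shape}")
    meta: dict = {"source": str(path), "axis_order": axis_order}
    pixel_size = z_spacing = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        pixel_size = side.get("pixel_size_um")
        z_spacing = side.get("z_spacing_um")
        meta.update(side)
    return ImageStack(data=data, pixel_size_um=pixel_size, z_spacing_um=z_spacing, meta=meta)


def write_stack(path: str | Path, stack: ImageStack, sidecar: bool = True) -> None:
    """Write an ImageStack as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data)
    if sidecar:
        side = {
            "pixel_size_um": stack.pixel_size_um,
            "z_spacing_um": stack.z_spacing_um,
            **{k: v for k, v in stack.meta.items() if _jsonable(v)},
        }
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_field(
    out_dir: str | Path,
    stack: ImageStack,
    autofluorescence: np.ndarray,
    truth,
    optics,
) -> dict[str, Path]:
    """Write one synthetic field: stack, segmentation image, truth CSV, optics JSON.

    The ground-truth table has columns cell_id, true_count, length_um.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out_dir / "stack.tif",
        "autofluorescence": out_dir / "autofluorescence.tif",
        "truth": out_dir / "truth.csv",
        "optics": out_dir / "optics.json",
    }
    write_stack(paths["stack"], stack)
    tifffile.imwrite(paths["autofluorescence"], autofluorescence)
    pd.DataFrame(
        {
            "cell_id": np.arange(len(truth.cells)),
            "true_count": truth.counts,
            "length_um": [round(c.total_length, 3) for c in truth.cells],
        }
    ).to_csv(paths["truth"], index=False)
    from dataclasses import asdict

    paths["optics"].write_text(json.dumps(asdict(optics), indent=2))
    return paths
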
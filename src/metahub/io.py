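"""NIfTI and table input/output plus the run configuration.

Volumes are exchanged as NIfTI-1 through nibabel; all in-memory analysis
uses flat gray-mask vectors (:class:`~metahub.grid.VoxelMap`). A volume is
only accepted when its shape matches the session grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridIncompatibilityError, VoxelGrid, VoxelMap

logger = logging.getLogger("metahub")


def write_volume(vmap: VoxelMap, path: str | Path) -> Path:
    """Write a masked map as a float32 NIfTI volume (0 outside the mask)."""
    path = Path(path)
    vol = vmap.grid.embed(vmap.values).astype(np.float32)
    img = nib.Nifti1Image(vol, vmap.grid.affine.astype(float))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, grid: VoxelGrid) -> VoxelMap:
    """Read a 3-D NIfTI volume onto the session grid."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3 or data.shape != tuple(grid.dims):
        raise GridIncompatibilityError(
            f"volume shape {data.shape} incompatible with grid {grid.dims}"
        )
    return VoxelMap(grid, grid.extract(np.asarray(data, dtype=float)))


def write_covariates(path: str | Path, subjects: list[str], ages, sexes) -> Path:
    """Write a per-cohort covariate sheet (TSV: subject, age, sex)."""
    path = Path(path)
    pd.DataFrame({"subject": subjects, "age": ages, "sex": sexes}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"subject", "age", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"covariate sheet missing columns: {sorted(missing)}")
    return df


@dataclasses.dataclass
class AnalysisConfig:
    """All pipeline thresholds in one place.

    Defaults are the study-protocol values: correlation cutoff 0.1,
    20-mm distance exclusion, alpha 0.001 with >200 mm^3 cluster extent,
    15-mm peak separation, 10,000 permutations.
    """

    r_threshold: float = 0.1
    min_distance_mm: float = 20.0
    alpha: float = 0.001
    min_cluster_mm3: float = 200.0
    peak_separation_mm: float = 15.0
    n_permutations: int = 10_000
    seed: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))

    def manifest(self) -> dict:
        """Run manifest: config hash + seed, for logging/provenance."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return {"config_sha256": hashlib.sha256(blob).hexdigest(), "seed": self.seed}
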
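"""Per-label volumetry with the canal+cyst merging convention.

Volumes are voxel counts times the voxel volume from the affine.  Because
canal cysts are anatomically part of the canal content (mucus-filled
cavities), the total canal volume reported for charting merges the cyst
label into the canal label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from scipy import ndimage

from .io import LABEL_NAMES, LabelVolume

__all__ = ["VolumetryResult", "compute_volumes"]


@dataclass
class VolumetryResult:
    volume_mm3: dict[int, float]
    canal_total_mm3: float
    cyst_count: int

    def to_dict(self) -> dict:
        return {
            "volume_mm3": {
                LABEL_NAMES.get(k, str(k)): v for k, v in self.volume_mm3.items()
            },
            "canal_total_mm3": self.canal_total_mm3,
            "cyst_count": self.cyst_count,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_volumes(vol: LabelVolume) -> VolumetryResult:
    """Voxel-counting volumes per non-background label; canal_total = canal + cysts."""
    vv = vol.voxel_volume_mm3()
    volumes = {
        code: float((vol.voxels == code).sum()) * vv for code in range(1, 6)
    }
    cyst_mask = vol.voxels == 4
    if cyst_mask.any():
        _, n = ndimage.label(cyst_mask, structure=ndimage.generate_binary_structure(3, 3))
    else:
        n = 0
    return VolumetryResult(
        volume_mm3=volumes,
        canal_total_mm3=volumes[1] + volumes[4],
        cyst_count=int(n),
    )
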
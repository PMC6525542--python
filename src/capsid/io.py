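"""File formats: capsomer tables (CSV), density maps (MRC), lattice-map
marker files (Chimera CMM XML) and run configurations (JSON).

Conventions
-----------
- Capsomer tables: comma-separated, dot decimal, UTF-8, mandatory header
  with at least ``particle_id,x,y,z`` (nm); optional ``class`` and
  ``degree`` columns.  Multiple particles per file are grouped by
  ``particle_id``.  Coordinates are written particle-centered (origin at
  the particle center of mass); readers accept any origin.
- MRC: MRC2014 via gemmi.  Voxel size is stored in Angstroms in the header
  and converted to nm on read (x0.1) / from nm on write (x10); likewise
  the ORIGIN record.  The in-memory axis convention is ``values[i, j, k]``
  with (i, j, k) = (x, y, z); header start-index records are ignored (MRC
  dialects disagree) with the ORIGIN record taking precedence.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .graph import CLASS_EDGE, CLASS_FIVEFOLD, CLASS_PSEUDO, CLASS_THREE, LatticeGraph
from .synth import CapsomerSet, DensityMap

__all__ = [
    "read_capsomer_table",
    "write_capsomer_table",
    "read_mrc",
    "write_mrc",
    "write_lattice_markers",
    "RunConfig",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("particle_id", "x", "y", "z")

# Lattice-map colour code: pentamers blue, true threefold hexamers yellow,
# pseudothreefold hexamers green; unclassifiable/boundary capsomers gray.
MARKER_COLORS = {
    CLASS_FIVEFOLD: (0.0, 0.0, 1.0),
    CLASS_THREE: (1.0, 1.0, 0.0),
    CLASS_PSEUDO: (0.0, 1.0, 0.0),
    CLASS_EDGE: (0.5, 0.5, 0.5),
}


def write_capsomer_table(
    sets: Union[CapsomerSet, Sequence[CapsomerSet]],
    path: Union[str, Path],
) -> None:
    """Write one or more capsomer sets to a CSV table, particle-centered."""
    if isinstance(sets, CapsomerSet):
        sets = [sets]
    frames = []
    for cs in sets:
        pos = cs.positions - cs.center
        frames.append(pd.DataFrame({
            "particle_id": cs.particle_id,
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_capsomer_table(path: Union[str, Path]) -> List[CapsomerSet]:
    """Read capsomer sets from a CSV table; one set per particle_id.

    Malformed numeric fields are reported with their 1-based file line
    number; missing required columns are fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"particle_id": str},
                     float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy()))[0]
        if bad.size:
            line = int(bad[0]) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"{path}: non-numeric or non-finite value in column "
                f"'{col}' on line {line}"
            )
        df[col] = vals
    out = []
    for pid, grp in df.groupby("particle_id", sort=False):
        out.append(CapsomerSet(
            particle_id=str(pid),
            positions=grp[["x", "y", "z"]].to_numpy(float),
            radius_nominal=None,
            source=str(path),
        ))
    return out


def write_mrc(dmap: DensityMap, path: Union[str, Path]) -> None:
    """Write a density map as MRC2014 (mode 2, float32); nm -> Angstrom."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    nx, ny, nz = dmap.shape
    vox_a = dmap.voxel_size * 10.0
    m.grid.unit_cell = gemmi.UnitCell(nx * vox_a, ny * vox_a, nz * vox_a,
                                      90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), dmap.origin * 10.0):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


def read_mrc(path: Union[str, Path]) -> DensityMap:
    """Read an MRC2014 map; Angstrom -> nm.

    The ORIGIN header record is honored; start-index records are ignored
    with a logged note.  Anisotropic voxels are rejected.
    """
    import gemmi

    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: corrupt or unreadable MRC file: {exc}") from exc
    mode = int(m.header_i32(4))
    if mode != 2:
        raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2)")
    values = np.array(m.grid, copy=True, dtype=float)
    uc = m.grid.unit_cell
    spacings = np.array([uc.a, uc.b, uc.c]) / np.array(values.shape)
    if not np.allclose(spacings, spacings[0], rtol=1e-4):
        raise ValueError(f"{path}: anisotropic voxels are not supported")
    starts = [m.header_i32(w) for w in (5, 6, 7)]
    if any(starts):
        logger.info("%s: ignoring non-zero start-index records %s "
                    "(ORIGIN takes precedence)", path, starts)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)]) * 0.1
    return DensityMap(values=values, voxel_size=float(spacings[0]) * 0.1,
                      origin=origin)


def write_lattice_markers(lg: LatticeGraph, path: Union[str, Path]) -> None:
    """Write a classified lattice graph as a Chimera marker-set XML file.

    One marker per capsomer, colored by symmetry class, plus one link per
    lattice edge.  Rejects unclassified graphs.
    """
    if not lg.classified:
        raise ValueError("classify the graph before writing markers")
    g = lg.graph
    spacing_guess = []
    root = ET.Element("marker_set", name=f"lattice_{lg.particle_id or 'map'}")
    for node in sorted(g):
        pos = g.nodes[node]["pos"]
        r, gg, b = MARKER_COLORS[g.nodes[node]["class_label"]]
        ET.SubElement(
            root, "marker", id=str(node),
            x=f"{pos[0]:.4f}", y=f"{pos[1]:.4f}", z=f"{pos[2]:.4f}",
            r=f"{r:g}", g=f"{gg:g}", b=f"{b:g}", radius="2.0",
            note=g.nodes[node]["class_label"],
        )
    for a, b_ in g.edges:
        ET.SubElement(root, "link", id1=str(a), id2=str(b_),
                      r="0.7", g="0.7", b="0.7", radius="0.4")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


@dataclasses.dataclass
class RunConfig:
    """Reproducible pipeline configuration; round-trips through JSON."""

    seed: int = 0
    cutoff_factor: float = 1.4
    projection: str = "sphere"
    voxel_nm: float = 1.0
    shrinkage_factor: float = 1.0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.projection not in ("sphere", "facet"):
            raise ValueError("projection must be 'sphere' or 'facet'")
        if not self.cutoff_factor > 0:
            raise ValueError("cutoff_factor must be positive")
        if not self.voxel_nm > 0:
            raise ValueError("voxel_nm must be positive")
        if not self.shrinkage_factor > 0:
            raise ValueError("shrinkage_factor must be positive")
        self.seed = int(self.seed)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
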
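"""Cell, cluster and sphere phantoms, and source-position sampling.

The cell is a set of nested spheres of unit-density water: a 14-µm-diameter
cell with a 10-nm membrane on its inner surface and a centred
10-µm-diameter nucleus.  A micrometastasis is modelled as 19 such cells on
a simple cubic lattice: one central cell, 6 first-neighbourhood cells in
direct contact (centre distance = one pitch) and 12 second-neighbourhood
cells (centre distance = pitch·√2).

Radionuclide decay positions are sampled uniformly in one of four source
regions per cell: on the cell surface, in the cytoplasm, in the nucleus, or
throughout the whole cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SOURCE_DISTRIBUTIONS",
    "CellModel",
    "ClusterModel",
    "SpherePhantom",
    "OverlapError",
    "make_cluster",
    "sample_source_positions",
    "sample_source_position",
    "region_of",
]

# the four source distributions considered
SOURCE_DISTRIBUTIONS = ("cell_surface", "cytoplasm", "nucleus", "whole_cell")


class OverlapError(ValueError):
    """Raised when cluster cells would overlap."""


@dataclass(frozen=True)
class CellModel:
    """Nested-sphere cell phantom (µm; unit-density water).

    The membrane is the 10-nm shell on the inside of the cell surface; the
    cytoplasm is the shell between nucleus and membrane.  The membrane is
    part of the cell for volume accounting but is never a source or target
    region.
    """

    cell_radius: float = 7.0
    nucleus_radius: float = 5.0
    membrane_thickness: float = 0.010
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    density: float = 1.0

    def __post_init__(self):
        if self.nucleus_radius + self.membrane_thickness >= self.cell_radius:
            raise ValueError("nucleus + membrane must fit inside the cell")

    @property
    def inner_membrane_radius(self) -> float:
        return self.cell_radius - self.membrane_thickness

    @property
    def volume(self) -> float:
        """Cell volume in µm³ (≈1436.8 at defaults)."""
        return 4.0 / 3.0 * np.pi * self.cell_radius**3

    @property
    def nucleus_volume(self) -> float:
        """Nucleus volume in µm³ (≈523.6 at defaults)."""
        return 4.0 / 3.0 * np.pi * self.nucleus_radius**3

    @property
    def cytoplasm_volume(self) -> float:
        return (
            4.0
            / 3.0
            * np.pi
            * (self.inner_membrane_radius**3 - self.nucleus_radius**3)
        )

    @property
    def membrane_volume(self) -> float:
        return (
            4.0
            / 3.0
            * np.pi
            * (self.cell_radius**3 - self.inner_membrane_radius**3)
        )

    def at(self, center) -> "CellModel":
        """Copy of this cell translated to ``center``."""
        return CellModel(
            cell_radius=self.cell_radius,
            nucleus_radius=self.nucleus_radius,
            membrane_thickness=self.membrane_thickness,
            center=tuple(float(c) for c in center),
            density=self.density,
        )


@dataclass(frozen=True)
class SpherePhantom:
    """Uniform water sphere (µm)."""

    radius: float
    density: float = 1.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass(frozen=True)
class ClusterModel:
    """19-cell simple-cubic micrometastasis phantom.

    ``labels[i]`` is the neighbourhood class of ``cells[i]``:
    ``central`` (1 cell), ``n1`` (6 cells at one pitch) or ``n2`` (12 cells
    at pitch·√2).
    """

    cells: tuple[CellModel, ...]
    labels: tuple[str, ...]
    pitch: float

    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.cells])

    def indices_of(self, label: str) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]

    def representative(self, label: str) -> int:
        """Index of one representative cell of a neighbourhood class."""
        return self.indices_of(label)[0]


def make_cluster(cell_template: CellModel | None = None, pitch: float = 14.0) -> ClusterModel:
    """Build the 19-cell simple cubic cluster.

    Cell centres: the origin, the 6 face positions (±p, 0, 0)… and the 12
    edge positions (±p, ±p, 0)….  ``pitch`` defaults to one cell diameter
    (cells in direct contact); a pitch below one cell diameter raises
    :class:`OverlapError`.
    """
    if cell_template is None:
        cell_template = CellModel()
    if pitch < 2 * cell_template.cell_radius:
        raise OverlapError(
            f"pitch {pitch} µm < cell diameter "
            f"{2 * cell_template.cell_radius} µm: cells would overlap"
        )
    p = float(pitch)
    centers = [(0.0, 0.0, 0.0)]
    labels = ["central"]
    for axis in range(3):
        for sign in (+1.0, -1.0):
            c = [0.0, 0.0, 0.0]
            c[axis] = sign * p
            centers.append(tuple(c))
            labels.append("n1")
    for a, b in ((0, 1), (0, 2), (1, 2)):
        for sa in (+1.0, -1.0):
            for sb in (+1.0, -1.0):
                c = [0.0, 0.0, 0.0]
                c[a], c[b] = sa * p, sb * p
                centers.append(tuple(c))
                labels.append("n2")
    cells = tuple(cell_template.at(c) for c in centers)
    return ClusterModel(cells=cells, labels=tuple(labels), pitch=p)


def _uniform_in_shell(r_inner: float, r_outer: float, n: int, rng) -> np.ndarray:
    """Uniform points in the shell r_inner <= r < r_outer (volume-weighted)."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = (r_inner**3 + rng.random(n) * (r_outer**3 - r_inner**3)) ** (1.0 / 3.0)
    return u * r[:, None]


def sample_source_positions(
    region: str,
    cell: CellModel,
    n: int,
    rng,
    surface_mode: str = "outer",
) -> np.ndarray:
    """Sample ``n`` decay positions (µm) uniformly in a source region.

    ``cell_surface`` places decays on the outer cell sphere by default;
    ``surface_mode`` may instead centre them mid-membrane (``mid``) or
    distribute them through the membrane shell (``shell``) — the 10-nm
    membrane makes the three indistinguishable at transport resolution.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if region == "cell_surface":
        if surface_mode == "outer":
            r_in = r_out = cell.cell_radius
        elif surface_mode == "mid":
            r_in = r_out = cell.cell_radius - 0.5 * cell.membrane_thickness
        elif surface_mode == "shell":
            r_in, r_out = cell.inner_membrane_radius, cell.cell_radius
        else:
            raise ValueError("surface_mode must be outer|mid|shell")
        if r_in == r_out:
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts = u * r_in
        else:
            pts = _uniform_in_shell(r_in, r_out, n, rng)
    elif region == "nucleus":
        pts = _uniform_in_shell(0.0, cell.nucleus_radius, n, rng)
    elif region == "cytoplasm":
        pts = _uniform_in_shell(
            cell.nucleus_radius, cell.inner_membrane_radius, n, rng
        )
    elif region == "whole_cell":
        pts = _uniform_in_shell(0.0, cell.cell_radius, n, rng)
    else:
        raise ValueError(
            f"unknown source region {region!r}: expected one of "
            f"{SOURCE_DISTRIBUTIONS}"
        )
    return pts + np.asarray(cell.center, dtype=float)


def sample_source_position(region: str, cell: CellModel, rng) -> np.ndarray:
    """Sample a single decay position; see :func:`sample_source_positions`."""
    return sample_source_positions(region, cell, 1, rng)[0]


def region_of(point, cell: CellModel) -> str:
    """Classify a point relative to one cell.

    Half-open radial shells: the nucleus boundary belongs to the cytoplasm
    and the inner membrane surface to the membrane; points at or beyond the
    cell radius are outside.
    """
    r = float(np.linalg.norm(np.asarray(point, dtype=float) - np.asarray(cell.center)))
    if r < cell.nucleus_radius:
        return "nucleus"
    if r < cell.inner_membrane_radius:
        return "cytoplasm"
    if r < cell.cell_radius:
        return "membrane"
    return "outside"
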
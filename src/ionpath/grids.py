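"""Regular free-energy grids over 1-3 collective-variable axes.

A :class:`FESGrid` stores free energies (kcal/mol) at the centers of a
regular grid.  Unsampled nodes carry NaN as an explicit sentinel; every
operation in the package treats NaN nodes as "no information", never as
zero free energy.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, thermal_energy

__all__ = ["GridAxis", "FESGrid"]


@dataclasses.dataclass(frozen=True)
class GridAxis:
    """One axis of a regular grid: ``n_bins`` bins spanning [minimum, maximum]."""

    name: str
    minimum: float
    maximum: float
    n_bins: int
    units: str = ""

    def __post_init__(self) -> None:
        if not self.maximum > self.minimum:
            raise ValueError(f"axis {self.name!r}: maximum must exceed minimum")
        if self.n_bins < 1:
            raise ValueError(f"axis {self.name!r}: need at least one bin")

    @property
    def spacing(self) -> float:
        return (self.maximum - self.minimum) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return self.minimum + self.spacing * (np.arange(self.n_bins) + 0.5)

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.minimum, self.maximum, self.n_bins + 1)

    def locate(self, value: float) -> int:
        """Bin index containing ``value`` (clipped to the axis range)."""
        idx = int(np.floor((value - self.minimum) / self.spacing))
        return min(max(idx, 0), self.n_bins - 1)


@dataclasses.dataclass
class FESGrid:
    """Free energies on a regular grid of 1-3 CV axes.

    ``values`` has one dimension per axis, in axis order.  NaN marks
    unsampled nodes.  ``normalize`` shifts the sampled minimum to zero.
    """

    axes: tuple[GridAxis, ...]
    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.axes = tuple(self.axes)
        self.values = np.asarray(self.values, dtype=float)
        expected = tuple(ax.n_bins for ax in self.axes)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match axes {expected}"
            )

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    def axis_index(self, name: str) -> int:
        for i, ax in enumerate(self.axes):
            if ax.name == name:
                return i
        raise KeyError(f"no axis named {name!r}; have {[a.name for a in self.axes]}")

    def sampled_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def normalize(self) -> "FESGrid":
        """Return a copy with the minimum over sampled nodes shifted to 0."""
        mask = self.sampled_mask()
        if not mask.any():
            raise ValueError("grid has no sampled nodes")
        shifted = self.values - np.nanmin(self.values)
        return FESGrid(self.axes, shifted, self.temperature)

    def locate(self, point: Sequence[float]) -> tuple[int, ...]:
        if len(point) != self.ndim:
            raise ValueError("point dimensionality does not match grid")
        return tuple(ax.locate(v) for ax, v in zip(self.axes, point))

    def node_coords(self, node: Sequence[int]) -> tuple[float, ...]:
        return tuple(ax.centers[i] for ax, i in zip(self.axes, node))

    def allclose(self, other: "FESGrid", atol: float = 1e-10) -> bool:
        if self.ndim != other.ndim or self.values.shape != other.values.shape:
            return False
        a, b = self.values, other.values
        both = np.isfinite(a) & np.isfinite(b)
        if not (np.isfinite(a) == np.isfinite(b)).all():
            return False
        return bool(np.allclose(a[both], b[both], atol=atol))
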
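"""Conversions between molecules/cell and media concentration.

The kinetic core is geometry-free: it tracks extracellular material as
cell-normalized molecules/cell.  Linking that to an ELISA-style ng/mL
read-out requires the experiment geometry — how many cells conditioned how
much media — and the protein's molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Avogadro

__all__ = ["Geometry", "molecules_per_cell_to_ng_per_ml", "concentration_to_molecules"]

#: Default molecular weight, g/mol.  The secreted sFLT1 glycoform runs at
#: ~90 kDa on immunoblots; glycoform mass varies, so 100 kDa is used as a
#: round default and geometry blocks in data files must state it explicitly.
DEFAULT_MOLECULAR_WEIGHT = 1e5


@dataclass(frozen=True)
class Geometry:
    """Experiment geometry for amount <-> concentration conversion."""

    n_cells: float
    media_volume_ml: float
    molecular_weight_g_per_mol: float = DEFAULT_MOLECULAR_WEIGHT

    def __post_init__(self) -> None:
        for name in ("n_cells", "media_volume_ml", "molecular_weight_g_per_mol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"geometry field {name!r} must be > 0")

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "media_volume_ml": self.media_volume_ml,
            "molecular_weight_g_per_mol": self.molecular_weight_g_per_mol,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Geometry":
        known = {"n_cells", "media_volume_ml", "molecular_weight_g_per_mol"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown geometry keys {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


def molecules_per_cell_to_ng_per_ml(amount, geom: Geometry):
    """Convert cell-normalized media content (molecules/cell) to ng/mL.

    total molecules = amount * n_cells; moles via Avogadro; mass via
    molecular weight; concentration over the media volume.
    """
    return (amount * geom.n_cells / (Avogadro * geom.media_volume_ml)
            * geom.molecular_weight_g_per_mol * 1e9)


def concentration_to_molecules(conc, geom: Geometry):
    """Exact inverse of :func:`molecules_per_cell_to_ng_per_ml`."""
    return (conc * 1e-9 / geom.molecular_weight_g_per_mol
            * Avogadro * geom.media_volume_ml / geom.n_cells)
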
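"""Standardized physicochemical property scales for the 20 amino acids.

Three raw per-residue properties are shipped as a packaged CSV — the
hydrophobicity and hydrophilicity values conventionally used with pseudo
amino acid composition, and the side-chain mass in daltons.  Before use,
each scale is standardized to mean 0 and population standard deviation 1
across the 20 residues, so the three properties contribute on a common,
dimensionless footing to the sequence-correlation factors.

A different raw table (same CSV layout) can be supplied to ``load_scales``
to swap property sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import AA_INDEX, AMINO_ACIDS


@dataclass(frozen=True)
class PropertyScales:
    """Standardized hydrophobicity (h1), hydrophilicity (h2) and side-chain
    mass (h3) vectors, indexed in ``AMINO_ACIDS`` order."""

    h1: np.ndarray
    h2: np.ndarray
    h3: np.ndarray
    # pairwise squared-difference correlation Φ, precomputed 20×20
    phi_matrix: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("h1", "h2", "h3"):
            v = getattr(self, name)
            if v.shape != (20,):
                raise ValueError(f"{name} must have exactly 20 entries")
            if abs(v.mean()) > 1e-9 or abs(v.std() - 1.0) > 1e-9:
                raise ValueError(f"{name} is not standardized to mean 0 / sd 1")
        if self.phi_matrix is None:
            phi = sum(
                (getattr(self, n)[None, :] - getattr(self, n)[:, None]) ** 2
                for n in ("h1", "h2", "h3")
            ) / 3.0
            object.__setattr__(self, "phi_matrix", phi)

    def value(self, scale: str, residue: str) -> float:
        """Scalar lookup, e.g. ``scales.value("h1", "A")``."""
        try:
            idx = AA_INDEX[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r}") from None
        return float(getattr(self, scale)[idx])


def standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale to population sd 1 (ddof=0) over the 20 residues."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValueError("constant property scale cannot be standardized")
    return (values - values.mean()) / sd


def load_scales(source: str | Path | None = None) -> PropertyScales:
    """Load and standardize the packaged (or a user-supplied) raw scale table.

    The CSV must have columns ``residue, hydrophobicity, hydrophilicity,
    side_chain_mass`` and exactly one row per standard amino acid.
    """
    if source is None:
        with resources.as_file(
            resources.files("psewave.data").joinpath("property_scales.csv")
        ) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(source)
    table = table.set_index("residue")
    missing = [aa for aa in AMINO_ACIDS if aa not in table.index]
    if missing:
        raise ValueError(f"scale table is missing residue rows: {missing}")
    table = table.loc[list(AMINO_ACIDS)]
    return PropertyScales(
        h1=standardize(table["hydrophobicity"].to_numpy()),
        h2=standardize(table["hydrophilicity"].to_numpy()),
        h3=standardize(table["side_chain_mass"].to_numpy()),
    )
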
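"""Pseudo amino acid composition (PseAAC) feature extraction.

Two representations of a protein sequence P = R₁R₂…R_L are provided.

Type 1 (parallel-correlation PseAAC, dimension 20+λ):

    p_u = f_u / (Σf_i + w Σθ_j)            for u = 1..20
    p_u = w θ_{u-20} / (Σf_i + w Σθ_j)     for u = 21..20+λ

where f_u are residue frequencies, w is a weight factor, and the
sequence-correlation factor θ_j at lag j averages a symmetric
squared-difference coupling over residue pairs:

    θ_j = (1/(L-j)) Σ_i Φ(R_i, R_{i+j})
    Φ(a, b) = ([H1(b)-H1(a)]² + [H2(b)-H2(a)]² + [H3(b)-H3(a)]²) / 3

with H1/H2/H3 the standardized hydrophobicity, hydrophilicity and
side-chain-mass scales.

Type 2 (amphiphilic / series-correlation PseAAC, dimension 20+2r) replaces
θ with paired hydrophobicity/hydrophilicity correlation factors per lag k:

    τ_{2k-1} = (1/(L-k)) Σ_i H¹(R_i)·H¹(R_{i+k})
    τ_{2k}   = (1/(L-k)) Σ_i H²(R_i)·H²(R_{i+k})

and normalizes the 20+2r components the same way (τ may be negative).  An
alternative coupling for the odd entries, H¹(R_i)·H²(R_{i+k}), is available
via ``eq6_as_printed=True`` (see docs/methods.md for why both exist).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scales import PropertyScales
from .sequences import AA_INDEX, AMINO_ACIDS, ProteinSequence


@dataclass(frozen=True)
class PseaacParams:
    """Extraction parameters.

    mode: "type1" or "type2"; lam (λ): number of type 1 correlation tiers;
    r: number of type 2 lag tiers (two components each); w: weight factor
    for the correlation block (0.05 is the customary default).
    """

    mode: str = "type1"
    lam: int = 2
    r: int = 2
    w: float = 0.05
    eq6_as_printed: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("type1", "type2"):
            raise ValueError(f"mode must be 'type1' or 'type2', got {self.mode!r}")
        if self.lam < 1 or self.r < 1:
            raise ValueError("lam and r must be >= 1")
        if not self.w > 0:
            raise ValueError("weight factor w must be > 0")

    @property
    def dimension(self) -> int:
        return 20 + self.lam if self.mode == "type1" else 20 + 2 * self.r

    @property
    def column_names(self) -> list[str]:
        base = list(AMINO_ACIDS)
        if self.mode == "type1":
            return base + [f"theta{j}" for j in range(1, self.lam + 1)]
        return base + [f"tau{j}" for j in range(1, 2 * self.r + 1)]


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    params: PseaacParams
    source_id: str


@dataclass
class FeatureMatrix:
    """N sequences × d feature values; rows in input-sequence order."""

    ids: list[str]
    values: np.ndarray
    params: PseaacParams | None = None
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValueError("values must be a 2-D array with one row per id")
        if self.columns is None and self.params is not None:
            self.columns = self.params.column_names
        if self.columns is not None and len(self.columns) != self.values.shape[1]:
            raise ValueError("column names do not match value width")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.columns or [f"c{i}" for i in range(self.values.shape[1])]
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"), columns=cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="id")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(float),
                   columns=[str(c) for c in df.columns])


def _indices(seq: ProteinSequence) -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[c] for c in seq.residues), dtype=np.intp,
                           count=len(seq.residues))
    except KeyError as e:
        raise ValueError(f"sequence {seq.id!r} contains nonstandard residue {e.args[0]!r}") from None


def correlation_phi(ri: str, rj: str, scales: PropertyScales) -> float:
    """Φ(ri, rj): mean squared difference of the three standardized scales."""
    for r in (ri, rj):
        if r not in AA_INDEX:
            raise ValueError(f"unknown residue {r!r}")
    return float(scales.phi_matrix[AA_INDEX[ri], AA_INDEX[rj]])


def theta(seq: ProteinSequence, lag: int, scales: PropertyScales) -> float:
    """Type 1 sequence-correlation factor at the given lag (mean of Φ)."""
    L = len(seq)
    if not 1 <= lag < L:
        raise ValueError(
            f"lag must satisfy 1 <= lag < L; got lag={lag} for sequence of length {L}"
        )
    idx = _indices(seq)
    return float(scales.phi_matrix[idx[:-lag], idx[lag:]].mean())


def tau(seq: ProteinSequence, r: int, scales: PropertyScales,
        eq6_as_printed: bool = False) -> np.ndarray:
    """Type 2 correlation factors: 2r values, a (hydrophobicity,
    hydrophilicity) product pair per lag 1..r."""
    L = len(seq)
    if not 1 <= r < L:
        raise ValueError(f"r must satisfy 1 <= r < L; got r={r} for sequence of length {L}")
    idx = _indices(seq)
    out = np.empty(2 * r)
    for k in range(1, r + 1):
        a, b = idx[:-k], idx[k:]
        first = scales.h1[a] * (scales.h2[b] if eq6_as_printed else scales.h1[b])
        out[2 * k - 2] = first.mean()
        out[2 * k - 1] = (scales.h2[a] * scales.h2[b]).mean()
    return out


def _frequencies(idx: np.ndarray) -> np.ndarray:
    return np.bincount(idx, minlength=20) / idx.size


def pseaac_type1(seq: ProteinSequence, params: PseaacParams,
                 scales: PropertyScales) -> FeatureVector:
    """Type 1 PseAAC vector of dimension 20+λ; components sum to 1."""
    if params.mode != "type1":
        raise ValueError("params.mode must be 'type1'")
    if params.lam >= len(seq):
        raise ValueError(
            f"sequence {seq.id!r}: λ={params.lam} must be less than the sequence length {len(seq)}"
        )
    idx = _indices(seq)
    f = _frequencies(idx)
    thetas = np.array([scales.phi_matrix[idx[:-j], idx[j:]].mean()
                       for j in range(1, params.lam + 1)])
    denom = f.sum() + params.w * thetas.sum()
    values = np.concatenate([f, params.w * thetas]) / denom
    return FeatureVector(values=values, params=params, source_id=seq.id)


def pseaac_type2(seq: ProteinSequence, params: PseaacParams,
                 scales: PropertyScales) -> FeatureVector:
    """Type 2 (amphiphilic) PseAAC vector of dimension 20+2r; components sum
    to 1 but the τ block may be negative."""
    if params.mode != "type2":
        raise ValueError("params.mode must be 'type2'")
    if params.r >= len(seq):
        raise ValueError(
            f"sequence {seq.id!r}: r={params.r} must be less than the sequence length {len(seq)}"
        )
    idx = _indices(seq)
    f = _frequencies(idx)
    taus = tau(seq, params.r, scales, eq6_as_printed=params.eq6_as_printed)
    denom = f.sum() + params.w * taus.sum()
    if denom <= 0:
        raise ValueError(
            f"sequence {seq.id!r}: degenerate type 2 normalization (denominator {denom:.6g} <= 0)"
        )
    values = np.concatenate([f, params.w * taus]) / denom
    return FeatureVector(values=values, params=params, source_id=seq.id)


def extract_vector(seq: ProteinSequence, params: PseaacParams,
                   scales: PropertyScales) -> FeatureVector:
    fn = pseaac_type1 if params.mode == "type1" else pseaac_type2
    return fn(seq, params, scales)


def extract_matrix(seqs: Sequence[ProteinSequence] | Iterable[ProteinSequence],
                   params: PseaacParams, scales: PropertyScales) -> FeatureMatrix:
    """Batch extraction: row i is the PseAAC vector of sequence i."""
    seqs = list(seqs)
    rows, ids = [], []
    for s in seqs:
        vec = extract_vector(s, params, scales)
        rows.append(vec.values)
        ids.append(s.id)
    if not rows:
        raise ValueError("no sequences to extract features from")
    return FeatureMatrix(ids=ids, values=np.vstack(rows), params=params)
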
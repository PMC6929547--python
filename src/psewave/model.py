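"""The fused-denoising structural-class model.

The end-to-end method extracts two pseudo amino acid composition blocks
from every sequence (type 1, 20+λ columns; type 2, 20+2r columns), denoises
each dataset-level block with its own 2-D wavelet spec, splices the two
denoised blocks into a 40+λ+2r-column matrix, and scores a K-nearest-
neighbor classifier by the jackknife test.  Six strategies expose the
ablations of that recipe:

    1  type 1 features only              (no denoising)
    2  type 2 features only              (no denoising)
    3  type 1 + 2-D wavelet denoising
    4  type 2 + 2-D wavelet denoising
    5  fuse first, then denoise the fused matrix
    6  denoise each block, then fuse     (the full method; default)

Dataset-level denoising treats the feature matrix (rows = proteins) as the
2-D input.  Because a wavelet transform along the sample axis presumes that
adjacent rows are similar, rows are first seriated by their leading
principal component (a label-free ordering), denoised, and restored to the
original order — making the pipeline invariant to the arbitrary row order
of an input file.

Denoising is transductive by default: the whole dataset matrix — training
and held-out rows alike — is denoised once before the jackknife, which is
how the method is ordinarily run but lets held-out rows influence the
denoised training features.  ``denoise_per_fold=True`` re-estimates the
threshold from each fold's training rows only (see docs/methods.md).

Usage follows the model/results convention::

    model = StructuralClassModel.from_files("seqs.fasta", "labels.tsv")
    res = model.fit()          # strategy 6, defaults λ=r=2, db4/sym4 level 5, K=1
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .knn import EvaluationReport, build_report, jackknife, knn_predict
from .pseaac import FeatureMatrix, PseaacParams, extract_matrix
from .scales import PropertyScales, load_scales
from .sequences import ProteinSequence, attach_labels, read_fasta, read_labels
from .wavelet import (WaveletSpec, decompose2d, denoise2d, reconstruct2d,
                      resolve_threshold, threshold_pyramid)

STRATEGIES = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the method, with the published defaults."""

    lam: int = 2
    r: int = 2
    w: float = 0.05
    spec_type1: WaveletSpec = field(default_factory=lambda: WaveletSpec("db4", 5, "default", None, "soft"))
    spec_type2: WaveletSpec = field(default_factory=lambda: WaveletSpec("sym4", 5, "default", None, "soft"))
    k_neighbors: int = 1
    strategy: int = 6
    residue_policy: str = "strict"
    eq6_as_printed: bool = False
    denoise_per_fold: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    def params(self, mode: str) -> PseaacParams:
        return PseaacParams(mode=mode, lam=self.lam, r=self.r, w=self.w,
                            eq6_as_printed=self.eq6_as_printed)


@dataclass
class FusedMatrix:
    """Type 1 block columns followed by type 2 block columns."""

    ids: list[str]
    values: np.ndarray
    columns: list[str]
    block_widths: tuple[int, int]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.columns)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def fuse(block1: FeatureMatrix, block2: FeatureMatrix,
         provenance: dict[str, str] | None = None) -> FusedMatrix:
    """Horizontally concatenate two feature blocks sharing row ids in
    identical order (type 1 columns first)."""
    if block1.ids != block2.ids:
        raise ValueError("blocks have mismatched row ids or row order")
    cols1 = block1.columns or [f"b1_{i}" for i in range(block1.values.shape[1])]
    cols2 = block2.columns or [f"b2_{i}" for i in range(block2.values.shape[1])]
    return FusedMatrix(
        ids=list(block1.ids),
        values=np.hstack([block1.values, block2.values]),
        columns=list(cols1) + list(cols2),
        block_widths=(block1.values.shape[1], block2.values.shape[1]),
        provenance=provenance or {},
    )


def pc1_order(values: np.ndarray) -> np.ndarray:
    """Row seriation: stable argsort of the rows' projections onto the
    leading principal component (sign fixed so the largest-magnitude
    projection is positive).

    A wavelet transform along the sample axis treats row adjacency as
    spatial continuity, so dataset-level 2-D denoising is only meaningful —
    and only invariant to the arbitrary order of an input file — if similar
    rows are placed next to each other first.  The projection uses the
    feature values alone, never the class labels.
    """
    X = np.asarray(values, dtype=float)
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    proj = Xc @ vt[0]
    if proj.size and proj[np.argmax(np.abs(proj))] < 0:
        proj = -proj
    return np.argsort(proj, kind="stable")


def denoise_matrix_rows(values: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """Seriate rows, 2-D denoise, restore the original row order."""
    order = pc1_order(values)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(order.size)
    return denoise2d(np.asarray(values, dtype=float)[order], spec)[inverse]


def _denoised(block: FeatureMatrix, spec: WaveletSpec) -> FeatureMatrix:
    return FeatureMatrix(ids=list(block.ids), values=denoise_matrix_rows(block.values, spec),
                         params=block.params, columns=block.columns)


class StructuralClassModel:
    """Structural-class predictor built from labelled protein sequences.

    Parameters
    ----------
    sequences : labelled ``ProteinSequence`` list (>= 2 per class).
    config : ``PipelineConfig``; defaults are the published settings.
    scales : property scales; the packaged standardized table by default.
    """

    def __init__(self, sequences: Sequence[ProteinSequence],
                 config: PipelineConfig | None = None,
                 scales: PropertyScales | None = None):
        self.sequences = list(sequences)
        if not self.sequences:
            raise ValueError("no sequences")
        unlabelled = [s.id for s in self.sequences if s.label is None]
        if unlabelled:
            raise ValueError(f"sequences without class labels: {unlabelled[:5]}")
        counts: dict = {}
        for s in self.sequences:
            counts[s.label] = counts.get(s.label, 0) + 1
        small = {str(c) for c, n in counts.items() if n < 2}
        if small:
            raise ValueError(
                f"each class needs at least 2 sequences for the jackknife; too few in: {sorted(small)}"
            )
        self.config = config or PipelineConfig()
        self.scales = scales or load_scales()
        self._blocks: dict[str, FeatureMatrix] = {}

    @classmethod
    def from_files(cls, fasta_path: str | Path, labels_path: str | Path,
                   config: PipelineConfig | None = None,
                   scales: PropertyScales | None = None) -> "StructuralClassModel":
        config = config or PipelineConfig()
        seqs = read_fasta(fasta_path, policy=config.residue_policy)
        return cls(attach_labels(seqs, read_labels(labels_path)), config=config, scales=scales)

    # -- feature blocks ------------------------------------------------------

    def features(self, mode: str) -> FeatureMatrix:
        """Raw (un-denoised) PseAAC block, cached per mode."""
        if mode not in self._blocks:
            self._blocks[mode] = extract_matrix(self.sequences,
                                                self.config.params(mode), self.scales)
        return self._blocks[mode]

    @property
    def labels(self) -> list:
        return [s.label for s in self.sequences]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    # -- fitting -------------------------------------------------------------

    def _classifier_input(self, strategy: int):
        cfg = self.config
        t1, t2 = self.features("type1"), self.features("type2")
        if strategy == 1:
            return t1, None
        if strategy == 2:
            return t2, None
        if strategy == 3:
            return _denoised(t1, cfg.spec_type1), None
        if strategy == 4:
            return _denoised(t2, cfg.spec_type2), None
        if strategy == 5:
            fused = fuse(t1, t2, provenance={"type1": "raw", "type2": "raw"})
            den = denoise_matrix_rows(fused.values, cfg.spec_type1)
            return replace(fused, values=den,
                           provenance={"type1": "fused-then-denoised",
                                       "type2": "fused-then-denoised"}), None
        if strategy == 6:
            return fuse(_denoised(t1, cfg.spec_type1), _denoised(t2, cfg.spec_type2),
                        provenance={"type1": "denoised", "type2": "denoised"}), None
        raise ValueError(f"unknown strategy {strategy}")

    def _per_fold_predictions(self, strategy: int) -> list:
        """Leakage-reduced jackknife: per fold, thresholds are estimated from
        the training rows only; the held-out row is denoised jointly with the
        training rows under that fixed threshold."""
        cfg = self.config
        t1, t2 = self.features("type1"), self.features("type2")
        if strategy == 3:
            blocks = [(t1.values, cfg.spec_type1)]
        elif strategy == 4:
            blocks = [(t2.values, cfg.spec_type2)]
        elif strategy == 5:
            blocks = [(np.hstack([t1.values, t2.values]), cfg.spec_type1)]
        elif strategy == 6:
            blocks = [(t1.values, cfg.spec_type1), (t2.values, cfg.spec_type2)]
        else:
            raise ValueError("per-fold denoising applies to strategies 3-6")
        labels = self.labels
        n = len(labels)
        # label-free row seriation, computed once per block on the raw features
        ordered = []
        for raw, spec in blocks:
            order = pc1_order(raw)
            inverse = np.empty_like(order)
            inverse[order] = np.arange(n)
            # full-matrix denoising is threshold-dependent; the seriated raw
            # matrix and its pyramid are reused across folds
            ordered.append((raw[order], spec, order, inverse))
        preds = []
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            train_parts, query_parts = [], []
            for raw_sorted, spec, order, inverse in ordered:
                pos = inverse[i]  # row i's position in seriated order
                mask[pos] = False
                pyr_train = decompose2d(raw_sorted[mask], spec)
                t = resolve_threshold(pyr_train, spec)
                train_den = reconstruct2d(threshold_pyramid(pyr_train, t, spec.threshold_fn))
                pyr_full = decompose2d(raw_sorted, spec)
                full_den = reconstruct2d(threshold_pyramid(pyr_full, t, spec.threshold_fn))
                # back to ascending original sample order (sample i omitted)
                orig_of_train = np.delete(order, pos)
                train_parts.append(train_den[np.argsort(orig_of_train)])
                query_parts.append(full_den[pos])
                mask[pos] = True
            rest_labels = labels[:i] + labels[i + 1:]
            preds.append(knn_predict(np.hstack(train_parts), rest_labels,
                                     np.concatenate(query_parts), cfg.k_neighbors))
        return preds

    def fit(self, strategy: int | None = None) -> "StructuralClassResults":
        """Run the chosen strategy end to end and evaluate by jackknife."""
        strategy = self.config.strategy if strategy is None else strategy
        if strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy}")
        if self.config.denoise_per_fold and strategy >= 3:
            matrix, _ = self._classifier_input(strategy)  # kept for inspection
            preds = self._per_fold_predictions(strategy)
        else:
            matrix, _ = self._classifier_input(strategy)
            preds = jackknife(matrix.values, self.labels, self.config.k_neighbors)
        report = build_report(preds, self.labels, ids=self.ids)
        return StructuralClassResults(model=self, strategy=strategy,
                                      report=report, matrix=matrix)


@dataclass
class StructuralClassResults:
    """Jackknife evaluation of one strategy, with the classifier input
    matrix retained for inspection."""

    model: StructuralClassModel
    strategy: int
    report: EvaluationReport
    matrix: FeatureMatrix | FusedMatrix

    @property
    def oa(self) -> float:
        return self.report.oa

    @property
    def per_class(self) -> dict:
        return self.report.per_class

    @property
    def predictions(self) -> list:
        return self.report.predictions

    def summary(self) -> str:
        cfg = self.model.config
        head = (
            f"Structural-class KNN (strategy {self.strategy}, K={cfg.k_neighbors}, "
            f"λ={cfg.lam}, r={cfg.r}, w={cfg.w})\n"
            f"classifier input: {self.matrix.shape[0]} × {self.matrix.shape[1]}\n"
        )
        return head + self.report.summary()


def run_strategy(seqs: Sequence[ProteinSequence], cfg: PipelineConfig,
                 strategy: int) -> StructuralClassResults:
    """Functional wrapper: build the model and fit one strategy."""
    return StructuralClassModel(seqs, config=cfg).fit(strategy=strategy)


def run_pipeline(seqs: Sequence[ProteinSequence],
                 cfg: PipelineConfig | None = None) -> StructuralClassResults:
    """Run the configured (default: full, strategy 6) method."""
    cfg = cfg or PipelineConfig()
    return StructuralClassModel(seqs, config=cfg).fit()
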
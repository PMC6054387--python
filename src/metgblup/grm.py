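"""Marker filtering and the VanRaden (method 1) genomic relationship matrix.

K = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z the dosage matrix column-centred
at twice the sample allele frequency. Missing dosages are mean-imputed per
marker before centring; allele frequencies come from the sample itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyPanelError, ModelError

__all__ = ["MarkerMatrix", "KinshipMatrix", "filter_markers", "compute_grm"]


@dataclass
class MarkerMatrix:
    """Lines x markers dosage matrix; entries in {0, 1, 2} or NaN for missing."""

    dosages: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        self.marker_ids = [str(s) for s in self.marker_ids]
        n, m = self.dosages.shape
        if n != len(self.line_ids) or m != len(self.marker_ids):
            raise ModelError("dosage shape does not match id lists")
        if len(set(self.line_ids)) != n:
            raise ModelError("duplicate line ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ModelError("dosages must be 0, 1, 2 or missing")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker alternate-allele frequency from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_lines(self, keep: list[str]) -> "MarkerMatrix":
        idx = [self.line_ids.index(s) for s in keep]
        return MarkerMatrix(self.dosages[idx], keep, list(self.marker_ids))


@dataclass
class KinshipMatrix:
    """Symmetric PSD additive relationship matrix with line labels."""

    values: np.ndarray
    line_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ModelError("kinship shape does not match line ids")
        scale = max(1.0, np.max(np.abs(self.values)))
        if np.max(np.abs(self.values - self.values.T)) > 1e-10 * scale:
            raise ModelError("kinship matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)
        # eigen check is O(n^3); for very large matrices rely on the
        # factorizations downstream, which fail loudly on an indefinite K
        if n <= 2000:
            wmin = np.linalg.eigvalsh(self.values)[0]
            if wmin < -1e-8 * scale:
                raise ModelError(
                    f"kinship matrix is not PSD (min eigenvalue {wmin:.3g})"
                )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, keep: list[str]) -> "KinshipMatrix":
        idx = [self.line_ids.index(s) for s in keep]
        return KinshipMatrix(self.values[np.ix_(idx, idx)], keep)


def filter_markers(
    mm: MarkerMatrix, maf_min: float = 0.05, max_missing: float = 0.20
) -> MarkerMatrix:
    """Drop markers with MAF <= maf_min or missing fraction >= max_missing.

    Both boundaries are exclusive for retention: a marker survives only if
    MAF > maf_min and missing fraction < max_missing. Marker order is
    preserved.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if not 0 <= max_missing <= 1:
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    p = mm.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    all_missing = np.isnan(p)
    maf = np.where(all_missing, 0.0, maf)
    keep = (maf > maf_min) & (mm.missing_fraction() < max_missing)
    if not keep.any():
        raise EmptyPanelError(
            f"all {mm.n_markers} markers removed by MAF>{maf_min}, "
            f"missing<{max_missing}"
        )
    return MarkerMatrix(
        mm.dosages[:, keep],
        list(mm.line_ids),
        [mid for mid, k in zip(mm.marker_ids, keep) if k],
    )


def compute_grm(mm: MarkerMatrix) -> KinshipMatrix:
    """VanRaden method-1 GRM from a (filtered) marker matrix."""
    X = mm.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    p = col_mean / 2.0
    denom = 2.0 * np.sum(p * (1 - p))
    if denom <= 0:
        raise ModelError("all markers monomorphic: VanRaden denominator is zero")
    Z = X - 2.0 * p
    K = (Z @ Z.T) / denom
    return KinshipMatrix(K, list(mm.line_ids))
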
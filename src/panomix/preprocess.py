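"""Quality control, transformation, imputation and block scaling.

Implements the preprocessing rules applied before integration: removal of
all-zero and low-variability features (coefficient of variation below 1%),
removal of features/samples with more than 20% missing entries, k-nearest-
neighbour imputation (k = 3), log transform of counts, beta-to-M conversion
of methylation proportions, CpG-island collapse by maximum connectivity,
per-column standardization with block weights 1/sqrt(p_l), and column
concatenation into the extended matrix.

Variances use denominator ``n`` throughout, so each standardized column has
sum of squares ``n`` and each weighted block total energy ``n`` — the
accounting the explained-variance (PVX) bookkeeping relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .blocks import ExtendedMatrix, OmicBlock, check_sample_alignment

__all__ = [
    "QCReport", "qc_filter", "knn_impute", "beta_to_m",
    "collapse_cpg_islands", "log_transform_counts",
    "standardize_and_weight", "concatenate_blocks",
]

_BETA_EPS = 1e-6


class EmptyBlockError(ValueError):
    """QC removed every feature; the report explains why."""

    def __init__(self, report: "QCReport"):
        self.report = report
        super().__init__("quality control removed every feature")


@dataclass
class QCReport:
    """Removals performed by :func:`qc_filter`, one reason per item."""

    removed_features: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    imputation_count: int = 0

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.removed_features:
            out[reason] = out.get(reason, 0) + 1
        return out


def qc_filter(block: OmicBlock, cv_min: float = 1.0,
              miss_max: float = 0.20) -> tuple[OmicBlock, QCReport]:
    """Drop uninformative features and overly missing features/samples.

    A feature is removed when (checked in this order, one reason each):

    * ``all_zero`` — every observed entry is zero;
    * ``high_missing`` — more than ``miss_max`` of its entries are missing;
    * ``low_cv`` — coefficient of variation ``sd/|mean| * 100`` over observed
      entries is below ``cv_min`` percent (features with mean exactly zero
      are left to the other rules).

    Samples with more than ``miss_max`` missing entries over the retained
    features are then removed.
    """
    if block.n_features == 0 or block.n_samples == 0:
        raise ValueError("qc_filter requires a non-empty block")
    V = block.values
    obs = ~np.isnan(V)
    report = QCReport()

    keep = np.ones(block.n_features, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(V, axis=0)
        sds = np.nanstd(V, axis=0)          # denominator n
    miss_frac = 1 - obs.mean(axis=0)
    for j, fid in enumerate(block.feature_ids):
        col_obs = V[obs[:, j], j]
        if col_obs.size and np.all(col_obs == 0):
            report.removed_features.append((fid, "all_zero"))
        elif miss_frac[j] > miss_max:
            report.removed_features.append((fid, "high_missing"))
        elif means[j] != 0 and not np.isnan(means[j]) \
                and abs(sds[j] / means[j]) * 100 < cv_min:
            report.removed_features.append((fid, "low_cv"))
        else:
            continue
        keep[j] = False

    if not keep.any():
        raise EmptyBlockError(report)

    V_kept = V[:, keep]
    sample_miss = np.isnan(V_kept).mean(axis=1)
    keep_s = sample_miss <= miss_max
    for i, sid in enumerate(block.sample_ids):
        if not keep_s[i]:
            report.removed_samples.append((sid, "high_missing"))

    out = OmicBlock(V_kept[keep_s], [s for s, k in zip(block.sample_ids, keep_s) if k],
                    block.features.loc[keep].reset_index(drop=True), block.name)
    return out, report


def knn_impute(block: OmicBlock, k: int = 3) -> OmicBlock:
    """Replace each missing entry by the mean over the k nearest samples.

    Distances are Euclidean over mutually observed features, scaled by the
    fraction observed, computed on per-column standardized values so no
    single high-variance feature dominates the neighbourhoods.
    """
    if k >= block.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    V = block.values
    if not np.isnan(V).any():
        return block.copy()
    if np.isnan(V).all(axis=0).any():
        raise ValueError("a feature is missing in every sample; run qc_filter first")
    mu = np.nanmean(V, axis=0)
    sd = np.nanstd(V, axis=0)
    sd[sd == 0] = 1.0
    Vs = (V - mu) / sd
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(Vs) * sd + mu
    out = block.copy()
    out.values = filled
    return out


def beta_to_m(beta, verbatim: bool = False):
    """Convert methylation beta proportions to M-values.

    Default is the logit-scale definition ``log2(beta / (1 - beta))``; with
    ``verbatim=True`` the plain ratio ``beta / (1 - beta)`` is returned
    instead.  Betas are clipped to ``[1e-6, 1 - 1e-6]``; values outside
    ``[0, 1]`` raise.
    """
    arr = np.asarray(beta, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, _BETA_EPS, 1 - _BETA_EPS)
    ratio = clipped / (1 - clipped)
    out = ratio if verbatim else np.log2(ratio)
    return out if out.shape else float(out)


def collapse_cpg_islands(probe_block: OmicBlock,
                         island_map: Mapping[str, str]) -> OmicBlock:
    """Summarize probe-level methylation at the island level.

    For each island with several probes the representative row is the probe
    maximizing connectivity — the sum of absolute Pearson correlations with
    the island's other probes across samples.  Singleton islands pass
    through; unmapped probes are dropped; an island whose probes all have
    zero variance falls back to its first probe with a warning.
    """
    fid = probe_block.feature_ids
    mapped = [(j, island_map[f]) for j, f in enumerate(fid) if f in island_map]
    if not mapped:
        raise ValueError("no probe maps to any island")
    islands: dict[str, list[int]] = {}
    for j, isl in mapped:
        islands.setdefault(isl, []).append(j)

    V = probe_block.values
    cols, rows = [], []
    for isl, idx in islands.items():
        if len(idx) == 1:
            rep = idx[0]
        else:
            sub = V[:, idx]
            sds = sub.std(axis=0)
            if np.all(sds == 0):
                warnings.warn(f"island {isl}: all probes constant; using first probe")
                rep = idx[0]
            else:
                with np.errstate(invalid="ignore"):
                    C = np.abs(np.corrcoef(sub.T))
                C = np.nan_to_num(C, nan=0.0)
                np.fill_diagonal(C, 0.0)
                rep = idx[int(np.argmax(C.sum(axis=1)))]
        cols.append(V[:, rep])
        rec = probe_block.features.iloc[rep].copy()
        rec["feature_id"] = isl
        rows.append(rec)
    feats = pd.DataFrame(rows).reset_index(drop=True)
    return OmicBlock(np.column_stack(cols), list(probe_block.sample_ids),
                     feats, probe_block.name)


def log_transform_counts(block: OmicBlock, pseudocount: float = 1.0) -> OmicBlock:
    """Natural log of ``value + pseudocount``; rejects negative input."""
    finite = block.values[np.isfinite(block.values)]
    if finite.size and finite.min() < 0:
        raise ValueError("log transform requires non-negative values")
    out = block.copy()
    out.values = np.log(block.values + pseudocount)
    return out


def standardize_and_weight(block: OmicBlock) -> OmicBlock:
    """Center each column, scale to unit sd (denominator n), divide by sqrt(p_l).

    After the transform each column has sum of squares ``n / p_l`` and each
    block contributes total energy ``n``, so no block dominates the
    concatenation regardless of its width.
    """
    V = block.values
    if np.isnan(V).any():
        raise ValueError("standardize_and_weight requires a complete block")
    sd = V.std(axis=0)
    if np.any(sd == 0):
        bad = [block.feature_ids[j] for j in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"zero-sd columns (run qc_filter first): {bad}")
    out = block.copy()
    out.values = (V - V.mean(axis=0)) / sd / np.sqrt(block.n_features)
    return out


def concatenate_blocks(blocks: Sequence[OmicBlock]) -> ExtendedMatrix:
    """Column-concatenate complete, sample-aligned blocks into ``X``."""
    if not blocks:
        raise ValueError("no blocks given")
    check_sample_alignment(blocks)
    for b in blocks:
        if np.isnan(b.values).any():
            raise ValueError(f"block '{b.name}' has missing values; impute first")
    values = np.hstack([b.values for b in blocks])
    feats = pd.concat([b.features.assign(block=b.name) for b in blocks],
                      ignore_index=True)
    return ExtendedMatrix(values, list(blocks[0].sample_ids), feats,
                          [b.n_features for b in blocks],
                          [b.name for b in blocks])
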
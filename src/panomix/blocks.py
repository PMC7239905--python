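"""Core data containers: per-assay omic blocks and their column concatenation.

An :class:`OmicBlock` holds one samples x features matrix from a single assay
(gene expression, methylation, copy number) together with per-feature
annotation.  Blocks sharing the same samples are column-concatenated into an
:class:`ExtendedMatrix`, the object the sparse factorization operates on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: recognised feature kinds
KINDS = ("GE", "METH_beta", "METH_m", "CNV", "other")

FEATURE_COLUMNS = ["feature_id", "gene_id", "chromosome", "kind"]


class AlignmentError(ValueError):
    """Sample ids differ or are differently ordered across blocks."""


@dataclass
class OmicBlock:
    """One samples x features matrix with per-feature annotation.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array; ``NaN`` marks missing entries.
    sample_ids
        Ordered, unique sample identifiers (length ``n_samples``).
    features
        Data frame with columns ``feature_id, gene_id, chromosome, kind``;
        one row per column of ``values``.
    name
        Short block label, e.g. ``"GE"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    features: pd.DataFrame
    name: str = "block"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        self.features = self.features.reset_index(drop=True)
        missing_cols = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing_cols:
            raise ValueError(f"feature annotation lacks columns {missing_cols}")
        if len(self.features) != p:
            raise ValueError(f"{len(self.features)} feature records for {p} columns")
        bad = set(self.features["kind"]) - set(KINDS)
        if bad:
            raise ValueError(f"unknown feature kinds {sorted(bad)}")
        beta = self.features["kind"].to_numpy() == "METH_beta"
        if beta.any():
            v = self.values[:, beta]
            v = v[np.isfinite(v)]
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError("METH_beta values must lie in [0, 1]")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return self.features["feature_id"].tolist()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "OmicBlock":
        return OmicBlock(self.values.copy(), list(self.sample_ids),
                         self.features.copy(), self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    # -- TSV round trip --------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write samples x features TSV (first column = sample id)."""
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, features: pd.DataFrame,
                 name: str = "block") -> "OmicBlock":
        df = pd.read_csv(path, sep="\t", index_col=0)
        feats = features.set_index("feature_id").loc[df.columns]
        feats.index.name = "feature_id"
        return cls(df.to_numpy(float), [str(s) for s in df.index],
                   feats.reset_index(), name)


@dataclass
class ExtendedMatrix:
    """Column concatenation ``X = [X_1, ..., X_L]`` of complete omic blocks."""

    values: np.ndarray
    sample_ids: list[str]
    features: pd.DataFrame          # includes a ``block`` column
    p_l: list[int]
    block_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("ExtendedMatrix must be complete (no NaN)")
        if self.values.shape[1] != sum(self.p_l):
            raise ValueError("sum of p_l must equal the number of columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def L(self) -> int:
        return len(self.p_l)

    @property
    def block_index(self) -> np.ndarray:
        """Per-column integer block id."""
        return np.repeat(np.arange(self.L), self.p_l)

    def block_slice(self, l: int) -> slice:
        start = int(np.sum(self.p_l[:l]))
        return slice(start, start + self.p_l[l])

    def with_values(self, values: np.ndarray) -> "ExtendedMatrix":
        return ExtendedMatrix(values, list(self.sample_ids),
                              self.features.copy(), list(self.p_l),
                              list(self.block_names))


# ---------------------------------------------------------------------------
# annotation / gene-set IO
# ---------------------------------------------------------------------------

def read_feature_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file lacks columns {missing}")
    return df


def write_feature_annotation(df: pd.DataFrame, path: str | Path) -> None:
    cols = FEATURE_COLUMNS + [c for c in ("block",) if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def check_sample_alignment(blocks: Sequence[OmicBlock]) -> None:
    """Raise :class:`AlignmentError` naming offending ids when blocks disagree."""
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            off = [s for s, r in zip(b.sample_ids, ref) if s != r]
            extra = sorted(set(b.sample_ids) ^ set(ref))
            detail = extra if extra else off[:10]
            raise AlignmentError(
                f"block '{b.name}' sample ids disagree with '{blocks[0].name}': "
                f"{detail[:10]}")
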
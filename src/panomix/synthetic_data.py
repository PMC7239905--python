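"""Synthetic multi-omic data with known tissue effects, factors and signatures.

The generator emulates the structure the integration method targets: ``L``
omic blocks over shared samples, dominated by tissue-specific mean shifts,
carrying a small number of sparse cross-block latent factors whose scores
cluster the samples, plus cluster-exclusive gene signatures with coupled
expression/copy-number shifts, i.i.d. block noise and (optionally) missing
entries.  Every planted quantity is returned as ground truth for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import OmicBlock, write_feature_annotation, write_gmt

__all__ = ["SynthConfig", "SyntheticTruth", "generate_multiomic", "mask_missing"]


@dataclass
class SynthConfig:
    """Generator settings.

    Defaults describe the bundled "tiny" benchmark: 120 samples, three blocks
    (GE / METH / CNV) of 200/300/150 features, three tissues whose mean shifts
    are three times the factor scale, four sparse factors expressing four
    sample clusters, and ten signature genes per cluster shifted by 1.5
    noise-standard-deviations in expression and copy number.
    """

    n_samples: int = 120
    n_tissues: int = 3
    block_sizes: tuple[int, ...] = (200, 300, 150)
    n_factors: int = 4
    support_fraction: float = 0.05
    factor_sd: float = 1.0
    tissue_sd: float = 3.0
    noise_sd: float | tuple[float, ...] = 0.5
    n_clusters: int = 4
    signature_size: int = 10
    signature_effect: float = 1.5    # shift in units of the block noise sd
    missing_fraction: float = 0.0
    cluster_spread: float = 0.35     # within-cluster sd of raw factor scores
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_sizes = tuple(int(p) for p in self.block_sizes)
        if self.n_samples < 1 or self.n_tissues < 1 or self.n_clusters < 1:
            raise ValueError("n_samples, n_tissues and n_clusters must be >= 1")
        if any(p < 1 for p in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        if self.n_factors < 0 or self.signature_size < 0:
            raise ValueError("n_factors and signature_size must be >= 0")
        if not (0 < self.support_fraction <= 1):
            raise ValueError("support_fraction must lie in (0, 1]")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_clusters > 1 and self.n_clusters > self.n_samples / 5:
            raise ValueError("need at least 5 samples per cluster")
        if self.signature_size * self.n_clusters > self._n_pairable_genes():
            raise ValueError(
                "signature_size * n_clusters exceeds the number of genes with "
                "both a GE and a CNV feature; enlarge the GE/CNV blocks")

    # genes carrying both a GE and a CNV feature (eligible for signatures)
    def _n_pairable_genes(self) -> int:
        kinds = self.block_kinds()
        ge = [p for p, k in zip(self.block_sizes, kinds) if k == "GE"]
        cnv = [p for p, k in zip(self.block_sizes, kinds) if k == "CNV"]
        if not ge or not cnv:
            return 0
        return min(ge[0], cnv[0])

    def block_kinds(self) -> tuple[str, ...]:
        L = len(self.block_sizes)
        if L == 1:
            return ("GE",)
        if L == 2:
            return ("GE", "CNV")
        return ("GE", "METH_m", "CNV") + tuple("other" for _ in range(L - 3))

    def noise_sds(self) -> tuple[float, ...]:
        if np.isscalar(self.noise_sd):
            return tuple(float(self.noise_sd) for _ in self.block_sizes)
        sds = tuple(float(s) for s in self.noise_sd)
        if len(sds) != len(self.block_sizes):
            raise ValueError("noise_sd must be scalar or one value per block")
        return sds


@dataclass
class SyntheticTruth:
    """Everything that was planted, for recovery checks."""

    tissue_labels: np.ndarray            # (n,) str
    cluster_labels: np.ndarray           # (n,) int
    factor_scores: np.ndarray            # (n, K)
    factor_loadings: np.ndarray          # (K, p) over the concatenated features
    support_mask: np.ndarray             # (K, p) bool
    signature_genes: dict[int, list[tuple[str, str]]]   # cluster -> [(gene, up/down)]
    missing_masks: list[np.ndarray]      # per block, bool

    @property
    def feature_support(self) -> np.ndarray:
        """Union of per-factor supports over the concatenated features."""
        if self.support_mask.size == 0:
            return np.zeros(self.factor_loadings.shape[1], dtype=bool)
        return self.support_mask.any(axis=0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tissue_labels": self.tissue_labels.tolist(),
            "cluster_labels": self.cluster_labels.tolist(),
            "factor_scores": self.factor_scores.tolist(),
            "factor_loadings": self.factor_loadings.tolist(),
            "support_mask": self.support_mask.astype(int).tolist(),
            "signature_genes": {str(c): g for c, g in self.signature_genes.items()},
            "missing_masks": [m.astype(int).tolist() for m in self.missing_masks],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            tissue_labels=np.asarray(d["tissue_labels"]),
            cluster_labels=np.asarray(d["cluster_labels"], dtype=int),
            factor_scores=np.asarray(d["factor_scores"], dtype=float),
            factor_loadings=np.asarray(d["factor_loadings"], dtype=float),
            support_mask=np.asarray(d["support_mask"], dtype=bool),
            signature_genes={int(c): [tuple(x) for x in g]
                             for c, g in d["signature_genes"].items()},
            missing_masks=[np.asarray(m, dtype=bool) for m in d["missing_masks"]],
        )


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Near-balanced random assignment of n items to k groups."""
    lab = np.arange(n) % k
    rng.shuffle(lab)
    return lab


def _spread_centroids(k: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy maximin pick of k well-separated standard-normal centroids."""
    cand = rng.standard_normal((max(50 * k, 100), dim))
    chosen = [cand[0]]
    for _ in range(k - 1):
        d = np.min(
            [np.linalg.norm(cand - c, axis=1) for c in chosen], axis=0)
        chosen.append(cand[int(np.argmax(d))])
    return np.asarray(chosen)


def _gene_map(config: SynthConfig) -> list[pd.DataFrame]:
    """Per-block feature annotation linking features to shared gene ids.

    One gene maps to one GE feature, one CNV feature (where block sizes
    allow) and one or two METH features; chromosomes are assigned cyclically.
    """
    kinds = config.block_kinds()
    n_genes = max(config.block_sizes)
    frames = []
    for l, (p, kind) in enumerate(zip(config.block_sizes, kinds)):
        prefix = {"GE": "ge", "METH_m": "meth", "CNV": "cnv"}.get(kind, f"b{l}")
        if kind in ("GE", "CNV", "other"):
            genes = np.arange(p)
        else:   # METH: cycle through genes so each gets 1-2 probes/islands
            genes = np.arange(p) % n_genes
        frames.append(pd.DataFrame({
            "feature_id": [f"{prefix}_{j:05d}" for j in range(p)],
            "gene_id": [f"g{g:05d}" for g in genes],
            "chromosome": [f"chr{(g % 22) + 1}" for g in genes],
            "kind": kind,
        }))
    return frames


def generate_multiomic(config: SynthConfig
                       ) -> tuple[list[OmicBlock], SyntheticTruth]:
    """Draw multi-block data ``X_l = tissue + Z W + signatures + noise``.

    Tissue effects are i.i.d. feature-wise mean shifts per tissue
    (``N(0, tissue_sd^2)``).  Factor scores are drawn around well-separated
    per-cluster centroids and standardized per factor; loadings are sparse
    with magnitudes in ``factor_sd * [0.5, 1.5]`` so every supported feature
    carries signal.  Signature genes receive a coupled-sign mean shift of
    ``signature_effect`` noise-sds on their GE and CNV features within their
    cluster, mirroring the positive covariation of expression and copy
    number the factorization is meant to expose.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    p_total = sum(config.block_sizes)
    kinds = config.block_kinds()
    noise = config.noise_sds()
    annotations = _gene_map(config)

    tissue_idx = _balanced_labels(n, config.n_tissues, rng)
    tissue_labels = np.array([f"tissue{t}" for t in tissue_idx])
    cluster_labels = _balanced_labels(n, config.n_clusters, rng)

    # tissue mean shifts, per tissue per concatenated feature
    tissue_means = rng.standard_normal((config.n_tissues, p_total)) * config.tissue_sd
    X = tissue_means[tissue_idx]

    # pick the signature genes first: factor supports must avoid every
    # feature of a signature gene, otherwise the planted "cluster-exclusive"
    # deregulation would be contradicted by factor structure on those genes
    signature_gene_ids: list[np.ndarray] = []
    if config.signature_size > 0:
        pool = rng.permutation(config._n_pairable_genes())
        for c in range(config.n_clusters):
            signature_gene_ids.append(
                pool[c * config.signature_size:(c + 1) * config.signature_size])
    all_feature_genes = np.concatenate(
        [ann["gene_id"].to_numpy() for ann in annotations])
    if signature_gene_ids:
        sig_names = {f"g{g:05d}" for ids in signature_gene_ids for g in ids}
        factor_candidates = np.flatnonzero(~np.isin(all_feature_genes,
                                                    list(sig_names)))
    else:
        factor_candidates = np.arange(p_total)

    # sparse latent factors whose scores separate the clusters
    K = config.n_factors
    if K > 0:
        centroids = _spread_centroids(config.n_clusters, K, rng)
        Z = centroids[cluster_labels] + \
            config.cluster_spread * rng.standard_normal((n, K))
        Z = Z - Z.mean(axis=0)
        Z = Z / Z.std(axis=0)
        support_size = max(1, round(config.support_fraction * p_total))
        support = np.zeros((K, p_total), dtype=bool)
        W = np.zeros((K, p_total))
        if support_size > factor_candidates.size:
            raise ValueError("factor support does not fit outside the "
                             "signature genes; shrink support_fraction or "
                             "signature_size")
        for k in range(K):
            idx = rng.choice(factor_candidates, size=support_size, replace=False)
            support[k, idx] = True
            mags = rng.uniform(0.5, 1.5, size=support_size)
            signs = rng.choice([-1.0, 1.0], size=support_size)
            W[k, idx] = config.factor_sd * mags * signs
        X = X + Z @ W
    else:
        Z = np.zeros((n, 0))
        W = np.zeros((0, p_total))
        support = np.zeros((0, p_total), dtype=bool)

    # cluster-exclusive signatures on paired GE/CNV features
    signature_genes: dict[int, list[tuple[str, str]]] = {}
    if config.signature_size > 0:
        ge_l = kinds.index("GE")
        cnv_l = kinds.index("CNV")
        offsets = np.concatenate([[0], np.cumsum(config.block_sizes)])
        for c in range(config.n_clusters):
            genes = signature_gene_ids[c]
            members = cluster_labels == c
            entries = []
            for g in genes:
                direction = rng.choice([-1.0, 1.0])
                for l in (ge_l, cnv_l):
                    col = offsets[l] + g     # gene g <-> feature g in GE/CNV
                    X[members, col] += direction * config.signature_effect * noise[l]
                entries.append((f"g{g:05d}", "up" if direction > 0 else "down"))
            signature_genes[c] = entries

    # block-wise noise, split into OmicBlocks
    blocks: list[OmicBlock] = []
    missing_masks: list[np.ndarray] = []
    sample_ids = [f"s{i:04d}" for i in range(n)]
    start = 0
    for l, (p, kind) in enumerate(zip(config.block_sizes, kinds)):
        vals = X[:, start:start + p] + noise[l] * rng.standard_normal((n, p))
        block = OmicBlock(vals, sample_ids, annotations[l], name=kind)
        if config.missing_fraction > 0:
            block, mask = mask_missing(block, config.missing_fraction,
                                       seed=int(rng.integers(2 ** 31)))
        else:
            mask = np.zeros((n, p), dtype=bool)
        blocks.append(block)
        missing_masks.append(mask)
        start += p

    truth = SyntheticTruth(tissue_labels, cluster_labels, Z, W, support,
                           signature_genes, missing_masks)
    return blocks, truth


def mask_missing(block: OmicBlock, fraction: float, seed: int
                 ) -> tuple[OmicBlock, np.ndarray]:
    """Blank ``round(fraction * n * p)`` entries uniformly at random.

    Returns the masked block and the boolean missing mask; deterministic in
    ``seed``.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    n, p = block.values.shape
    mask = np.zeros((n, p), dtype=bool)
    n_missing = round(fraction * n * p)
    if n_missing:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n * p, size=n_missing, replace=False)
        mask.flat[flat] = True
    out = block.copy()
    out.values[mask] = np.nan
    return out, mask


def write_dataset(blocks: list[OmicBlock], truth: SyntheticTruth,
                  out_dir: str | Path) -> None:
    """Write blocks as TSV, annotations as TSV, truth as JSON, signatures as GMT."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = []
    for block in blocks:
        block.to_tsv(out / f"{block.name}.tsv")
        ann.append(block.features.assign(block=block.name))
    write_feature_annotation(pd.concat(ann, ignore_index=True),
                             out / "features.tsv")
    truth.to_json(out / "truth.json")
    sets = {f"cluster{c}_signature": [g for g, _ in genes]
            for c, genes in truth.signature_genes.items()}
    if sets:
        write_gmt(sets, out / "signatures.gmt")
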
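"""End-to-end orchestration: preprocess -> project -> sSVD -> embed -> cluster
-> signatures, from a single YAML-able configuration, with TSV artifacts and
a JSON manifest (parameters, seeds, checksums) making reruns reproducible.

Stage order is fixed: log transform (optional) -> QC -> imputation ->
standardize/weight -> concatenate -> tissue projection -> sparse SVD ->
axis selection -> t-SNE -> DBSCAN -> gene scores -> signatures ->
phenotype association.  Each stage can be toggled off.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .blocks import OmicBlock, read_feature_annotation
from .embedding import dbscan_tune, tsne_embed
from .projection import apply_projection, build_indicator
from .signatures import (gene_scores, logrank_by_cluster,
                         phenotype_association, signature_funnel)
from .ssvd import fit_ssvd, scree_rank, select_informative_axes
from .synthetic_data import SynthConfig, SyntheticTruth, generate_multiomic, \
    write_dataset

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "PRESETS"]


@dataclass
class PipelineConfig:
    """All inputs and stage parameters for one pipeline run."""

    block_paths: dict[str, str]          # name -> TSV path
    features_path: str
    samples_path: str                    # sample table with tissue column
    out_dir: str
    truth_path: str | None = None        # optional planted truth for reporting

    # stage toggles
    log_ge: bool = False
    qc: bool = True
    impute: bool = True
    project: bool = True
    ssvd: bool = True
    embed: bool = True
    cluster: bool = True
    signatures: bool = True

    # stage parameters
    cv_min: float = 1.0
    miss_max: float = 0.20
    knn_k: int = 3
    tissue_column: str = "tissue"
    n_axes: int | str = "scree"          # integer or "scree"
    alpha: float = 0.5
    n_grid: int = 50
    drop_leading: int = 0
    perplexities: tuple[float, ...] = (50, 100)
    tsne_iter: int = 100_000
    min_pts: int = 10
    alpha_family: float = 0.05
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["block_paths"] = dict(raw["block_paths"])
        raw["perplexities"] = tuple(raw.get("perplexities", (50, 100)))
        return cls(**raw)

    def validate(self) -> None:
        paths = [*self.block_paths.values(), self.features_path, self.samples_path]
        if self.truth_path:
            paths.append(self.truth_path)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ari(a, b) -> float:
    from sklearn.metrics import adjusted_rand_score
    return float(adjusted_rand_score(a, b))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = read_feature_annotation(config.features_path)
    samples = pd.read_csv(config.samples_path, sep="\t", dtype={"sample_id": str})

    blocks: list[OmicBlock] = []
    for name, path in config.block_paths.items():
        feats = features[features["block"] == name] if "block" in features \
            else features
        blocks.append(OmicBlock.from_tsv(path, feats, name=name))

    manifest: dict = {"parameters": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()},
        "stages": []}

    # ---- per-block preprocessing -------------------------------------
    if config.log_ge:
        blocks = [pp.log_transform_counts(b) if b.name == "GE" else b
                  for b in blocks]
        manifest["stages"].append("log_ge")
    if config.qc:
        qc_out = []
        for b in blocks:
            fb, report = pp.qc_filter(b, cv_min=config.cv_min,
                                      miss_max=config.miss_max)
            qc_out.append(fb)
            manifest.setdefault("qc", {})[b.name] = report.reasons()
        blocks = qc_out
        # keep only samples surviving QC in every block
        shared = set(blocks[0].sample_ids)
        for b in blocks[1:]:
            shared &= set(b.sample_ids)
        for i, b in enumerate(blocks):
            keep = [s in shared for s in b.sample_ids]
            blocks[i] = OmicBlock(b.values[np.asarray(keep)],
                                  [s for s in b.sample_ids if s in shared],
                                  b.features, b.name)
        manifest["stages"].append("qc")
    if config.impute:
        blocks = [pp.knn_impute(b, k=config.knn_k) if np.isnan(b.values).any()
                  else b for b in blocks]
        manifest["stages"].append("impute")

    blocks = [pp.standardize_and_weight(b) for b in blocks]
    X = pp.concatenate_blocks(blocks)
    manifest["stages"].append("standardize_concatenate")

    samples = samples.set_index("sample_id").loc[X.sample_ids].reset_index()

    if config.project:
        design = build_indicator(samples[config.tissue_column].tolist())
        X = apply_projection(X, design)
        manifest["stages"].append("project")

    result = None
    if config.ssvd:
        if config.n_axes == "scree":
            sv = np.linalg.svd(X.values, compute_uv=False)
            n_axes = max(2, scree_rank(sv))
        else:
            n_axes = int(config.n_axes)
        result = fit_ssvd(X, n_axes=n_axes, alpha=config.alpha,
                          n_grid=config.n_grid)
        pd.DataFrame(result.Z, index=X.sample_ids).to_csv(
            out / "Z.tsv", sep="\t", float_format="%.10g")
        pd.DataFrame(result.W, columns=X.features["feature_id"]).to_csv(
            out / "W.tsv", sep="\t", float_format="%.10g")
        pd.DataFrame({"d": result.d, "lambda": result.lambdas}).to_csv(
            out / "d.tsv", sep="\t", index=False, float_format="%.10g")
        manifest["n_axes"] = int(n_axes)
        manifest["stages"].append("ssvd")

    labels = None
    truth = SyntheticTruth.from_json(config.truth_path) if config.truth_path \
        else None
    if config.embed and result is not None:
        axes = select_informative_axes(result, drop_leading=config.drop_leading)
        scores = result.Z[:, axes] * result.d[axes]   # scale-carrying scores
        emb = tsne_embed(scores, perplexities=config.perplexities,
                         n_iter=config.tsne_iter, seed=config.seed)
        pd.DataFrame(emb.coords, index=X.sample_ids, columns=["x", "y"]).to_csv(
            out / "coords.tsv", sep="\t", float_format="%.10g")
        manifest["embedding"] = {"perplexity": emb.perplexity,
                                 "cost": emb.cost, "n_iter": emb.n_iter}
        manifest["selected_axes"] = [int(a) for a in axes]
        manifest["stages"].append("embed")
        if config.cluster:
            assignment = dbscan_tune(emb.coords, min_pts=config.min_pts)
            labels = assignment.labels
            pd.DataFrame({"sample_id": X.sample_ids, "cluster": labels}).to_csv(
                out / "clusters.tsv", sep="\t", index=False)
            manifest["clustering"] = {
                "eps": assignment.eps, "min_pts": assignment.min_pts,
                "silhouette": assignment.silhouette,
                "n_clusters": assignment.n_clusters,
                "n_noise": int((labels == -1).sum())}
            manifest["stages"].append("cluster")
            if truth is not None:
                keep = labels != -1
                order = {s: i for i, s in
                         enumerate(pd.read_csv(config.samples_path, sep="\t")
                                   ["sample_id"].astype(str))}
                idx = [order[s] for s in X.sample_ids]
                manifest["ari_vs_planted_clusters"] = _ari(
                    truth.cluster_labels[idx][keep], labels[keep])
                manifest["ari_vs_tissues"] = _ari(
                    truth.tissue_labels[idx][keep], labels[keep])

    if config.signatures and result is not None and labels is not None \
            and len(set(labels[labels != -1])) >= 2:
        table = gene_scores(X, result)
        table.scores.to_csv(out / "gene_scores.tsv", sep="\t",
                            float_format="%.10g")
        anova, _, sigs = signature_funnel(table, labels,
                                          alpha_family=config.alpha_family)
        sigs.table.to_csv(out / "signatures.tsv", sep="\t", index=False)
        manifest["n_signature_genes"] = int(len(sigs.all_genes()))
        manifest["n_anova_significant"] = int(anova["significant"].sum())
        manifest["n_genes_scored"] = int(table.scores.shape[1])
        manifest["stages"].append("signatures")

        # phenotype association over any extra sample-table columns
        reserved = {"sample_id", config.tissue_column, "survival_time",
                    "survival_status"}
        covars = samples[[c for c in samples.columns if c not in reserved]]
        if covars.shape[1]:
            assoc = phenotype_association(covars, labels,
                                          alpha=config.alpha_family)
            assoc.omnibus.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
            manifest["n_significant_covariates"] = int(
                assoc.omnibus["significant"].sum())
        if {"survival_time", "survival_status"} <= set(samples.columns):
            surv = logrank_by_cluster(samples["survival_time"].to_numpy(float),
                                      samples["survival_status"].to_numpy(int),
                                      labels)
            surv.to_csv(out / "survival.tsv", sep="\t", index=False)
            manifest["logrank"] = {"statistic": surv.attrs["statistic"],
                                   "p": surv.attrs["p"]}

    manifest["checksums"] = {f.name: _sha256(f)
                             for f in sorted(out.glob("*.tsv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

PRESETS: dict[str, SynthConfig] = {
    # desk-scale benchmark: strong tissue structure on top of four
    # cluster-forming sparse factors and per-cluster signatures
    "tiny": SynthConfig(n_samples=120, n_tissues=3, block_sizes=(200, 300, 150),
                        n_factors=4, n_clusters=4, tissue_sd=3.0,
                        factor_sd=1.0, noise_sd=0.5, signature_size=10,
                        seed=42),
    "default": SynthConfig(n_samples=200, n_tissues=3,
                           block_sizes=(300, 450, 225), n_factors=4,
                           n_clusters=4, tissue_sd=3.0, factor_sd=1.0,
                           noise_sd=0.5, signature_size=10, seed=0),
    # no planted structure at all: the signature caller should come back
    # empty when scores are tested against labels carrying no signal
    "null": SynthConfig(n_samples=120, n_tissues=1, tissue_sd=0.0,
                        block_sizes=(100, 150, 80), n_factors=0,
                        n_clusters=3, signature_size=0, noise_sd=1.0,
                        seed=0),
}


def make_fixture(out_dir: str | Path, preset: str = "tiny",
                 seed: int | None = None) -> PipelineConfig:
    """Write a ready-to-run synthetic dataset plus a pipeline config."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset '{preset}'; choose from {list(PRESETS)}")
    cfg = dataclasses.replace(PRESETS[preset])
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    out = Path(out_dir)
    blocks, truth = generate_multiomic(cfg)
    write_dataset(blocks, truth, out)
    rng = np.random.default_rng(cfg.seed + 1)
    event = rng.exponential(5.0, cfg.n_samples)
    censor = rng.exponential(10.0, cfg.n_samples)
    pd.DataFrame({
        "sample_id": blocks[0].sample_ids,
        "tissue": truth.tissue_labels,
        "covariate_null": rng.standard_normal(cfg.n_samples),
        "survival_time": np.minimum(event, censor) + 1e-9,
        "survival_status": (event <= censor).astype(int),
    }).to_csv(out / "samples.tsv", sep="\t", index=False)
    pipe = PipelineConfig(
        block_paths={b.name: str(out / f"{b.name}.tsv") for b in blocks},
        features_path=str(out / "features.tsv"),
        samples_path=str(out / "samples.tsv"),
        truth_path=str(out / "truth.json"),
        out_dir=str(out / "results"),
        # perplexities scaled to the fixture's cluster sizes (~30 samples)
        perplexities=(15, 30),
        seed=cfg.seed,
    )
    pipe.to_yaml(out / "config.yaml")
    return pipe
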
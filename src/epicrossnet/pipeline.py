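"""End-to-end orchestration: simulate, select, encode, train, evaluate,
interpret, cross-test.

Each stage communicates through declared artifacts, all randomness flows
from a single global seed (stage seeds are CRC32 hashes of the seed and
stage name, kept below 2**31), and a manifest records the configuration
snapshot and SHA-256 digests of every written file so a rerun with an
identical configuration can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .encoding import EncodedDataset, assemble_dataset, encode_windows, normalize_features
from .evaluation import CrossTestMatrix, auroc, cluster_conditions, cross_test
from .exceptions import EpiCrossNetError
from .interpret import AttributionReport, BackgroundSet, attribute_genomic
from .io import write_fixture
from .models import CrossNetClassifier, SequenceConvClassifier
from .schema import default_schema
from .selection import (
    LabeledSiteSet,
    associate_catalog,
    balance_sample,
    filter_high_confidence,
    select_pan_cancer,
)
from .simulate import FeatureEffect, GeneratorParams, generate_catalog, generate_features

STAGES = ("simulate", "select", "encode", "train", "evaluate", "interpret",
          "crosstest")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2 ** 31)


@dataclass
class RunConfig:
    outdir: str = "run_output"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    min_studies: int = 1
    lor_cut: float = 2.0
    q_cut: float = 0.05
    dcn: dict = field(default_factory=dict)
    cnn: dict = field(default_factory=dict)
    interpret_n_permutations: int = 30
    interpret_background: int = 50
    interpret_max_samples: int = 200
    crosstest_pairs_per_family: int = 2
    crosstest_n_sites: int = 1200

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorParams.from_dict(d["generator"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    version: str
    digests: dict[str, str]
    metrics: dict
    wall_seconds: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


class JsonlLogger:
    """Structured JSONL event log (stage, level, message, metrics)."""

    def __init__(self, path: Optional[Path]):
        self.path = path
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text("")

    def event(self, stage: str, message: str, **metrics) -> None:
        if self.path is None:
            return
        with open(self.path, "a") as fh:
            fh.write(json.dumps(
                {"stage": stage, "level": "info", "message": message,
                 "metrics": metrics}) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_balanced_labels(labeled: LabeledSiteSet, seed: int) -> LabeledSiteSet:
    """Balance positives and negatives 1:1, trimming the larger side."""
    if len(labeled.negatives) >= len(labeled.positives):
        return balance_sample(labeled, seed)
    rng = np.random.default_rng(seed)
    pos = sorted(labeled.positives)
    keep = set(rng.choice(pos, size=len(labeled.negatives), replace=False).tolist())
    trimmed = LabeledSiteSet(keep, set(labeled.negatives), labeled.provenance,
                             dict(labeled.selection_params))
    return trimmed


def build_encoded_dataset(catalog, features, labeled: LabeledSiteSet,
                          seed: int) -> EncodedDataset:
    """Encode the labeled sites and split 8:1:1 with train-only scaling."""
    order = [sid for sid in catalog.site_ids
             if sid in labeled.positives or sid in labeled.negatives]
    labels = np.array([1 if sid in labeled.positives else 0 for sid in order])
    by_id = {s.site_id: s for s in catalog.sites}
    one_hot = encode_windows([by_id[sid].window_seq for sid in order])
    sub = features.subset(order)
    ds = assemble_dataset(one_hot, sub.values, labels, seed, site_ids=order)
    norm = normalize_features(sub, ds.mask("train"))
    ds.genomic = norm.values
    return ds


def run_core_experiment(
    params: Optional[GeneratorParams] = None,
    seed: int = 0,
    min_studies: int = 1,
    lor_cut: float = 2.0,
    q_cut: float = 0.05,
    dcn_kwargs: Optional[dict] = None,
    cnn_kwargs: Optional[dict] = None,
    train_genomic_only: bool = False,
    interpret_n_permutations: int = 30,
    interpret_background: int = 50,
    interpret_max_samples: int = 200,
    with_interpretation: bool = True,
) -> dict:
    """Simulate, select, encode, train and evaluate in memory.

    Returns a dict with the fitted models, test AUROCs, the selection
    recovery table and (optionally) the Shapley attribution report.
    """
    if params is None:
        params = GeneratorParams(seed=stage_seed(seed, "simulate"))
    catalog = generate_catalog(params)
    features = generate_features(catalog, params)
    if min_studies > 1:
        keep = set(filter_high_confidence(catalog, min_studies).site_ids)
        mask = np.array([sid in keep for sid in catalog.site_ids])
        catalog = catalog.subset(mask)
        features = features.subset(catalog.site_ids)

    results = associate_catalog(catalog)
    labeled = select_pan_cancer(results, lor_cut=lor_cut, q_cut=q_cut)
    balanced = make_balanced_labels(labeled, stage_seed(seed, "select"))
    ds = build_encoded_dataset(catalog, features, balanced,
                               stage_seed(seed, "encode"))

    out: dict = {"catalog": catalog, "features": features,
                 "association": results, "labeled": labeled,
                 "balanced": balanced, "dataset": ds}

    train_seed = stage_seed(seed, "train")
    X_tr, y_tr = ds.model_inputs("train", "integrated")
    X_va, y_va = ds.model_inputs("val", "integrated")
    X_te, y_te = ds.model_inputs("test", "integrated")
    dcn = CrossNetClassifier(random_state=train_seed, **(dcn_kwargs or {}))
    dcn.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
    out["integrated_model"] = dcn
    out["integrated_auroc"] = auroc(dcn.predict_proba(X_te)[:, 1], y_te)

    S_tr, _ = ds.model_inputs("train", "sequence_only")
    S_va, _ = ds.model_inputs("val", "sequence_only")
    S_te, _ = ds.model_inputs("test", "sequence_only")
    cnn = SequenceConvClassifier(random_state=train_seed, **(cnn_kwargs or {}))
    cnn.fit(S_tr, y_tr, X_val=S_va, y_val=y_va)
    out["sequence_model"] = cnn
    out["sequence_auroc"] = auroc(cnn.predict_proba(S_te)[:, 1], y_te)

    if train_genomic_only:
        G_tr, _ = ds.model_inputs("train", "genomic_only")
        G_va, _ = ds.model_inputs("val", "genomic_only")
        G_te, _ = ds.model_inputs("test", "genomic_only")
        gmodel = CrossNetClassifier(random_state=train_seed, **(dcn_kwargs or {}))
        gmodel.fit(G_tr, y_tr, X_val=G_va, y_val=y_va)
        out["genomic_model"] = gmodel
        out["genomic_auroc"] = auroc(gmodel.predict_proba(G_te)[:, 1], y_te)

    if with_interpretation:
        rng = np.random.default_rng(stage_seed(seed, "interpret"))
        tr_mask = ds.mask("train")
        bg_idx = rng.choice(np.flatnonzero(tr_mask),
                            size=min(interpret_background, int(tr_mask.sum())),
                            replace=False)
        background = BackgroundSet(ds.genomic[bg_idx])
        te_mask = np.flatnonzero(ds.mask("test"))
        if len(te_mask) > interpret_max_samples:
            te_mask = rng.choice(te_mask, size=interpret_max_samples, replace=False)
        n_sel = len(te_mask)
        seq_flat = ds.one_hot[te_mask].reshape(n_sel, -1)
        report = attribute_genomic(
            dcn, seq_flat, ds.genomic[te_mask], background,
            n_permutations=interpret_n_permutations,
            seed=stage_seed(seed, "interpret"),
            site_ids=[ds.site_ids[i] for i in te_mask],
            feature_names=features.schema.names,
        )
        out["attribution"] = report
    return out


FAMILY_B_EFFECTS: dict[str, FeatureEffect] = {
    # a disjoint planted signature used by the second condition family
    "phastcons_site": FeatureEffect("normal", (1.0, 1.0), (0.0, 1.0)),
    "rel_pos_utr5": FeatureEffect("beta", (5.0, 2.0), (2.0, 2.0)),
    "bind_mettl3": FeatureEffect("bernoulli", (0.7,), (0.3,)),
    "exon_count": FeatureEffect("poisson_plus1", (5.0,), (2.0,)),
    "housekeeping": FeatureEffect("bernoulli", (0.3,), (0.7,)),
}


def transfer_experiment(
    seed: int = 0,
    pairs_per_family: int = 2,
    n_sites: int = 1200,
    dcn_kwargs: Optional[dict] = None,
) -> dict:
    """Two condition families with shared vs disjoint feature effects.

    Each condition pair yields a balanced pan-cancer dataset; a
    genomic-only cross-network model per pair is cross-evaluated on every
    other pair's test split, and the transfer matrix is clustered at K=2.
    """
    from .simulate import DEFAULT_FEATURE_EFFECTS

    family_effects = {"A": DEFAULT_FEATURE_EFFECTS, "B": FAMILY_B_EFFECTS}
    models, datasets, truth = {}, {}, {}
    kwargs = {"epochs": 8}
    kwargs.update(dcn_kwargs or {})
    for fam, effects in family_effects.items():
        for k in range(pairs_per_family):
            cid = f"{fam}{k+1}"
            pseed = stage_seed(seed, f"crosstest:{cid}")
            params = GeneratorParams(
                n_sites=n_sites, feature_effects=dict(effects), seed=pseed,
            )
            catalog = generate_catalog(params)
            features = generate_features(catalog, params)
            labeled = select_pan_cancer(associate_catalog(catalog))
            balanced = make_balanced_labels(labeled, pseed)
            ds = build_encoded_dataset(catalog, features, balanced, pseed)
            G_tr, y_tr = ds.model_inputs("train", "genomic_only")
            G_va, y_va = ds.model_inputs("val", "genomic_only")
            G_te, y_te = ds.model_inputs("test", "genomic_only")
            model = CrossNetClassifier(random_state=pseed, **kwargs)
            model.fit(G_tr, y_tr, X_val=G_va, y_val=y_va)
            models[cid] = model
            datasets[cid] = (G_te, y_te)
            truth[cid] = fam
    matrix = cross_test(models, datasets)
    Z, labels = cluster_conditions(matrix, n_clusters=2)
    fams = np.array([truth[c] for c in matrix.condition_ids])
    # clustering recovers the families iff cluster labels partition by family
    recovered = all(
        len(np.unique(labels[fams == f])) == 1 for f in np.unique(fams)
    ) and len(np.unique([labels[fams == f][0] for f in np.unique(fams)])) == 2
    return {"matrix": matrix, "linkage": Z, "cluster_labels": labels,
            "families": fams, "recovered": bool(recovered)}


def run_all(config: RunConfig) -> RunManifest:
    """Execute the configured stages, writing artifacts and a manifest."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = JsonlLogger(outdir / "run.log.jsonl")
    metrics: dict = {}
    written: list[Path] = []
    stage = "init"
    try:
        do = set(config.stages)
        gen = dataclasses.replace(
            config.generator, seed=stage_seed(config.seed, "simulate"))
        res = run_core_experiment(
            params=gen,
            seed=config.seed,
            min_studies=config.min_studies,
            lor_cut=config.lor_cut,
            q_cut=config.q_cut,
            dcn_kwargs=config.dcn,
            cnn_kwargs=config.cnn,
            train_genomic_only=True,
            interpret_n_permutations=config.interpret_n_permutations,
            interpret_background=config.interpret_background,
            interpret_max_samples=config.interpret_max_samples,
            with_interpretation="interpret" in do,
        )
        stage = "simulate"
        if "simulate" in do:
            paths = write_fixture(res["catalog"], res["features"], gen,
                                  outdir / "fixture")
            written.extend(paths.values())
            logger.event(stage, "fixture written",
                         n_sites=len(res["catalog"].sites))
        stage = "select"
        if "select" in do:
            import pandas as pd

            df = pd.DataFrame([
                {"site_id": r.site_id, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                 "odds_ratio": r.odds_ratio, "log2_or": r.log2_or,
                 "p_value": r.p_value, "q_value": r.q_value,
                 "label": ("positive" if r.site_id in res["balanced"].positives
                           else "negative" if r.site_id in res["balanced"].negatives
                           else "unselected")}
                for r in res["association"]
            ])
            p = outdir / "association.tsv"
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
            metrics["n_positives"] = len(res["balanced"].positives)
            metrics["n_negatives"] = len(res["balanced"].negatives)
            logger.event(stage, "pan-cancer selection done", **{
                k: metrics[k] for k in ("n_positives", "n_negatives")})
        stage = "train"
        if "train" in do:
            p = outdir / "training_metrics.jsonl"
            with open(p, "w") as fh:
                for name in ("integrated", "sequence", "genomic"):
                    model = res.get(f"{name}_model")
                    if model is None:
                        continue
                    for ep, (tl, vl) in enumerate(zip(
                            model.history_["train_loss"],
                            model.history_["val_loss"])):
                        fh.write(json.dumps({
                            "model": name, "epoch": ep,
                            "train_loss": tl, "val_loss": vl}) + "\n")
            written.append(p)
            logger.event(stage, "models trained")
        stage = "evaluate"
        if "evaluate" in do:
            for name in ("integrated", "sequence", "genomic"):
                key = f"{name}_auroc"
                if key in res:
                    metrics[key] = res[key]
            p = outdir / "metrics.json"
            with open(p, "w") as fh:
                json.dump({k: v for k, v in metrics.items()}, fh, indent=1)
            written.append(p)
            logger.event(stage, "evaluation done", **{
                k: v for k, v in metrics.items() if k.endswith("auroc")})
        stage = "interpret"
        if "interpret" in do and "attribution" in res:
            rep: AttributionReport = res["attribution"]
            p1 = outdir / "shap_ranking.tsv"
            rep.ranking.to_csv(p1, sep="\t", index=False)
            p2 = outdir / "shap_beeswarm.tsv"
            rep.beeswarm.to_csv(p2, sep="\t", index=False)
            written.extend([p1, p2])
            metrics["top_feature"] = rep.ranking["feature"].iloc[0]
            logger.event(stage, "attribution done",
                         top_feature=metrics["top_feature"])
        stage = "crosstest"
        if "crosstest" in do:
            tr = transfer_experiment(
                seed=config.seed,
                pairs_per_family=config.crosstest_pairs_per_family,
                n_sites=config.crosstest_n_sites,
                dcn_kwargs=config.dcn,
            )
            import pandas as pd

            ct: CrossTestMatrix = tr["matrix"]
            p = outdir / "crosstest_matrix.tsv"
            pd.DataFrame(ct.matrix, index=ct.condition_ids,
                         columns=ct.condition_ids).to_csv(
                p, sep="\t", index_label="model")
            written.append(p)
            p2 = outdir / "crosstest_linkage.json"
            with open(p2, "w") as fh:
                json.dump({"linkage": tr["linkage"].tolist(),
                           "cluster_labels": tr["cluster_labels"].tolist(),
                           "families": tr["families"].tolist(),
                           "recovered": tr["recovered"]}, fh, indent=1)
            written.append(p2)
            metrics["crosstest_recovered"] = tr["recovered"]
            logger.event(stage, "cross-testing done", recovered=tr["recovered"])
    except EpiCrossNetError as exc:
        partial = RunManifest(config.to_dict(), __version__,
                              {str(p): _sha256(Path(p)) for p in written
                               if Path(p).exists()},
                              metrics, time.time() - t0)
        partial.to_json(outdir / "manifest.partial.json")
        raise EpiCrossNetError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        digests={str(Path(p).relative_to(outdir)): _sha256(Path(p))
                 for p in written},
        metrics=metrics,
        wall_seconds=time.time() - t0,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
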
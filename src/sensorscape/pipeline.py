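"""End-to-end orchestration: simulate/ingest -> extract -> cluster -> profile
-> metrics -> train -> explain, from a single JSON configuration.

Every stage writes its artifacts into a run directory and a manifest records a
SHA-256 checksum per file; re-running with the same configuration reproduces
the checksums of the deterministic stages (everything up to and including the
metrics stage, and — because the boosting backend is run in deterministic
single-thread mode — normally the model stages too, though only the former is
contractual).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import cluster as _cluster
from . import ecometrics as _eco
from . import explain as _explain
from . import io as _io
from . import models as _models
from . import profile as _profile
from . import simulate as _simulate
from .extract import HKConfig, excise_sensors, identify_hk

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "extract", "cluster", "profile", "metrics", "train", "explain")
_KNOWN_KEYS = {
    "seed",
    "simulate",
    "inputs",
    "cluster",
    "profile",
    "metrics",
    "train",
    "explain",
    "figures",
}


class ConfigError(ValueError):
    """The run configuration is malformed."""


@dataclass
class RunConfig:
    """Validated pipeline configuration with per-stage parameter blocks.

    Exactly one of ``simulate`` (synthetic corpus parameters) or ``inputs``
    (paths to annotation/protein/metadata files) must be present.  Unknown top
    -level keys are rejected so typos fail fast.
    """

    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    cluster: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    explain: dict = field(default_factory=dict)
    figures: bool = False

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**{k: raw[k] for k in raw})
        if (cfg.simulate is None) == (cfg.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' is required")
        if cfg.inputs is not None:
            report = validate_inputs(cfg.inputs)
            if report["errors"]:
                raise ConfigError("invalid inputs:\n" + "\n".join(report["errors"]))
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def provenance(self) -> dict:
        from . import __version__

        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(_KNOWN_KEYS)}, sort_keys=True, default=str
        )
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "package_version": __version__,
            "seed": self.seed,
        }


def validate_inputs(paths: Mapping[str, str]) -> dict:
    """Schema-check annotation TSV, metadata TSV and FASTA inputs.

    Returns ``{"errors": [...], "counts": {...}}`` with per-line diagnostics
    for coordinate violations and duplicate FASTA ids.
    """
    errors: list[str] = []
    counts: dict[str, int] = {}
    ann = paths.get("annotations")
    if ann:
        if not Path(ann).exists():
            errors.append(f"{ann}: file not found")
        else:
            df = pd.read_csv(ann, sep="\t")
            missing = set(_io.ANNOTATION_COLUMNS) - set(df.columns)
            if missing:
                errors.append(f"{ann}: missing columns {sorted(missing)}")
            else:
                counts["annotation_rows"] = len(df)
                has_acc = df["pfam_acc"].notna() & (df["pfam_acc"] != "")
                bad = df[has_acc & (df["ali_end"] < df["ali_start"])]
                for idx in bad.index:
                    errors.append(f"{ann}: line {idx + 2}: ali_end < ali_start")
                bad = df[has_acc & (df["ali_end"] > df["protein_length"])]
                for idx in bad.index:
                    errors.append(f"{ann}: line {idx + 2}: hit beyond protein length")
    meta = paths.get("metadata")
    if meta:
        if not Path(meta).exists():
            errors.append(f"{meta}: file not found")
        else:
            try:
                mdf = _io.read_metadata(meta)
                counts["metadata_rows"] = len(mdf)
                if mdf["metagenome_id"].duplicated().any():
                    errors.append(f"{meta}: duplicate metagenome ids")
            except Exception as exc:  # noqa: BLE001 - report, don't crash
                errors.append(f"{meta}: {exc}")
    for key in ("proteins", "sensors"):
        fa = paths.get(key)
        if fa:
            if not Path(fa).exists():
                errors.append(f"{fa}: file not found")
                continue
            seen: set[str] = set()
            nrec = 0
            for line in Path(fa).read_text().splitlines():
                if line.startswith(">"):
                    nrec += 1
                    rid = line[1:].split()[0]
                    if rid in seen:
                        errors.append(f"{fa}: duplicate FASTA id {rid}")
                    seen.add(rid)
            counts[f"{key}_records"] = nrec
    return {"errors": errors, "counts": counts}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _specs_from_config(block: dict) -> tuple[list[_simulate.EcosystemSpec], dict]:
    eco = [
        _simulate.EcosystemSpec(**spec) for spec in block.get("ecosystems", [])
    ]
    pool_kwargs = block.get("pool", {})
    return eco, pool_kwargs


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and return the manifest.

    Any stage failure propagates with the stage named; artifacts written by
    earlier stages stay on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"provenance": cfg.provenance(), "stages": {}}

    def record(stage: str, files: Mapping[str, Path], **info) -> None:
        manifest["stages"][stage] = {
            "files": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in files.items()},
            **info,
        }

    stage = "simulate"
    try:
        if cfg.simulate is not None:
            specs, pool_kwargs = _specs_from_config(cfg.simulate)
            pool = _simulate.make_family_pool(seed=cfg.seed, **pool_kwargs)
            corpus = _simulate.generate_corpus(specs, pool, global_seed=cfg.seed)
            sim_dir = outdir / "simulate"
            files = corpus.write(sim_dir)
            record(stage, files, n_genes=len(corpus.genes), n_domains=len(corpus.domains))
            genes, proteins, meta = corpus.genes, corpus.proteins, corpus.metadata
            hk_cfg = corpus.hk_config
        else:
            genes = _io.read_annotations(cfg.inputs["annotations"])
            proteins = _io.read_fasta(cfg.inputs["proteins"])
            meta = _io.read_metadata(cfg.inputs["metadata"])
            sensor_accs = frozenset(
                Path(cfg.inputs["sensor_accessions"]).read_text().split()
            )
            hk_cfg = HKConfig(sensor_accs=sensor_accs)
            record("simulate", {}, ingested=True, n_genes=len(genes))

        stage = "extract"
        hks = identify_hk(genes, hk_cfg)
        domains = [d for hk in hks for d in excise_sensors(hk, proteins[hk.gene_id], hk_cfg)]
        ext_dir = outdir / "extract"
        ext_dir.mkdir(exist_ok=True)
        _io.write_sensor_fasta(domains, ext_dir / "sensors.faa")
        _io.write_annotations(hks, ext_dir / "hk_genes.tsv")
        record(stage, {"sensors": ext_dir / "sensors.faa", "hk_genes": ext_dir / "hk_genes.tsv"},
               n_hk=len(hks), n_domains=len(domains))
        logger.info("extract: %d genes -> %d HKs -> %d sensor domains", len(genes), len(hks), len(domains))

        stage = "cluster"
        unique, multiplicity = _cluster.dedup(domains)
        params = _cluster.ClusterParams(**cfg.cluster)
        assignment = _cluster.cluster_greedy(unique, params, seed=cfg.seed, multiplicity=multiplicity)
        clu_dir = outdir / "cluster"
        clu_dir.mkdir(exist_ok=True)
        _cluster.write_cluster_tsv(assignment, clu_dir / "clusters.tsv")
        record(stage, {"clusters": clu_dir / "clusters.tsv"},
               n_unique=len(unique), n_clusters=assignment.n_clusters())
        logger.info("cluster: %d domains -> %d unique -> %d clusters",
                    len(domains), len(unique), assignment.n_clusters())

        stage = "profile"
        totals = _profile.gene_totals_from_records(genes)
        matrix = _profile.build_matrix(domains, assignment, totals, meta)
        filtered = _profile.filter_clusters(matrix, cfg.profile.get("min_prevalence", 1))
        label_field = cfg.profile.get("label_field", "ecosystem")
        filtered = _profile.filter_samples(
            filtered,
            min_per_class=cfg.profile.get("min_per_class", 0),
            drop_labels=set(cfg.profile.get("drop_labels", ["Unclassified"])),
            label_field=label_field,
        )
        prof_dir = outdir / "profile"
        prof_dir.mkdir(exist_ok=True)
        files = matrix.write(prof_dir / "matrix")
        files.update({f"filtered_{k}": v for k, v in filtered.write(prof_dir / "matrix_filtered").items()})
        record(stage, files, n_samples=filtered.n_samples, n_clusters=filtered.n_clusters)

        stage = "metrics"
        met_dir = outdir / "metrics"
        met_dir.mkdir(exist_ok=True)
        metrics = _eco.ecosystem_metrics(matrix, by=label_field)
        metrics.to_csv(met_dir / "ecosystem_metrics.tsv", sep="\t")
        files = {"metrics": met_dir / "ecosystem_metrics.tsv"}
        if metrics.shape[0] >= 2:
            corr = _eco.ecosystem_correlation(filtered, by=label_field)
            corr.to_csv(met_dir / "ecosystem_correlation.tsv", sep="\t")
            files["correlation"] = met_dir / "ecosystem_correlation.tsv"
        if cfg.figures:
            _eco.plot_richness_scatter(metrics, met_dir / "richness.png")
        record(stage, files, n_ecosystems=metrics.shape[0])

        stage = "train"
        train_dir = outdir / "train"
        train_dir.mkdir(exist_ok=True)
        mcfg = _models.ModelConfig(
            task=cfg.train.get("task", "multiclass"),
            grid=cfg.train.get("grid", {"learning_rate": [0.1], "depth": [6], "l2_leaf_reg": [3.0]}),
            n_estimators=cfg.train.get("n_estimators", 200),
            seed=cfg.seed,
        )
        labels = filtered.meta[label_field]
        spec = _models.SplitSpec(seed=cfg.seed)
        train_ids, test_ids, val_ids = _models.split(labels, spec)
        X = filtered.values
        best, model = _models.grid_search(
            X.loc[train_ids], labels.loc[train_ids], X.loc[val_ids], labels.loc[val_ids], mcfg
        )
        report = _models.evaluate(model, X.loc[test_ids], labels.loc[test_ids], best)
        (train_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
        report.confusion.to_csv(train_dir / "confusion.tsv", sep="\t")
        model.booster_.save_model(str(train_dir / "model.txt"))
        (train_dir / "model.json").write_text(json.dumps(
            {"best_params": best, "seed": cfg.seed,
             "split_sizes": [len(train_ids), len(test_ids), len(val_ids)]}, indent=1))
        record(stage, {"report": train_dir / "report.json", "confusion": train_dir / "confusion.tsv",
                       "model": train_dir / "model.txt", "sidecar": train_dir / "model.json"},
               accuracy=report.accuracy)

        stage = "explain"
        exp_dir = outdir / "explain"
        exp_dir.mkdir(exist_ok=True)
        attr = _explain.attribute(model, X.loc[test_ids])
        attr.write(exp_dir / "attributions.tsv")
        ranking = _explain.rank_features(attr, scope="global")
        ranking.to_csv(exp_dir / "feature_ranking.tsv", sep="\t")
        files = {"attributions": exp_dir / "attributions.tsv", "ranking": exp_dir / "feature_ranking.tsv"}
        if cfg.figures:
            _explain.plot_heatmap(filtered, exp_dir / "heatmap.png")
        record(stage, files, top_feature=str(ranking.index[0]))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def deterministic_checksums(manifest: dict) -> dict[str, str]:
    """Checksums of the contractually deterministic stages of a manifest."""
    out: dict[str, str] = {}
    for stage in ("simulate", "extract", "cluster", "profile", "metrics"):
        for name, entry in manifest["stages"].get(stage, {}).get("files", {}).items():
            out[f"{stage}/{name}"] = entry["sha256"]
    return out
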
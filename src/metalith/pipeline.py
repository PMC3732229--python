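"""Config-driven orchestration: simulate/load -> filter -> normalize ->
differential statistics -> PLS-DA -> network -> exports, with a checksummed
run manifest so identical configs reproduce identical outputs."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .diffstats import differential_table
from .multivariate import autoscale, cross_validate, nipals_pls
from .netmap import (
    map_statistics,
    merge_networks,
    rpair_edges,
    similarity_edges,
    write_node_attributes,
    write_sif,
)
from .preprocess import DesignGroupSpec, presence_filter, sum_normalize
from .study_io import (
    IntensityMatrix,
    read_annotations,
    read_intensity_table,
    read_rpair_table,
    write_differential_table,
    write_intensity_table,
)
from .synthetic import (
    SyntheticTruth,
    default_truth,
    generate_compounds,
    generate_rpairs,
    generate_study,
    truth_sidecar,
)

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline"]


class PipelineError(Exception):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONTRASTS = [
    {
        "name": "genotype_cerebellum",
        "stratum": {"tissue": "cerebellum", "treatment": "control"},
        "numerator": {"genotype": "SCA1"},
        "denominator": {"genotype": "WT"},
    },
    {
        "name": "lithium_wt_cerebellum",
        "stratum": {"tissue": "cerebellum", "genotype": "WT"},
        "numerator": {"treatment": "lithium"},
        "denominator": {"treatment": "control"},
    },
]


@dataclass
class RunConfig:
    """Pipeline settings; exactly one of (intensity_path, simulate) is set."""

    output_dir: str = "metalith_run"
    intensity_path: str | None = None
    annotation_path: str | None = None
    rpair_path: str | None = None
    simulate: dict | None = None  # {"seed": int, ...} overrides for the generator
    design_factors: tuple = ("tissue", "genotype", "treatment")
    filter_threshold: float = 0.5
    filter_mode: str = "any_group"
    contrasts: list = field(default_factory=lambda: [dict(c) for c in DEFAULT_CONTRASTS])
    alpha: float = 0.05
    pls: dict = field(
        default_factory=lambda: {
            "stratum": {"tissue": "cerebellum"},
            "class_factors": ["genotype", "treatment"],
            "n_components": 3,
            "k": 7,
            "seed": 0,
            "max_iter": 50,
            "tol": 1e-4,
        }
    )
    network: dict = field(
        default_factory=lambda: {
            "threshold": 0.5,
            "size_range": [20.0, 80.0],
            "n_clusters": 4,
            "n_rpairs": 20,
            "contrast": "lithium_wt_cerebellum",
        }
    )

    def validate(self) -> None:
        if (self.intensity_path is None) == (self.simulate is None):
            raise ValueError(
                "config must set exactly one of intensity_path or simulate"
            )
        for c in self.contrasts:
            for part in ("stratum", "numerator", "denominator"):
                for factor in c.get(part, {}):
                    if factor not in ("tissue", "genotype", "treatment", "sex"):
                        raise ValueError(
                            f"contrast {c.get('name', '?')!r} references unknown "
                            f"factor {factor!r}"
                        )


def load_config(path) -> RunConfig:
    """Read a RunConfig from a TOML (or JSON) file."""
    p = Path(path)
    raw: Mapping[str, Any]
    if p.suffix == ".json":
        raw = json.loads(p.read_text())
    else:
        raw = tomllib.loads(p.read_text())
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written as JSON).

    A stage failure writes a FAILED marker naming the stage and re-raises as
    :class:`PipelineError`; outputs produced before the failure are kept.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    log: list[str] = []
    stage = "init"

    def note(msg: str) -> None:
        log.append(f"{datetime.now(timezone.utc).isoformat()} INFO [{stage}] {msg}")

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path)

    try:
        # ---- input / simulation ----------------------------------------
        stage = "input"
        record = None
        if config.simulate is not None:
            sim = dict(config.simulate)
            seed = int(sim.pop("seed", 0))
            truth = default_truth(seed)
            if sim:
                from dataclasses import replace

                truth = replace(truth, **sim)
            matrix, record = generate_study(truth)
            path = outdir / "simulated_intensities.tsv"
            write_intensity_table(matrix, path)
            emit("intensity_table", path)
            sidecar = outdir / "truth.tsv"
            truth_sidecar(record).to_csv(sidecar, sep="\t")
            emit("truth_sidecar", sidecar)
            note(f"simulated {matrix.values.shape[0]} samples x "
                 f"{matrix.values.shape[1]} metabolites (seed={seed})")
        else:
            matrix = read_intensity_table(config.intensity_path)
            if config.annotation_path:
                ann = read_annotations(config.annotation_path)
                matrix = IntensityMatrix(
                    matrix.values, matrix.samples,
                    ann.reindex(matrix.values.columns).fillna({"identified": False}),
                )
            note(f"read {matrix.values.shape[0]} x {matrix.values.shape[1]} table")

        # ---- presence filter -------------------------------------------
        stage = "filter"
        spec = DesignGroupSpec(tuple(config.design_factors))
        filtered, flog = presence_filter(
            matrix, spec, threshold=config.filter_threshold, mode=config.filter_mode
        )
        path = outdir / "filter_log.tsv"
        flog.write(path)
        emit("filter_log", path)
        note(f"retained {filtered.values.shape[1]} of {matrix.values.shape[1]} "
             "metabolites")

        # ---- normalization ----------------------------------------------
        stage = "normalize"
        normed = sum_normalize(filtered)
        path = outdir / "normalized_intensities.tsv"
        write_intensity_table(normed, path)
        emit("normalized_table", path)

        # ---- differential statistics ------------------------------------
        stage = "diffstats"
        all_results: dict[str, list] = {}
        for c in config.contrasts:
            results = differential_table(
                normed,
                stratum=c["stratum"],
                contrast=(c["numerator"], c["denominator"]),
                alpha=config.alpha,
            )
            all_results[c["name"]] = results
            path = outdir / f"differential_{c['name']}.tsv"
            write_differential_table(results, path)
            emit(f"differential_{c['name']}", path)
            n_sig = sum(r.significant for r in results)
            note(f"contrast {c['name']}: {n_sig} significant at "
                 f"p<{config.alpha}")

        # ---- PLS-DA ------------------------------------------------------
        stage = "pls"
        pls_cfg = config.pls
        sub = normed.subset(sample_ids=normed.select_samples(pls_cfg["stratum"])) \
            if pls_cfg.get("stratum") else normed
        classes = [
            "/".join(str(sub.samples.loc[s, f]) for f in pls_cfg["class_factors"])
            for s in sub.sample_ids
        ]
        X, _rec = autoscale(sub.values)
        n_comp = int(pls_cfg["n_components"])
        model = nipals_pls(X, classes, n_comp,
                           max_iter=int(pls_cfg["max_iter"]),
                           tol=float(pls_cfg["tol"]))
        model.q2 = cross_validate(X, classes, n_comp, k=int(pls_cfg["k"]),
                                  seed=int(pls_cfg["seed"]),
                                  max_iter=int(pls_cfg["max_iter"]),
                                  tol=float(pls_cfg["tol"]))
        scores = model.scores_frame()
        scores["class"] = classes
        path = outdir / "pls_scores.tsv"
        scores.to_csv(path, sep="\t", index_label="sample_id")
        emit("pls_scores", path)
        summary = pd.DataFrame(
            {
                "x_variance_explained": model.x_variance_explained,
                "y_variance_explained": model.y_variance_explained,
                "q2": model.q2,
            },
            index=[f"v{i + 1}" for i in range(n_comp)],
        )
        path = outdir / "pls_summary.tsv"
        summary.to_csv(path, sep="\t", index_label="component")
        emit("pls_summary", path)
        note(f"PLS-DA v1 explains {model.x_variance_explained[0]:.1%} of X")

        # ---- network ------------------------------------------------------
        stage = "network"
        net_cfg = config.network
        ident = [m for m in normed.identified_ids]
        seed = int(config.simulate.get("seed", 0)) if config.simulate else 0
        fps, _labels = generate_compounds(
            len(ident), n_clusters=int(net_cfg["n_clusters"]), seed=seed
        )
        # generated compound ids are positional; rekey onto the study ids
        fps = {ident[i]: fp for i, (_, fp) in enumerate(sorted(fps.items()))}
        if config.rpair_path:
            rpairs = read_rpair_table(config.rpair_path)
            resolver = {}
            if "kegg" in normed.annotations.columns:
                resolver = {
                    str(v): m
                    for m, v in normed.annotations["kegg"].items()
                    if str(v)
                }
        else:
            resolver = {
                str(normed.annotations.loc[m, "kegg"]): m
                for m in ident
                if "kegg" in normed.annotations.columns
                and str(normed.annotations.loc[m, "kegg"])
            }
            ref_of = {m: str(normed.annotations.loc[m, "kegg"]) for m in ident}
            rpairs, _planted = generate_rpairs(
                ident, k=min(int(net_cfg["n_rpairs"]),
                             len(ident) * (len(ident) - 1) // 2),
                seed=seed, id_to_ref=ref_of,
            )
        sim = similarity_edges(fps, threshold=float(net_cfg["threshold"]))
        rxn, rpt = rpair_edges(ident, rpairs, resolver)
        net = merge_networks(sim, rxn, ident)
        contrast_name = net_cfg.get("contrast") or config.contrasts[0]["name"]
        results = all_results.get(contrast_name, [])
        net = map_statistics(net, [r for r in results if r.metabolite_id in net.nodes],
                             size_range=tuple(net_cfg["size_range"]))
        sif = outdir / "network.sif"
        write_sif(net, sif)
        emit("network_sif", sif)
        attrs = outdir / "node_attributes.tsv"
        write_node_attributes(net, attrs)
        emit("node_attributes", attrs)
        note(f"network: {net.n_nodes} nodes, {net.n_edges} edges "
             f"({rpt['n_edges']} rpair)")

        # ---- manifest ------------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": (int(config.simulate.get("seed", 0))
                     if config.simulate else None),
            "config": {
                k: getattr(config, k)
                for k in RunConfig.__dataclass_fields__
            },
            "outputs": {
                name: {"path": p, "sha256": _sha256(Path(p))}
                for name, p in outputs.items()
            },
            "log": log,
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=str))
        return manifest
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
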
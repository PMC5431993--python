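"""End-to-end pipeline orchestration.

A single YAML config names every input file, the stages to run and the
analysis parameters; :func:`run_pipeline` executes the stages in
dependency order, writes each stage's tables under the output
directory, and records a MANIFEST of completed stages. Every output
table starts with a ``# config_hash=`` comment so results are traceable
to the exact configuration (read them back with
``pd.read_csv(..., comment='#')``). One seed from the config drives all
stochastic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import causal, gwas, meta, mirna, network, preservation, qc, simulate

log = logging.getLogger("sysgen")

ALL_STAGES = ("gwas", "qc", "network", "causal", "mirna", "preserve", "meta")

_INPUT_KEYS = (
    "expression", "detection", "traits", "snps", "gene_models", "ld",
    "mirna", "targets", "causal_expression", "studies_dir",
)


@dataclass
class PipelineConfig:
    out_dir: str
    inputs: dict = field(default_factory=dict)
    stages: tuple = ALL_STAGES
    beta: int = 6
    upstream_bp: int = 1000
    r2_threshold: float = 0.80
    gwas_alpha: float = 0.05
    ci_alpha: float = 0.01
    h: int = 3
    max_cond_size: int | None = 3
    min_module_size: int = 30
    mm_cut: float = 0.8
    gs_cut: float = 0.2
    fdr_cut: float = 0.05
    n_perm: int = 100
    b_perm: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        location does not affect results and is excluded)."""
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in sorted(self.__dict__.items())
             if k != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """All problems at once, never fail-fast on the first."""
    errors: list[str] = []
    for stage in config.stages:
        if stage not in ALL_STAGES:
            errors.append(f"unknown stage: {stage!r}")
    for key, path in config.inputs.items():
        if key not in _INPUT_KEYS:
            errors.append(f"unknown input key: {key!r}")
        elif path is not None and not Path(path).exists():
            errors.append(f"input {key}: no such file {path}")
    if not 0 < config.ci_alpha < 1:
        errors.append(f"ci_alpha={config.ci_alpha} outside (0, 1)")
    if not 0 < config.gwas_alpha < 1:
        errors.append(f"gwas_alpha={config.gwas_alpha} outside (0, 1)")
    if config.beta < 1:
        errors.append(f"beta={config.beta} must be >= 1")
    if config.h < 1:
        errors.append(f"h={config.h} must be >= 1")
    if not 0 <= config.r2_threshold <= 1:
        errors.append(f"r2_threshold={config.r2_threshold} outside [0, 1]")
    return errors


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the MANIFEST dict (also written to ``MANIFEST.json``):
    completed stages, per-stage outputs and the config hash. Raises on
    the first stage error after writing the partial MANIFEST.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    manifest = {"config_hash": cfg_hash, "stages": {}}
    state: dict = {}

    def _done(stage: str, outputs: list[str]) -> None:
        manifest["stages"][stage] = {"outputs": outputs}
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
        log.info("stage=%s status=done outputs=%d", stage, len(outputs))

    try:
        for stage in [s for s in ALL_STAGES if s in config.stages]:
            t0 = time.time()
            log.info("stage=%s status=start", stage)
            if stage == "gwas":
                snps = gwas.read_snps(config.inputs["snps"])
                genes = gwas.read_gene_models(config.inputs["gene_models"])
                ld = gwas.read_ld(config.inputs["ld"])
                table, candidates = gwas.prioritize(
                    snps, genes, ld,
                    upstream_bp=config.upstream_bp,
                    r2_threshold=config.r2_threshold,
                    alpha=config.gwas_alpha,
                )
                _write(table, out / "gene_pvalues.tsv", cfg_hash, index=False)
                (out / "candidates.txt").write_text(
                    "\n".join(sorted(candidates)) + "\n"
                )
                state["candidates"] = candidates
                _done(stage, ["gene_pvalues.tsv", "candidates.txt"])
            elif stage == "qc":
                expr = _read_tsv(config.inputs["expression"])
                det_path = config.inputs.get("detection")
                if det_path:
                    det = _read_tsv(det_path)
                    expr = qc.detection_filter(expr, det)
                expr = qc.knn_impute(expr)
                report = qc.detect_outlier_samples(expr)
                expr = expr.drop(columns=list(report.index))
                _write(expr, out / "expr_qc.tsv", cfg_hash)
                _write(report, out / "outliers.tsv", cfg_hash)
                state["expr"] = expr
                _done(stage, ["expr_qc.tsv", "outliers.tsv"])
            elif stage == "network":
                expr = state.get("expr")
                if expr is None:
                    expr = _read_tsv(config.inputs["expression"])
                if "candidates" in state:
                    keep = expr.index.intersection(sorted(state["candidates"]))
                    expr = expr.loc[keep]
                traits = _read_tsv(config.inputs["traits"])
                traits = traits.loc[expr.columns]
                net = network.CoexpressionNetwork(
                    beta=config.beta,
                    min_module_size=config.min_module_size,
                    mm_cut=config.mm_cut,
                    gs_cut=config.gs_cut,
                ).fit(expr)
                mt = net.module_trait_table(traits)
                gs = net.gene_significance_table(traits["obesity"])
                hubs = net.hub_genes(traits["obesity"])
                _write(net.labels_.to_frame(), out / "modules.tsv", cfg_hash)
                _write(net.eigengenes_, out / "eigengenes.tsv", cfg_hash)
                _write(mt, out / "module_trait.tsv", cfg_hash, index=False)
                gs_mm = gs.join(net.kme_.add_prefix("kME_"))
                _write(gs_mm, out / "gs_mm.tsv", cfg_hash)
                (out / "hubs.json").write_text(json.dumps(hubs, indent=1))
                state["net"] = net
                state["net_expr"] = expr
                state["traits"] = traits
                _done(stage, ["modules.tsv", "eigengenes.tsv",
                              "module_trait.tsv", "gs_mm.tsv", "hubs.json"])
            elif stage == "causal":
                cexpr = _read_tsv(config.inputs["causal_expression"])
                pc = causal.PCAlgorithm(
                    alpha=config.ci_alpha, max_cond_size=config.max_cond_size
                ).fit(cexpr)
                kda = causal.key_driver_analysis(
                    pc.graph_, list(cexpr.index), h=config.h
                )
                _write(
                    pc.graph_.edge_list(), out / "causal_edges.tsv",
                    cfg_hash, index=False,
                )
                (out / "kda.json").write_text(json.dumps({
                    "mu": kda.mu.to_dict(),
                    "out_degree": kda.degree.to_dict(),
                    "mu_threshold": kda.mu_threshold,
                    "degree_threshold": kda.degree_threshold,
                    "causal_regulators": sorted(kda.causal_regulators),
                    "key_drivers": sorted(kda.key_drivers),
                }, indent=1))
                _done(stage, ["causal_edges.tsv", "kda.json"])
            elif stage == "mirna":
                expr = state.get("net_expr")
                if expr is None:
                    expr = _read_tsv(config.inputs["expression"])
                mir = _read_tsv(config.inputs["mirna"])
                targets = pd.read_csv(
                    config.inputs["targets"], sep="\t", comment="#"
                )
                # QC may have dropped samples; align on the shared set
                shared = [s for s in expr.columns if s in mir.columns]
                res = mirna.integrate(
                    expr[shared], mir[shared], targets,
                    fdr_cut=config.fdr_cut,
                )
                _write(res, out / "interactions.tsv", cfg_hash, index=False)
                _done(stage, ["interactions.tsv"])
            elif stage == "preserve":
                net = state.get("net")
                expr = state.get("net_expr")
                if net is None:
                    raise ValueError(
                        "preserve stage requires the network stage"
                    )
                studies = simulate.read_studies(config.inputs["studies_dir"])
                rows = []
                target = _target_module(net, state.get("traits"))
                for study in studies:
                    res = preservation.zsummary(
                        expr, study.expression, net.labels_, target,
                        n_perm=config.n_perm, beta=config.beta,
                        seed=config.seed,
                    )
                    rows.append((study.name, target, res.z_density,
                                 res.z_connectivity, res.z_summary))
                df = pd.DataFrame(rows, columns=[
                    "study", "module", "z_density", "z_connectivity",
                    "z_summary",
                ])
                _write(df, out / "preservation.tsv", cfg_hash, index=False)
                _done(stage, ["preservation.tsv"])
            elif stage == "meta":
                studies = simulate.read_studies(config.inputs["studies_dir"])
                genes = None
                if "net" in state:
                    net = state["net"]
                    target = _target_module(net, state.get("traits"))
                    genes = sorted(
                        net.labels_.index[net.labels_ == target]
                    )
                res = meta.meta_analyze(
                    studies, genes=genes, b_perm=config.b_perm,
                    seed=config.seed,
                )
                _write(res, out / "meta_results.tsv", cfg_hash)
                _done(stage, ["meta_results.tsv"])
            log.info(
                "stage=%s status=end elapsed=%.1fs", stage, time.time() - t0
            )
    except Exception:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
        raise
    return manifest


def _target_module(net, traits) -> str:
    """Most obesity-associated module (by age-adjusted p), else the
    largest module."""
    if traits is not None:
        mt = net.module_trait_table(traits)
        sub = mt[mt["trait"] == "obesity"]
        if len(sub):
            return sub.loc[sub["p"].idxmin(), "module"]
    sizes = net.labels_[net.labels_ != "grey"].value_counts()
    return sizes.index[0]
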
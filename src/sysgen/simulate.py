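"""Synthetic data generation for the systems-genetics pipeline.

Every downstream stage (GWAS gene prioritization, coexpression modules,
causal discovery, miRNA integration, preservation, meta-analysis) is
exercised on data produced here, so the generator plants the exact
structure each stage is meant to recover:

* expression follows a latent-factor model — each module has one
  per-sample factor and member genes load on it, which reproduces the
  module/eigengene duality weighted coexpression analysis assumes;
* a BMI-like trait is driven by the first module's factor plus an age
  covariate, with obesity defined by thresholding the trait;
* a linear structural equation model (SEM) over a small gene set gives a
  ground-truth causal graph with a known root regulator;
* target miRNAs are negatively correlated with module genes;
* replicate study datasets share the discovery loading structure and
  carry a planted standardized group difference for meta-analysis.

A single integer seed drives everything; each component draws from its
own deterministic sub-stream so adding one component never perturbs the
output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SyntheticBundle",
    "Study",
    "StudyCollection",
    "simulate_modular_expression",
    "simulate_traits",
    "simulate_causal_module",
    "simulate_mirna",
    "simulate_study_collection",
    "simulate_gwas_inputs",
    "make_gene_models",
    "make_bundle",
    "write_bundle",
    "write_studies",
    "read_studies",
    "default_dag_edges",
]

# stable sub-stream codes; never renumber, only append
_STREAM = {
    "expression": 1,
    "traits": 2,
    "causal": 3,
    "mirna": 4,
    "studies": 5,
    "gwas": 6,
    "genemodels": 7,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[component]])


def default_dag_edges() -> list[tuple[str, str, float]]:
    """Planted causal DAG: root R drives A1..A4, independent co-parents
    Z1..Z4 create colliders at the A genes (so the constraint-based search
    can orient the edges), and each A gene drives one downstream B gene.

    R is the unique key driver by construction: out-degree 4 and a
    3-layer downstream neighborhood of 8 nodes, both far above the
    network means.
    """
    edges: list[tuple[str, str, float]] = []
    for i in range(1, 5):
        edges.append(("R", f"A{i}", 0.8))
        edges.append((f"Z{i}", f"A{i}", 0.6))
        edges.append((f"A{i}", f"B{i}", 0.8))
    return edges


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the discovery cohort scale: 200 subjects, 1000
    candidate genes of which five 40-gene modules carry signal, gene
    loadings spanning the hub/non-hub range, a trait driven by the first
    module's eigengene plus age, and five replicate studies with a unit
    standardized group shift in the planted module genes.
    """

    n_samples: int = 200
    n_genes: int = 1000
    module_sizes: tuple[int, ...] = (40, 40, 40, 40, 40)
    loading_range: tuple[float, float] = (0.5, 0.95)
    trait_effect: float = 0.6     # β1, factor → trait
    age_effect: float = 0.3       # β2, standardized age → trait
    trait_noise_sd: float = 0.74  # σ_ε of the trait model
    planted_smd: float = 1.0      # δ, within-group SD units, obese lower
    n_datasets: int = 5
    mirna_gamma: float = 0.5
    n_target_mirnas: int = 20
    n_background_mirnas: int = 30
    n_decoy_pairs: int = 180
    dag_edges: tuple[tuple[str, str, float], ...] = field(
        default_factory=lambda: tuple(default_dag_edges())
    )
    causal_n_samples: int = 1000  # SEM fixture; CI tests need the power
    hub_loading_gap: float = 0.05  # planted hub sits this far above rest
    obesity_quantile: float = 0.70  # trait threshold; 30% prevalence
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("every module needs at least 2 genes")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} "
                f"> n_genes={self.n_genes}"
            )
        lo, hi = self.loading_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("loading_range must satisfy 0 < low < high < 1")
        if self.n_datasets < 2:
            raise ValueError("need at least 2 replicate datasets")
        if not (0.0 <= self.mirna_gamma <= 1.0):
            raise ValueError("mirna_gamma must lie in [0, 1]")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class Study:
    """One replicate expression dataset with obese/non-obese labels."""

    name: str
    expression: pd.DataFrame      # genes x samples
    group: pd.Series              # 1 = obese, 0 = non-obese, per sample
    age: pd.Series | None = None


@dataclass
class StudyCollection:
    studies: list[Study]

    def __iter__(self):
        return iter(self.studies)

    def __len__(self) -> int:
        return len(self.studies)


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the planted ground truth."""

    config: SimConfig
    expression: pd.DataFrame          # genes x samples
    traits: pd.DataFrame              # samples x phenotypes
    mirna: pd.DataFrame               # miRNAs x samples
    target_table: pd.DataFrame        # mirna_id, gene_id, p_database
    snps: pd.DataFrame                # snp_id, chr, pos, p
    gene_models: pd.DataFrame         # gene_id, chr, start, end, strand
    ld: pd.DataFrame                  # snp_a, snp_b, r2
    causal_expression: pd.DataFrame   # SEM genes x samples
    causal_dag: nx.DiGraph
    truth: dict


# ---------------------------------------------------------------------------
# expression


def simulate_modular_expression(
    cfg: SimConfig, rng: np.random.Generator | None = None
):
    """Latent-factor expression matrix with planted modules.

    Member gene i of module m is ``x_i = w_i * e_m + sqrt(1-w_i^2) * eps``
    with ``e_m`` a per-sample standard-normal factor and loading ``w_i``
    uniform on ``loading_range``; background genes are pure noise. Rows
    are standardized to sample mean 0, variance 1.

    Each module's first member is its planted hub: its loading sits at
    the top of ``loading_range`` while the other members draw at least
    ``hub_loading_gap`` below it, so the maximally connected gene is
    well defined in finite samples.

    Returns ``(expression, labels, factors, loadings)`` where labels map
    gene -> module index (0 = background) and factors is modules x samples.
    """
    rng = _rng(cfg.seed, "expression") if rng is None else rng
    n, g = cfg.n_samples, cfg.n_genes
    gene_ids = [f"G{i:04d}" for i in range(g)]
    sample_ids = [f"S{j:03d}" for j in range(n)]
    m = len(cfg.module_sizes)

    factors = rng.standard_normal((m, n))
    lo, hi = cfg.loading_range
    loadings = np.zeros(g)
    labels = np.zeros(g, dtype=int)

    x = rng.standard_normal((g, n))  # noise for every gene
    pos = 0
    for mod, size in enumerate(cfg.module_sizes, start=1):
        w = rng.uniform(lo, max(lo, hi - cfg.hub_loading_gap), size=size)
        w[0] = hi
        block = slice(pos, pos + size)
        labels[block] = mod
        loadings[block] = w
        x[block] = (
            w[:, None] * factors[mod - 1]
            + np.sqrt(1.0 - w**2)[:, None] * x[block]
        )
        pos += size

    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    expr = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    return (
        expr,
        pd.Series(labels, index=gene_ids, name="module"),
        pd.DataFrame(
            factors,
            index=[f"factor_{k}" for k in range(1, m + 1)],
            columns=sample_ids,
        ),
        pd.Series(loadings, index=gene_ids, name="loading"),
    )


def simulate_traits(
    e_target: np.ndarray | pd.Series,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample phenotypes driven by one module's latent factor.

    ``bmi = β1 * e + β2 * age_std + ε`` with age uniform on [30, 70];
    obesity is the indicator of bmi above its ``obesity_quantile``
    quantile. Two additional quantitative traits are generated as a
    positive (fat-mass-like) and a negative (HDL-like) correlate of the
    factor.
    """
    rng = _rng(cfg.seed, "traits") if rng is None else rng
    e = np.asarray(e_target, dtype=float)
    if e.shape[0] != cfg.n_samples:
        raise ValueError("factor length must equal n_samples")
    index = (
        e_target.index
        if isinstance(e_target, pd.Series)
        else [f"S{j:03d}" for j in range(cfg.n_samples)]
    )
    age = rng.uniform(30.0, 70.0, size=cfg.n_samples)
    age_std = (age - age.mean()) / age.std()
    eps = rng.standard_normal(cfg.n_samples) * cfg.trait_noise_sd
    bmi = cfg.trait_effect * e + cfg.age_effect * age_std + eps
    obesity = (bmi > np.quantile(bmi, cfg.obesity_quantile)).astype(int)
    fm = 0.5 * e + rng.standard_normal(cfg.n_samples)
    hdl = -0.5 * e + rng.standard_normal(cfg.n_samples)
    return pd.DataFrame(
        {"age": age, "bmi": bmi, "obesity": obesity, "fm": fm, "hdl": hdl},
        index=pd.Index(index, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# causal SEM


def simulate_causal_module(
    dag_edges,
    n_samples: int,
    seed: int | np.random.Generator = 0,
):
    """Expression respecting a linear structural equation model.

    Genes are generated in topological order:
    ``x_child = sum_parents w * x_parent + noise``. Returns the genes x
    samples matrix and the true DAG (edge weights on the ``weight``
    attribute). Raises on cyclic edge lists.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else _rng(int(seed), "causal")
    )
    dag = nx.DiGraph()
    for parent, child, w in dag_edges:
        dag.add_edge(parent, child, weight=float(w))
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("dag_edges contain a cycle")
    order = list(nx.topological_sort(dag))
    data: dict[str, np.ndarray] = {}
    for node in order:
        x = rng.standard_normal(n_samples)
        for parent in dag.predecessors(node):
            x = x + dag[parent][node]["weight"] * data[parent]
        data[node] = x
    genes = sorted(dag.nodes)
    mat = np.vstack([data[gene] for gene in genes])
    expr = pd.DataFrame(
        mat, index=genes, columns=[f"S{j:03d}" for j in range(n_samples)]
    )
    return expr, dag


# ---------------------------------------------------------------------------
# miRNA


def simulate_mirna(
    expression: pd.DataFrame,
    targets: dict[str, str],
    gamma: float,
    seed: int | np.random.Generator = 0,
    n_background: int = 0,
) -> pd.DataFrame:
    """miRNA expression negatively coupled to target genes.

    ``miR_j = -gamma * x_target(j) + sqrt(1-gamma^2) * noise`` for each
    (mirna, gene) entry of ``targets``; ``n_background`` extra miRNAs are
    pure noise. Target rows use the standardized gene expression so the
    population correlation with the target is exactly ``-gamma``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else _rng(int(seed), "mirna")
    )
    missing = set(targets.values()) - set(expression.index)
    if missing:
        raise KeyError(f"unknown target gene ids: {sorted(missing)}")
    n = expression.shape[1]
    rows, ids = [], []
    for mir, gene in targets.items():
        x = expression.loc[gene].to_numpy(dtype=float)
        x = (x - x.mean()) / x.std()
        rows.append(-gamma * x + np.sqrt(1.0 - gamma**2) * rng.standard_normal(n))
        ids.append(mir)
    for b in range(n_background):
        rows.append(rng.standard_normal(n))
        ids.append(f"miR-bg-{b:03d}")
    return pd.DataFrame(np.vstack(rows), index=ids, columns=expression.columns)


# ---------------------------------------------------------------------------
# replicate studies


def _study_expression(
    labels: pd.Series,
    loadings: pd.Series,
    n_samples: int,
    rng: np.random.Generator,
    scramble: bool = False,
    delta: float = 0.0,
    group: np.ndarray | None = None,
) -> pd.DataFrame:
    """One dataset re-drawn from the discovery loading structure (new
    factors, new noise). ``scramble`` permutes the gene -> module
    assignment so the reference module structure is destroyed. With
    ``delta`` and ``group``, the genes carrying module structure in
    THIS dataset are shifted by ``-delta`` within-group SD units in the
    group-1 samples."""
    genes = labels.index
    lab = labels.to_numpy().copy()
    w = loadings.to_numpy().copy()
    if scramble:
        perm = rng.permutation(len(lab))
        lab, w = lab[perm], w[perm]
    n_modules = int(lab.max())
    factors = rng.standard_normal((n_modules + 1, n_samples))
    noise = rng.standard_normal((len(genes), n_samples))
    x = np.where(
        (lab > 0)[:, None],
        w[:, None] * factors[lab] + np.sqrt(1.0 - w**2)[:, None] * noise,
        noise,
    )
    if delta and group is not None:
        x[np.ix_(lab > 0, np.asarray(group) == 1)] -= delta
    return pd.DataFrame(
        x, index=genes, columns=[f"T{j:03d}" for j in range(n_samples)]
    )


def simulate_study_collection(
    cfg: SimConfig,
    labels: pd.Series | None = None,
    loadings: pd.Series | None = None,
    include_scrambled: bool = False,
    rng: np.random.Generator | None = None,
) -> StudyCollection:
    """k replicate datasets sharing the discovery loading structure.

    In each study, half the samples are labelled obese and every planted
    (non-background) module gene is shifted by ``-planted_smd`` within-
    group SD units in the obese group. With ``include_scrambled`` a final
    study with permuted gene-factor assignments is appended; the
    reference modules are noise there.
    """
    rng = _rng(cfg.seed, "studies") if rng is None else rng
    if labels is None or loadings is None:
        _, labels, _, loadings = simulate_modular_expression(cfg)
    studies = []
    flags = [False] * cfg.n_datasets + ([True] if include_scrambled else [])
    for i, scramble in enumerate(flags):
        group = np.zeros(cfg.n_samples, dtype=int)
        group[cfg.n_samples // 2:] = 1
        expr = _study_expression(
            labels, loadings, cfg.n_samples, rng, scramble=scramble,
            delta=cfg.planted_smd, group=group,
        )
        age = pd.Series(
            rng.uniform(30.0, 70.0, cfg.n_samples),
            index=expr.columns,
            name="age",
        )
        name = f"study_{i + 1}" + ("_scrambled" if scramble else "")
        studies.append(
            Study(
                name=name,
                expression=expr,
                group=pd.Series(group, index=expr.columns, name="obesity"),
                age=age,
            )
        )
    return StudyCollection(studies)


# ---------------------------------------------------------------------------
# GWAS fixtures


def make_gene_models(
    gene_ids, rng: np.random.Generator, genes_per_chrom: int = 100
) -> pd.DataFrame:
    """Non-overlapping transcript spans laid out on synthetic chromosomes."""
    records = []
    for i, gene in enumerate(gene_ids):
        chrom = f"chr{i // genes_per_chrom + 1}"
        offset = (i % genes_per_chrom) * 60_000 + 10_000
        length = int(rng.integers(2_000, 40_000))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append((gene, chrom, offset, offset + length, strand))
    return pd.DataFrame(
        records, columns=["gene_id", "chr", "start", "end", "strand"]
    )


def simulate_gwas_inputs(
    gene_models: pd.DataFrame,
    planted_genes,
    seed: int | np.random.Generator = 0,
):
    """SNP summary statistics and an LD table with planted gene signals.

    Each gene receives 1-20 SNPs in its body plus 1-kb upstream window.
    The minimum SNP p-value per gene is uniform(0, 0.05) for planted
    genes and uniform(0, 1) for background genes; remaining SNPs draw
    above that minimum. Consecutive SNP pairs within a gene are linked at
    r² = 0.9 to form proxy clusters.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else _rng(int(seed), "gwas")
    )
    planted = set(planted_genes)
    unknown = planted - set(gene_models["gene_id"])
    if unknown:
        raise KeyError(f"planted genes not in gene models: {sorted(unknown)}")
    snp_rows, ld_rows = [], []
    counter = 0
    for rec in gene_models.itertuples(index=False):
        n_snps = int(rng.integers(1, 21))
        if rec.strand == "+":
            lo, hi = rec.start - 1000, rec.end
        else:
            lo, hi = rec.start, rec.end + 1000
        positions = np.sort(rng.integers(max(lo, 1), hi + 1, size=n_snps))
        p_min = rng.uniform(0, 0.05 if rec.gene_id in planted else 1.0)
        pvals = rng.uniform(p_min, 1.0, size=n_snps)
        pvals[rng.integers(0, n_snps)] = p_min
        ids = [f"rs{counter + k}" for k in range(n_snps)]
        counter += n_snps
        for sid, pos, p in zip(ids, positions, pvals):
            snp_rows.append((sid, rec.chr, int(pos), float(p)))
        for a, b in zip(ids, ids[1:]):
            ld_rows.append((a, b, 0.9))
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chr", "pos", "p"])
    ld = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"])
    return snps, ld


# ---------------------------------------------------------------------------
# the full bundle


def make_bundle(cfg: SimConfig | None = None) -> SyntheticBundle:
    """Generate every pipeline input plus the planted ground truth."""
    cfg = SimConfig() if cfg is None else cfg
    expr, labels, factors, loadings = simulate_modular_expression(cfg)
    traits = simulate_traits(
        pd.Series(factors.iloc[0].to_numpy(), index=expr.columns), cfg
    )
    causal_expr, causal_dag = simulate_causal_module(
        cfg.dag_edges, cfg.causal_n_samples, _rng(cfg.seed, "causal")
    )

    mirna_rng = _rng(cfg.seed, "mirna")
    module1 = list(labels.index[labels == 1])
    n_t = min(cfg.n_target_mirnas, len(module1))
    target_genes = list(mirna_rng.choice(module1, size=n_t, replace=False))
    targets = {f"miR-t-{k:03d}": g for k, g in enumerate(target_genes)}
    mirna = simulate_mirna(
        expr, targets, cfg.mirna_gamma, mirna_rng, cfg.n_background_mirnas
    )
    pairs = [(m, g) for m, g in targets.items()]
    module_genes = list(labels.index[labels > 0])
    # decoys: database-predicted pairs with no expression support, i.e.
    # background miRNAs paired with module genes
    background_mirs = [m for m in mirna.index if m.startswith("miR-bg-")]
    existing = set(pairs)
    while len(pairs) < n_t + cfg.n_decoy_pairs:
        pair = (
            str(mirna_rng.choice(background_mirs)),
            str(mirna_rng.choice(module_genes)),
        )
        if pair not in existing:
            existing.add(pair)
            pairs.append(pair)
    target_table = pd.DataFrame(pairs, columns=["mirna_id", "gene_id"])
    target_table["p_database"] = mirna_rng.uniform(0, 0.05, len(target_table))

    gm_rng = _rng(cfg.seed, "genemodels")
    gene_models = make_gene_models(expr.index, gm_rng)
    snps, ld = simulate_gwas_inputs(
        gene_models, module_genes, _rng(cfg.seed, "gwas")
    )

    hub = loadings[labels == 1].idxmax()
    truth = {
        "labels": labels,
        "loadings": loadings,
        "factors": factors,
        "target_module": 1,
        "hub_gene": hub,
        "key_driver": "R",
        "true_mirna_targets": targets,
        "planted_smd": cfg.planted_smd,
        "planted_genes": module_genes,
    }
    return SyntheticBundle(
        config=cfg,
        expression=expr,
        traits=traits,
        mirna=mirna,
        target_table=target_table,
        snps=snps,
        gene_models=gene_models,
        ld=ld,
        causal_expression=causal_expr,
        causal_dag=causal_dag,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write all fixture inputs as TSV plus a truth manifest (JSON)."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.expression.to_csv(out / "expression.tsv", sep="\t")
    bundle.traits.to_csv(out / "traits.tsv", sep="\t")
    bundle.mirna.to_csv(out / "mirna.tsv", sep="\t")
    bundle.target_table.to_csv(out / "targets.tsv", sep="\t", index=False)
    bundle.snps.to_csv(out / "gwas_snps.tsv", sep="\t", index=False)
    bundle.gene_models.to_csv(out / "gene_models.tsv", sep="\t", index=False)
    bundle.ld.to_csv(out / "ld.tsv", sep="\t", index=False)
    bundle.causal_expression.to_csv(out / "causal_expression.tsv", sep="\t")
    manifest = {
        "labels": bundle.truth["labels"].to_dict(),
        "hub_gene": bundle.truth["hub_gene"],
        "key_driver": bundle.truth["key_driver"],
        "target_module": bundle.truth["target_module"],
        "true_mirna_targets": bundle.truth["true_mirna_targets"],
        "planted_smd": bundle.truth["planted_smd"],
        "causal_edges": [
            [u, v, bundle.causal_dag[u][v]["weight"]]
            for u, v in bundle.causal_dag.edges
        ],
        "seed": bundle.config.seed,
    }
    (out / "truth.json").write_text(json.dumps(manifest, indent=1))


def write_studies(collection: StudyCollection, outdir) -> None:
    """Write each study as expression + phenotype TSV pairs."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for study in collection:
        study.expression.to_csv(out / f"{study.name}_expr.tsv", sep="\t")
        pheno = pd.DataFrame({"obesity": study.group})
        if study.age is not None:
            pheno["age"] = study.age
        pheno.index.name = "sample_id"
        pheno.to_csv(out / f"{study.name}_pheno.tsv", sep="\t")


def read_studies(outdir) -> StudyCollection:
    """Read back a directory written by :func:`write_studies`."""
    from pathlib import Path

    out = Path(outdir)
    studies = []
    for f in sorted(out.glob("*_expr.tsv")):
        name = f.name.removesuffix("_expr.tsv")
        expr = pd.read_csv(f, sep="\t", index_col=0)
        pheno = pd.read_csv(
            out / f"{name}_pheno.tsv", sep="\t", index_col=0
        )
        age = pheno["age"] if "age" in pheno.columns else None
        studies.append(
            Study(
                name=name,
                expression=expr,
                group=pheno["obesity"],
                age=age,
            )
        )
    return StudyCollection(studies)
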
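"""Gene-based prioritization of GWAS summary statistics.

SNP-level association p-values are collapsed to gene-wide p-values: each
gene is the transcript span plus a 1-kb upstream promoter extension,
SNPs within a gene are grouped into proxy clusters by linkage
disequilibrium (single-linkage components at an r² threshold), each
cluster scores the minimum member p-value, and the gene-wide p-value is
the minimum over its singleton SNPs and clusters. Genes at gene-wide
p <= alpha form the nominally significant candidate set that seeds the
coexpression network.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "assign_snps_to_genes",
    "cluster_snps_by_ld",
    "gene_wide_pvalue",
    "select_candidate_genes",
    "prioritize",
    "read_snps",
    "read_gene_models",
    "read_ld",
]

_SNP_COLS = ["snp_id", "chr", "pos", "p"]
_GENE_COLS = ["gene_id", "chr", "start", "end", "strand"]


def read_snps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _validate_snps(df)
    return df


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _validate_genes(df)
    return df


def read_ld(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _validate_snps(snps: pd.DataFrame) -> None:
    missing = [c for c in _SNP_COLS if c not in snps.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    bad = snps.index[(snps["p"] <= 0) | (snps["p"] > 1) | (snps["pos"] < 1)]
    if len(bad):
        raise ValueError(
            f"malformed SNP records at rows {list(bad[:5])}: "
            "need p in (0,1] and pos >= 1"
        )


def _validate_genes(genes: pd.DataFrame) -> None:
    missing = [c for c in _GENE_COLS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene model table missing columns: {missing}")
    bad = genes.index[genes["start"] > genes["end"]]
    if len(bad):
        raise ValueError(f"gene models with start > end at rows {list(bad[:5])}")


def assign_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, upstream_bp: int = 1000
) -> dict[str, set[str]]:
    """Map each gene to the SNPs in its transcript + upstream window.

    The window is [start - upstream_bp, end] on the + strand and
    [start, end + upstream_bp] on the - strand (1-based inclusive). A
    SNP inside two overlapping genes is assigned to both.
    """
    _validate_snps(snps)
    _validate_genes(genes)
    out: dict[str, set[str]] = {}
    for chrom, gchunk in genes.groupby("chr", sort=False):
        schunk = snps[snps["chr"] == chrom]
        if schunk.empty:
            continue
        pos = schunk["pos"].to_numpy()
        ids = schunk["snp_id"].to_numpy()
        for rec in gchunk.itertuples(index=False):
            if rec.strand == "+":
                lo, hi = rec.start - upstream_bp, rec.end
            else:
                lo, hi = rec.start, rec.end + upstream_bp
            hit = (pos >= lo) & (pos <= hi)
            if hit.any():
                out.setdefault(rec.gene_id, set()).update(ids[hit])
    return out


def cluster_snps_by_ld(
    snp_set,
    ld_table: pd.DataFrame,
    r2_threshold: float = 0.80,
    direction: str = "ge",
) -> list[set[str]]:
    """Single-linkage proxy clusters of SNPs in high LD.

    Connected components of the graph whose edges are SNP pairs with
    r² >= threshold (``direction='le'`` flips the comparison); SNPs
    with no qualifying partner are singletons. Pairs absent from the
    LD table count as r² = 0.
    """
    members = set(snp_set)
    parent = {s: s for s in members}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    if len(members) and len(ld_table):
        sub = ld_table[
            ld_table["snp_a"].isin(members) & ld_table["snp_b"].isin(members)
        ]
        if direction == "ge":
            sub = sub[sub["r2"] >= r2_threshold]
        elif direction == "le":
            sub = sub[sub["r2"] <= r2_threshold]
        else:
            raise ValueError("direction must be 'ge' or 'le'")
        for a, b in zip(sub["snp_a"], sub["snp_b"]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    clusters: dict[str, set[str]] = {}
    for s in members:
        clusters.setdefault(find(s), set()).add(s)
    return sorted(clusters.values(), key=lambda c: sorted(c)[0])


def gene_wide_pvalue(
    gene_snp_map: dict[str, set[str]],
    snp_p: pd.Series | dict,
    ld_table: pd.DataFrame | None = None,
    r2_threshold: float = 0.80,
    direction: str = "ge",
) -> pd.DataFrame:
    """Gene-wide p-value = min over singleton and proxy-cluster p-values.

    Cluster p-values are the minimum member p; since min-of-mins equals
    the global minimum, the gene p-value is invariant to how the
    clustering partitions the SNPs — clusters are still computed and
    counted for reporting. Genes with no assigned SNPs are omitted.
    """
    snp_p = pd.Series(snp_p)
    rows = []
    for gene in sorted(gene_snp_map):
        snps = gene_snp_map[gene]
        if not snps:
            continue
        if ld_table is not None:
            clusters = cluster_snps_by_ld(
                snps, ld_table, r2_threshold, direction
            )
        else:
            clusters = [{s} for s in sorted(snps)]
        p_gene = min(min(snp_p[s] for s in c) for c in clusters)
        rows.append((gene, float(p_gene), len(snps), len(clusters)))
    return pd.DataFrame(
        rows, columns=["gene_id", "p_gene", "n_snps", "n_clusters"]
    )


def select_candidate_genes(
    gene_pvalues: pd.DataFrame, alpha: float = 0.05
) -> set[str]:
    """Nominally significant genes at inclusive gene-wide p <= alpha."""
    keep = gene_pvalues["p_gene"] <= alpha
    return set(gene_pvalues.loc[keep, "gene_id"])


def prioritize(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    ld_table: pd.DataFrame,
    upstream_bp: int = 1000,
    r2_threshold: float = 0.80,
    alpha: float = 0.05,
    direction: str = "ge",
):
    """Full stage-I pass: returns (gene_pvalues table, candidate set)."""
    mapping = assign_snps_to_genes(snps, genes, upstream_bp)
    snp_p = snps.set_index("snp_id")["p"]
    table = gene_wide_pvalue(mapping, snp_p, ld_table, r2_threshold, direction)
    return table, select_candidate_genes(table, alpha)
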
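"""Weighted gene coexpression network construction and module analysis.

The network over genes is built from pairwise Pearson correlations
raised to a soft-thresholding power beta, a_ij = |cor(x_i, x_j)|^beta,
with beta chosen so the connectivity distribution approximates
scale-free topology (signed R^2 of the log-log frequency fit >= 0.8).
Pairwise topological overlap

    TOM_ij = (sum_{u != i} a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{u != i} a_ui converts shared-neighbor
agreement into a similarity; 1 - TOM is the dissimilarity for
average-linkage hierarchical clustering. Branches of the dendrogram are
modules; each module is summarized by its eigengene (first principal
component of the standardized module submatrix). Per-gene statistics:

* gene significance GS = |cor(gene, trait)|;
* module membership kME = |cor(gene, module eigengene)|;
* hub genes have kME > 0.8 and GS > 0.2, or the largest intramodular
  connectivity.

Module-trait relationships are age-adjusted partial correlations of the
eigengenes with the phenotypes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

__all__ = [
    "adjacency",
    "scale_free_fit_index",
    "pick_soft_threshold",
    "tom",
    "cluster_modules",
    "module_eigengenes",
    "module_trait_association",
    "gene_significance",
    "module_membership",
    "identify_hub_genes",
    "enrichment_test",
    "CoexpressionNetwork",
    "MODULE_COLORS",
]

# canonical color sequence used to label modules by decreasing size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
]
GREY = "grey"


def _cor_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the t transform."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def adjacency(expr: pd.DataFrame, beta: float = 6) -> pd.DataFrame:
    """Soft-threshold adjacency a_ij = |Pearson cor(x_i, x_j)|^beta."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = expr.to_numpy().std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])
        raise ValueError(f"constant gene row(s): {bad[:5]}")
    c = np.corrcoef(expr.to_numpy())
    a = np.abs(c) ** beta
    np.fill_diagonal(a, 1.0)
    adj = pd.DataFrame(a, index=expr.index, columns=expr.index)
    adj.attrs["beta"] = beta
    return adj


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit.

    Connectivities are binned into ``n_bins`` equal-width bins;
    log10(frequency) is regressed on log10(mean connectivity) over
    non-empty bins. The returned R^2 carries the sign of minus the
    slope, so a decreasing log-log relation (the scale-free shape)
    scores positive.
    """
    k = np.asarray(k, dtype=float)
    if np.unique(k).size < n_bins:
        raise ValueError(
            f"need at least {n_bins} distinct connectivity values"
        )
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            log_freq.append(np.log10(sel.mean()))
            log_k.append(np.log10(k[sel].mean()))
    slope, _, r, _, _ = stats.linregress(log_k, log_freq)
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    betas=tuple(range(1, 21)),
    r2_target: float = 0.8,
    n_bins: int = 10,
):
    """Smallest power whose network attains signed scale-free R^2 >=
    target; falls back to the best power with a warning if none does.

    Returns ``(beta, profile)`` where profile is a DataFrame of the
    signed R^2 and mean connectivity per candidate power.
    """
    betas = list(betas)
    if betas != sorted(betas):
        raise ValueError("betas must be ascending")
    absc = np.abs(np.corrcoef(expr.to_numpy()))
    np.fill_diagonal(absc, 0.0)
    rows = []
    for b in betas:
        a = absc**b
        k = a.sum(axis=0)
        try:
            r2 = scale_free_fit_index(k, n_bins=n_bins)
        except ValueError:
            r2 = np.nan
        rows.append((b, r2, float(k.mean())))
    profile = pd.DataFrame(rows, columns=["beta", "signed_r2", "mean_k"])
    ok = profile[profile["signed_r2"] >= r2_target]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
    else:
        chosen = int(profile.loc[profile["signed_r2"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate power reached signed R^2 >= {r2_target}; "
            f"using beta={chosen} with R^2="
            f"{profile['signed_r2'].max():.3f}"
        )
    return chosen, profile


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    Off-diagonal entries apply the shared-neighbor formula with
    connectivity k_i excluding the diagonal; the diagonal is 1 by
    convention.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    t = num / den
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def _branch_labels(clusters: np.ndarray, min_module_size: int) -> np.ndarray:
    """Keep clusters of at least ``min_module_size`` genes, numbered by
    decreasing size; everything else 0."""
    sizes = pd.Series(clusters).value_counts()
    keep = sizes.index[sizes >= min_module_size]
    labels = np.zeros(len(clusters), dtype=int)
    for new, cl in enumerate(
        sorted(keep, key=lambda c: (-sizes[c], c)), start=1
    ):
        labels[clusters == cl] = new
    return labels


def _rank_normalize(diss: np.ndarray) -> np.ndarray:
    """Rank-transform a dissimilarity to a uniform [0, 1] scale.

    TOM dissimilarities are often compressed into a narrow band (e.g.
    just below 1 at high powers); ranks make the silhouette criterion
    scale-free.
    """
    cond = squareform(diss, checks=False)
    ranks = stats.rankdata(cond) / len(cond)
    out = squareform(ranks)
    return out


def _branch_silhouettes(diss: np.ndarray, labels: np.ndarray) -> dict:
    """Mean silhouette per branch on the (rank-normalized) TOM
    dissimilarity.

    Unassigned genes form one pseudo-cluster that competes as a
    neighbor, so a branch indistinguishable from the background scores
    near zero.
    """
    groups = {
        m: np.flatnonzero(labels == m) for m in range(1, labels.max() + 1)
    }
    grey = np.flatnonzero(labels == 0)
    if len(grey):
        groups[0] = grey
    out = {}
    for m in range(1, labels.max() + 1):
        own = groups[m]
        scores, tightness = [], []
        for i in own:
            a = diss[i, own].sum() / (len(own) - 1)
            b = min(
                diss[i, grp].mean()
                for g, grp in groups.items()
                if g != m and len(grp)
            )
            scores.append((b - a) / max(a, b))
            tightness.append(a)
        # a real module is denser than a random gene set: its mean
        # within-branch rank must beat the 0.5 expected under no
        # structure, otherwise it is background that merely looks
        # separated because true modules are tighter still
        if np.mean(tightness) >= 0.5:
            out[m] = -np.inf
        else:
            out[m] = float(np.mean(scores))
    return out


def _static_cut(
    diss: np.ndarray,
    min_module_size: int,
    cut_quantiles,
    min_silhouette: float,
):
    """Candidate branches from the best static cut of the average-
    linkage tree.

    The tree is cut at each quantile of its merge heights in
    ``cut_quantiles``; branches of at least ``min_module_size`` genes
    are candidates, each scored by its mean silhouette width on the
    rank-normalized dissimilarity (separation from the other branches
    and from the unassigned background). A branch is sound when its
    score clears ``min_silhouette``; the cut producing the most sound
    branches wins, ties broken by their mean score, and only the sound
    branches are kept. Structureless data keeps nothing.
    """
    link = average(squareform(diss, checks=False))
    heights = link[:, 2]
    ranked = _rank_normalize(diss)
    candidates = []
    seen: set = set()
    for q in cut_quantiles:
        clusters = fcluster(
            link, t=float(np.quantile(heights, q)), criterion="distance"
        )
        labels = _branch_labels(clusters, min_module_size)
        key = labels.tobytes()
        if labels.max() == 0 or key in seen:
            continue
        seen.add(key)
        scores = _branch_silhouettes(ranked, labels)
        good = [m for m, s in scores.items() if s > min_silhouette]
        if good:
            kept = np.where(np.isin(labels, good), labels, 0)
            candidates.append(
                (len(good), float(np.mean([scores[m] for m in good])), kept)
            )
    if not candidates:
        return np.zeros(diss.shape[0], dtype=int)
    best = max(candidates, key=lambda c: (c[0], c[1]))[2]
    # renumber the surviving branches by decreasing size (0 stays
    # unassigned)
    sizes = pd.Series(best[best > 0]).value_counts()
    out = np.zeros_like(best)
    for new, cl in enumerate(
        sorted(sizes.index, key=lambda c: (-sizes[c], c)), start=1
    ):
        out[best == cl] = new
    return out


DEFAULT_CUT_QUANTILES = (
    0.99, 0.95, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1,
)


def cluster_modules(
    diss_tom: pd.DataFrame,
    expr: pd.DataFrame | None = None,
    min_module_size: int = 30,
    cut_quantiles=DEFAULT_CUT_QUANTILES,
    min_silhouette: float = 0.2,
    kme_attach: float = 0.3,
    deep_split: int = 2,
) -> pd.Series:
    """Module labels from average-linkage clustering of 1 - TOM.

    Two passes: (1) a static cut of the dendrogram — chosen among the
    ``cut_quantiles`` quantiles of the merge heights by silhouette
    width, see :func:`_static_cut` — keeps branches of at least
    ``min_module_size`` genes as candidate modules; (2) when ``expr``
    is given, unassigned genes are attached to the module whose
    eigengene they correlate with most strongly, provided that kME
    exceeds ``kme_attach``. Remaining genes are labelled grey. Modules
    are named by decreasing size following the conventional color
    sequence. ``deep_split`` is accepted for configuration
    compatibility and has no effect.
    """
    del deep_split
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    genes = diss_tom.index
    labels = _static_cut(
        diss_tom.to_numpy(dtype=float),
        min_module_size,
        cut_quantiles,
        min_silhouette,
    )
    if expr is not None and (labels == 0).any() and labels.max() > 0:
        tmp = pd.Series(labels, index=genes)
        mes = module_eigengenes(expr, tmp.map(str).where(tmp > 0, GREY))
        sub = expr.loc[genes[labels == 0]]
        kme = _kme_matrix(sub, mes)
        best = kme.idxmax(axis=1)
        best_val = kme.max(axis=1)
        for gene in sub.index:
            if best_val[gene] > kme_attach:
                labels[genes.get_loc(gene)] = int(best[gene])
    # map to colors by decreasing final size
    out = pd.Series(GREY, index=genes, name="module", dtype=object)
    sizes = pd.Series(labels[labels > 0]).value_counts()
    for rank, cl in enumerate(
        sorted(sizes.index, key=lambda c: (-sizes[c], c))
    ):
        color = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module{rank + 1}"
        )
        out[labels == cl] = color
    return out


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First-principal-component summary profile per module.

    The module submatrix is gene-standardized, the first right singular
    vector gives per-sample scores, scaled to unit variance and
    sign-aligned so the average member gene correlates positively with
    its eigengene. Grey (unassigned) genes get no eigengene. Returns a
    samples x modules frame with columns ``ME<color>``.
    """
    mes = {}
    for module in sorted(set(labels) - {GREY}):
        sub = expr.loc[labels.index[labels == module]].to_numpy(dtype=float)
        if sub.shape[0] < 2:
            raise ValueError(f"module {module} has fewer than 2 genes")
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd
        # SVD-based first PC over samples; robust to singular submatrices
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        if np.mean([np.corrcoef(row, me)[0, 1] for row in z]) < 0:
            me = -me
        mes[f"ME{module}"] = me
    return pd.DataFrame(mes, index=expr.columns)


def _partial_corr(x: np.ndarray, y: np.ndarray, covar: np.ndarray):
    """Residual-on-residual Pearson correlation controlling covariates."""
    design = np.column_stack([np.ones_like(x), covar])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def module_trait_association(
    me: pd.Series | np.ndarray,
    trait: pd.Series | np.ndarray,
    age: pd.Series | np.ndarray,
) -> dict:
    """Age-adjusted correlation of a module eigengene with a trait.

    Partial Pearson correlation controlling age, with a two-sided p from
    the t transform at n - 3 degrees of freedom; binary traits enter as
    0/1. Returns ``{"r", "p", "r2"}`` where r2 is the squared partial
    correlation (variance explained after the age adjustment).
    """
    me = np.asarray(me, dtype=float)
    trait = np.asarray(trait, dtype=float)
    age = np.asarray(age, dtype=float)
    if trait.std() == 0:
        raise ValueError("trait has zero variance")
    n = len(me)
    r = _partial_corr(me, trait, age)
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt((n - 3) / (1 - r_**2))
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return {"r": r, "p": float(p), "r2": r**2}


def gene_significance(
    expr_row: pd.Series | np.ndarray, trait: pd.Series | np.ndarray
) -> tuple[float, float]:
    """GS = |Pearson cor(gene, trait)| with its two-sided p-value."""
    x = np.asarray(expr_row, dtype=float)
    y = np.asarray(trait, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    return abs(r), float(_cor_pvalue(r, len(x)))


def _kme_matrix(expr: pd.DataFrame, mes: pd.DataFrame) -> pd.DataFrame:
    x = expr.to_numpy(dtype=float)
    m = mes.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    mz = (m - m.mean(axis=0)) / m.std(axis=0)
    kme = np.abs(xz @ mz / x.shape[1])
    cols = [c.removeprefix("ME") for c in mes.columns]
    return pd.DataFrame(kme, index=expr.index, columns=cols)


def module_membership(expr: pd.DataFrame, mes: pd.DataFrame):
    """kME of every gene against every module eigengene.

    kME_q(i) = |cor(x_i, ME_q)|, reported for members and non-members
    alike. Returns ``(kme, p)`` frames of shape genes x modules.
    """
    kme = _kme_matrix(expr, mes)
    p = pd.DataFrame(
        _cor_pvalue(kme.to_numpy(), expr.shape[1]),
        index=kme.index,
        columns=kme.columns,
    )
    return kme, p


def identify_hub_genes(
    gs: pd.Series,
    kme: pd.DataFrame,
    labels: pd.Series,
    mm_cut: float = 0.8,
    gs_cut: float = 0.2,
    mode: str = "criteria",
    adj: pd.DataFrame | None = None,
) -> dict[str, list[str]]:
    """Hub genes per module.

    ``criteria`` mode: genes with kME to their own module strictly
    above ``mm_cut`` and GS strictly above ``gs_cut``. The
    ``max_connectivity`` mode returns each module's gene of maximal
    intramodular connectivity (sum of adjacency to module co-members;
    requires ``adj``); ties break by gene id order.
    """
    hubs: dict[str, list[str]] = {}
    for module in sorted(set(labels) - {GREY}):
        members = labels.index[labels == module]
        if mode == "criteria":
            sel = [
                g
                for g in members
                if kme.loc[g, module] > mm_cut and gs[g] > gs_cut
            ]
            hubs[module] = sorted(sel)
        elif mode == "max_connectivity":
            if adj is None:
                raise ValueError("max_connectivity mode needs the adjacency")
            sub = adj.loc[members, members].to_numpy(dtype=float).copy()
            np.fill_diagonal(sub, 0.0)
            conn = pd.Series(sub.sum(axis=0), index=members)
            top = conn[conn == conn.max()].index.sort_values()[0]
            hubs[module] = [top]
        else:
            raise ValueError("mode must be 'criteria' or 'max_connectivity'")
    return hubs


def enrichment_test(
    module_genes, category_map: dict, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of categories in a module.

    fold = (k/n) / (K/N) and upper-tail hypergeometric p for drawing k
    category genes in a module of n from a universe of N containing K;
    Bonferroni adjustment across the tested categories. Categories with
    no gene in the universe are skipped with a warning.
    """
    universe = set(universe)
    module = set(module_genes)
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    n, n_universe = len(module), len(universe)
    rows = []
    for cat, genes in sorted(category_map.items()):
        cat_genes = set(genes) & universe
        if not cat_genes:
            warnings.warn(f"category {cat!r} absent from universe; skipped")
            continue
        big_k = len(cat_genes)
        k = len(cat_genes & module)
        fold = (k / n) / (big_k / n_universe) if n else 0.0
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n)) if k else 1.0
        rows.append((cat, k, big_k, fold, p))
    out = pd.DataFrame(
        rows, columns=["category", "k", "K", "fold", "p"]
    )
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


class CoexpressionNetwork(BaseEstimator):
    """Weighted coexpression network with module detection.

    Scikit-learn-style estimator over a genes x samples DataFrame.
    ``fit`` builds the adjacency (choosing the soft threshold when
    ``beta`` is None), the topological overlap matrix, the module
    partition, eigengenes and kME tables.

    Fitted attributes: ``beta_``, ``adjacency_``, ``tom_``, ``labels_``,
    ``eigengenes_``, ``kme_``, ``kme_p_``.
    """

    def __init__(
        self,
        beta: int | None = 6,
        r2_target: float = 0.8,
        min_module_size: int = 30,
        cut_quantiles=DEFAULT_CUT_QUANTILES,
        min_silhouette: float = 0.2,
        kme_attach: float = 0.3,
        mm_cut: float = 0.8,
        gs_cut: float = 0.2,
    ):
        self.beta = beta
        self.r2_target = r2_target
        self.min_module_size = min_module_size
        self.cut_quantiles = cut_quantiles
        self.min_silhouette = min_silhouette
        self.kme_attach = kme_attach
        self.mm_cut = mm_cut
        self.gs_cut = gs_cut

    def fit(self, X: pd.DataFrame, y=None):
        if self.beta is None:
            self.beta_, self.threshold_profile_ = pick_soft_threshold(
                X, r2_target=self.r2_target
            )
        else:
            self.beta_ = self.beta
        self.adjacency_ = adjacency(X, self.beta_)
        self.tom_ = tom(self.adjacency_)
        self.labels_ = cluster_modules(
            1.0 - self.tom_,
            expr=X,
            min_module_size=self.min_module_size,
            cut_quantiles=self.cut_quantiles,
            min_silhouette=self.min_silhouette,
            kme_attach=self.kme_attach,
        )
        self.eigengenes_ = module_eigengenes(X, self.labels_)
        self.kme_, self.kme_p_ = module_membership(X, self.eigengenes_)
        self._expr = X
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_

    def module_trait_table(
        self, traits: pd.DataFrame, age_col: str = "age"
    ) -> pd.DataFrame:
        """Age-adjusted module-trait partial correlations and p-values."""
        age = traits[age_col]
        rows = []
        for me_col in self.eigengenes_.columns:
            for trait in traits.columns:
                if trait == age_col:
                    continue
                res = module_trait_association(
                    self.eigengenes_[me_col], traits[trait], age
                )
                rows.append(
                    (me_col.removeprefix("ME"), trait, res["r"], res["p"],
                     res["r2"])
                )
        return pd.DataFrame(
            rows, columns=["module", "trait", "r", "p", "r2"]
        )

    def gene_significance_table(self, trait: pd.Series) -> pd.DataFrame:
        """GS and p-value of every gene against a trait."""
        rows = [
            (g, *gene_significance(self._expr.loc[g], trait))
            for g in self._expr.index
        ]
        return pd.DataFrame(rows, columns=["gene_id", "gs", "p"]).set_index(
            "gene_id"
        )

    def hub_genes(
        self, trait: pd.Series, mode: str = "criteria"
    ) -> dict[str, list[str]]:
        gs = self.gene_significance_table(trait)["gs"]
        return identify_hub_genes(
            gs,
            self.kme_,
            self.labels_,
            mm_cut=self.mm_cut,
            gs_cut=self.gs_cut,
            mode=mode,
            adj=self.adjacency_,
        )
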
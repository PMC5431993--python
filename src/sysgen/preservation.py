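"""Module preservation between a discovery and a test dataset.

Whether a module found in a reference (discovery) network is still a
module in an independent test network is quantified by permutation Z
statistics. Two density statistics ask whether the module genes remain
interconnected in the test data (mean intra-module correlation, mean
intra-module adjacency at the reference soft threshold) and two
connectivity statistics ask whether the connection pattern is similar
across datasets (correlation of intramodular connectivity vectors;
correlation of the vectorized intra-module correlation matrices). Each
observed statistic is standardized against a permutation null in which
the module label is reassigned to random same-size gene sets of the
test network; Zdensity and Zconnectivity are the medians of their two
component Z scores and Zsummary is their mean. The conventional reading
is Zsummary < 2 no evidence, 2-10 weak to moderate, >= 10 strong
evidence of preservation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["PreservationResult", "preservation_stats", "zsummary",
           "ModulePreservation"]

_STATS = ("mean_cor", "mean_adj", "cor_kim", "cor_cor")


@dataclass
class PreservationResult:
    module: str
    observed: dict
    perm_mean: dict
    perm_sd: dict
    z: dict
    z_density: float
    z_connectivity: float
    z_summary: float
    n_permutations: int


def _module_stats(
    ref: np.ndarray, test: np.ndarray, beta: float
) -> dict[str, float]:
    """The four preservation statistics for one gene set.

    ``ref``/``test`` are module-genes x samples blocks from the two
    datasets (rows aligned).
    """
    cr = np.corrcoef(ref)
    ct = np.corrcoef(test)
    iu = np.triu_indices_from(ct, k=1)
    mean_cor = float(ct[iu].mean())
    mean_adj = float((np.abs(ct[iu]) ** beta).mean())
    ar = np.abs(cr) ** beta
    at = np.abs(ct) ** beta
    np.fill_diagonal(ar, 0.0)
    np.fill_diagonal(at, 0.0)
    cor_kim = float(np.corrcoef(ar.sum(axis=0), at.sum(axis=0))[0, 1])
    cor_cor = float(np.corrcoef(cr[iu], ct[iu])[0, 1])
    return {
        "mean_cor": mean_cor,
        "mean_adj": mean_adj,
        "cor_kim": cor_kim,
        "cor_cor": cor_cor,
    }


def preservation_stats(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    labels: pd.Series,
    module: str,
    beta: float = 6,
) -> dict[str, float]:
    """Observed density and connectivity preservation statistics.

    Uses the genes of ``module`` present in both datasets; raises when
    fewer than 4 are shared.
    """
    genes = labels.index[labels == module]
    shared = [
        g for g in genes if g in ref_expr.index and g in test_expr.index
    ]
    if len(shared) < 4:
        raise ValueError(
            f"module {module}: only {len(shared)} genes shared between "
            "reference and test data"
        )
    if len(shared) < len(genes):
        warnings.warn(
            f"module {module}: {len(shared)}/{len(genes)} genes shared"
        )
    return _module_stats(
        ref_expr.loc[shared].to_numpy(dtype=float),
        test_expr.loc[shared].to_numpy(dtype=float),
        beta,
    )


def zsummary(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    labels: pd.Series,
    module: str,
    n_perm: int = 100,
    beta: float = 6,
    seed: int = 0,
) -> PreservationResult:
    """Permutation Zsummary of one module in a test dataset.

    The null reassigns the module label to uniformly drawn gene sets of
    equal size from all test-network genes (the observed assignment is
    excluded); each statistic is standardized by its permutation mean
    and sd. Zdensity / Zconnectivity are medians of the two density /
    connectivity Z scores and Zsummary is their mean.
    """
    if n_perm < 50:
        raise ValueError("need at least 50 permutations")
    genes = labels.index[labels == module]
    shared = [
        g for g in genes if g in ref_expr.index and g in test_expr.index
    ]
    observed = preservation_stats(ref_expr, test_expr, labels, module, beta)
    pool = [g for g in test_expr.index if g in ref_expr.index]
    size = len(shared)
    rng = np.random.default_rng(seed)
    ref_mat = ref_expr.loc[pool].to_numpy(dtype=float)
    test_mat = test_expr.loc[pool].to_numpy(dtype=float)
    observed_set = set(shared)
    perm = {s: np.empty(n_perm) for s in _STATS}
    done = 0
    while done < n_perm:
        idx = rng.choice(len(pool), size=size, replace=False)
        if {pool[i] for i in idx} == observed_set:
            continue
        stats_p = _module_stats(ref_mat[idx], test_mat[idx], beta)
        for s in _STATS:
            perm[s][done] = stats_p[s]
        done += 1
    perm_mean = {s: float(perm[s].mean()) for s in _STATS}
    perm_sd = {s: float(perm[s].std(ddof=1)) for s in _STATS}
    z = {}
    for s in _STATS:
        if perm_sd[s] == 0:
            warnings.warn(f"zero permutation sd for {s}; Z set to +inf")
            z[s] = float("inf")
        else:
            z[s] = (observed[s] - perm_mean[s]) / perm_sd[s]
    z_density = float(np.median([z["mean_cor"], z["mean_adj"]]))
    z_connectivity = float(np.median([z["cor_kim"], z["cor_cor"]]))
    return PreservationResult(
        module=module,
        observed=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        z=z,
        z_density=z_density,
        z_connectivity=z_connectivity,
        z_summary=(z_density + z_connectivity) / 2.0,
        n_permutations=n_perm,
    )


class ModulePreservation(BaseEstimator):
    """Estimator interface: ``fit`` stores the reference network, and
    ``score_modules`` evaluates Zsummary per module in a test dataset."""

    def __init__(self, n_perm: int = 100, beta: float = 6, seed: int = 0):
        self.n_perm = n_perm
        self.beta = beta
        self.seed = seed

    def fit(self, ref_expr: pd.DataFrame, labels: pd.Series):
        self.ref_expr_ = ref_expr
        self.labels_ = labels
        return self

    def score_modules(
        self, test_expr: pd.DataFrame, modules=None
    ) -> dict[str, PreservationResult]:
        if modules is None:
            modules = sorted(set(self.labels_) - {"grey"})
        return {
            m: zsummary(
                self.ref_expr_,
                test_expr,
                self.labels_,
                m,
                n_perm=self.n_perm,
                beta=self.beta,
                seed=self.seed,
            )
            for m in modules
        }
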
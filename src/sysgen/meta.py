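"""Differential expression and cross-study meta-analysis.

Per-dataset differential expression uses empirical-Bayes moderated
statistics: each gene's linear model (group effect, optional covariates
such as age) yields a residual variance s^2 that is shrunk toward a
common prior, s2_post = (d0*s0^2 + d*s^2) / (d0 + d), where the prior
degrees of freedom d0 and scale s0^2 come from moment-matching a scaled
F distribution to the observed log s^2 ensemble. Moderated t uses
s2_post with d0 + d degrees of freedom; the moderated F tests a set of
contrasts simultaneously.

Across studies, evidence is combined two ways:

* Fisher's method, chi^2 = -2 * sum(ln p_i), referred to chi-square
  with 2k degrees of freedom where k counts the studies in which the
  gene was measured;
* standardized mean differences (Hedges g with small-sample
  correction), pooled by inverse variance under a fixed-effects model
  or, when Cochran's Q has p < 0.05 or I^2 > 50%, a DerSimonian-Laird
  random-effects model. The pooled z can additionally be calibrated by
  within-study label permutation.

All multiple-testing adjustment is Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "moderated_t",
    "moderated_f_contrasts",
    "fold_change",
    "fisher_combine",
    "smd",
    "heterogeneity",
    "pooled_effect",
    "permutation_p",
    "bh_fdr",
    "meta_analyze",
    "squeeze_var",
]


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (x > 0); used to moment-match
    the prior degrees of freedom."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    return float(
        optimize.brentq(lambda y: special.polygamma(1, y) - x, 1e-8, 1e8)
    )


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene variances toward a common prior.

    Moment-matching on log s^2: with e = log s2 - digamma(df/2) +
    log(df/2), the excess variance of e over trigamma(df/2) identifies
    the prior df d0 through trigamma(d0/2), and the prior scale s0^2
    through the mean of e. Returns ``(s2_post, d0, s0_2)``; ``d0`` is
    ``inf`` when the s^2 ensemble is no more dispersed than chi-square
    sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    e = np.log(np.where(ok, s2, np.nan))
    e = e - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = np.nanmean(e)
    e_var = np.nanvar(e, ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        s2_post = np.full_like(s2, s0_2)
    return s2_post, float(d0), s0_2


def _fit_linear(x: np.ndarray, y: np.ndarray):
    """OLS of every gene (rows of y) on design x: returns coefficients
    (genes x p), residual variances and residual df."""
    n, p = x.shape
    pinv = np.linalg.pinv(x)
    coef = y @ pinv.T
    resid = y - coef @ x.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    return coef, s2, df, pinv


def _design_matrix(group, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(group)), np.asarray(group, dtype=float)]
    names = ["intercept", "group"]
    for i, cov in enumerate(covariates or []):
        cols.append(np.asarray(cov, dtype=float))
        name = getattr(cov, "name", None) or f"cov{i + 1}"
        names.append(str(name))
    return np.column_stack(cols), names


def moderated_t(
    expr: pd.DataFrame,
    group,
    covariates=None,
) -> pd.DataFrame:
    """Per-gene moderated t-test of a group effect, adjusting covariates.

    Fits gene ~ intercept + group (+ covariates), shrinks the residual
    variances with :func:`squeeze_var` and tests the group coefficient
    with d0 + d degrees of freedom. With fewer than 3 residual df the
    shrinkage is unreliable and ordinary per-gene t-tests are used with
    a warning. Returns a frame indexed by gene with ``coef``, ``t``,
    ``p``, ``fdr``, ``s2``, ``s2_post``, ``df_total``.
    """
    g = np.asarray(group, dtype=float)
    if min((g == v).sum() for v in np.unique(g)) < 2:
        raise ValueError("need at least 2 samples per group")
    x, _ = _design_matrix(g, covariates)
    y = expr.to_numpy(dtype=float)
    coef, s2, df, pinv = _fit_linear(x, y)
    unscaled = float((pinv @ pinv.T)[1, 1])  # Var(b_group) / sigma^2
    if df < 3:
        warnings.warn(
            f"only {df} residual df; falling back to ordinary t-statistics"
        )
        s2_post, d0 = s2, 0.0
    else:
        s2_post, d0, _ = squeeze_var(s2, df)
    se = np.sqrt(unscaled * s2_post)
    t = coef[:, 1] / se
    # d0 = inf (no excess variance dispersion) degenerates to a normal
    # reference; scipy needs a finite df
    df_total = min(d0 + df, 1e9)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return pd.DataFrame(
        {
            "coef": coef[:, 1],
            "t": t,
            "p": p,
            "fdr": bh_fdr(p),
            "s2": s2,
            "s2_post": s2_post,
            "df_total": df_total,
        },
        index=expr.index,
    )


def moderated_f_contrasts(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: np.ndarray | pd.DataFrame,
) -> pd.DataFrame:
    """Moderated F over a contrast set (all contrasts zero at once).

    ``design`` is samples x parameters, ``contrasts`` parameters x q.
    F = (C'b)' [C'(X'X)^-1 C]^-1 (C'b) / (q * s2_post), with p from
    F(q, d0 + d). A rank-deficient design raises, naming the aliased
    columns.
    """
    x = np.asarray(design, dtype=float)
    names = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{i}" for i in range(x.shape[1])
    ]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        r = np.linalg.qr(x, mode="r")
        aliased = [names[i] for i in range(x.shape[1])
                   if abs(r[i, i]) < 1e-10]
        raise ValueError(f"design is rank deficient; aliased: {aliased}")
    c = np.asarray(contrasts, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    q = c.shape[1]
    y = expr.to_numpy(dtype=float)
    coef, s2, df, _ = _fit_linear(x, y)
    s2_post, d0, _ = squeeze_var(s2, df) if df >= 3 else (s2, 0.0, None)
    xtx_inv = np.linalg.inv(x.T @ x)
    mid = np.linalg.inv(c.T @ xtx_inv @ c)
    cb = coef @ c                      # genes x q
    quad = np.einsum("gq,qr,gr->g", cb, mid, cb)
    f = quad / (q * s2_post)
    df_total = min(d0 + df, 1e9)
    p = stats.f.sf(f, q, df_total)
    return pd.DataFrame(
        {"F": f, "p": p, "fdr": bh_fdr(p), "df_total": df_total},
        index=expr.index,
    )


def fold_change(
    expr: pd.DataFrame, mask_a, mask_b, scale: str = None
) -> pd.Series:
    """Natural-scale fold change of condition A over condition B.

    The input must be declared ``scale='log2'``; FC = 2^(mean_A - mean_B)
    per gene.
    """
    if scale != "log2":
        raise ValueError("declare the input scale explicitly: scale='log2'")
    a = expr.loc[:, np.asarray(mask_a, dtype=bool)].mean(axis=1)
    b = expr.loc[:, np.asarray(mask_b, dtype=bool)].mean(axis=1)
    return (2.0 ** (a - b)).rename("fold_change")


# ---------------------------------------------------------------------------
# meta-analysis primitives


def fisher_combine(p_list) -> tuple[float, float]:
    """Fisher's method: chi^2 = -2 sum(ln p) on chi-square with 2k df.

    Missing entries (NaN) are dropped and k reduced accordingly; p = 0
    raises (clamp upstream if needed).
    """
    p = np.asarray(
        [v for v in p_list if v is not None and not np.isnan(v)], dtype=float
    )
    if (p <= 0).any() or (p > 1).any():
        raise ValueError(
            "p-values must lie in (0, 1]; clamp zero p-values upstream"
        )
    k = len(p)
    chi2 = float(-2.0 * np.log(p).sum())
    return chi2, float(stats.chi2.sf(chi2, df=2 * k))


def smd(group_a, group_b) -> tuple[float, float]:
    """Hedges-corrected standardized mean difference and its variance.

    g = J * (mean_a - mean_b) / pooled_sd with
    J = 1 - 3 / (4 (nA + nB - 2) - 1); variance
    (nA + nB) / (nA nB) + g^2 / (2 (nA + nB)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (na + nb - 2) - 1.0)
    g = j * d
    var_g = (na + nb) / (na * nb) + g**2 / (2.0 * (na + nb))
    return float(g), float(var_g)


def heterogeneity(effects, variances) -> tuple[float, float, float]:
    """Cochran's Q, I^2 (percent, floored at 0) and the Q-test p-value."""
    g = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(g) < 2:
        raise ValueError("need at least 2 studies")
    if (v <= 0).any():
        raise ValueError("variances must be positive")
    w = 1.0 / v
    pooled = (w * g).sum() / w.sum()
    q = float((w * (g - pooled) ** 2).sum())
    k = len(g)
    q_p = float(stats.chi2.sf(q, df=k - 1))
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    return q, i2, q_p


def pooled_effect(effects, variances, rule: str = "auto") -> dict:
    """Inverse-variance pooled effect with model selection.

    ``fixed`` uses weights 1/v; ``random`` adds the DerSimonian-Laird
    tau^2 to every variance; ``auto`` chooses random when the Q test
    has p < 0.05 or I^2 > 50%. Returns pooled estimate, SE, symmetric
    95% CI, z, normal p, and the heterogeneity summary.
    """
    g = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    q, i2, q_p = heterogeneity(g, v)
    k = len(g)
    if rule == "auto":
        model = "random" if (q_p < 0.05 or i2 > 50.0) else "fixed"
    elif rule in ("fixed", "random"):
        model = rule
    else:
        raise ValueError("rule must be auto, fixed or random")
    w = 1.0 / v
    tau2 = 0.0
    if model == "random":
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom)
        w = 1.0 / (v + tau2)
    pooled = float((w * g).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    z = pooled / se
    return {
        "model": model,
        "pooled": pooled,
        "se": se,
        "ci_low": pooled - 1.96 * se,
        "ci_high": pooled + 1.96 * se,
        "z": float(z),
        "p": float(2.0 * stats.norm.sf(abs(z))),
        "Q": q,
        "I2": i2,
        "Q_p": q_p,
        "tau2": float(tau2),
    }


def _gene_pooled_z(studies, gene, rule="auto") -> float:
    effects, variances = [], []
    for study in studies:
        if gene not in study.expression.index:
            continue
        x = study.expression.loc[gene].to_numpy(dtype=float)
        grp = study.group.to_numpy()
        g, v = smd(x[grp == 1], x[grp == 0])
        effects.append(g)
        variances.append(v)
    return pooled_effect(effects, variances, rule=rule)["z"]


def permutation_p(
    study_collection,
    gene: str,
    b: int = 1000,
    seed: int = 0,
    rule: str = "auto",
) -> float:
    """Within-study label-permutation p-value for the pooled z.

    Group labels are permuted independently inside each study, the
    pooled z is recomputed, and perm_p = (1 + #{|z_b| >= |z_obs|}) /
    (B + 1).
    """
    rng = np.random.default_rng(seed)
    z_obs = abs(_gene_pooled_z(study_collection, gene, rule))
    rows = []
    for study in study_collection:
        if gene in study.expression.index:
            rows.append(
                (
                    study.expression.loc[gene].to_numpy(dtype=float),
                    study.group.to_numpy().copy(),
                )
            )
    count = 0
    for _ in range(b):
        effects, variances = [], []
        for x, grp in rows:
            perm = rng.permutation(grp)
            g, v = smd(x[perm == 1], x[perm == 0])
            effects.append(g)
            variances.append(v)
        if abs(pooled_effect(effects, variances, rule=rule)["z"]) >= z_obs:
            count += 1
    return (1 + count) / (b + 1)


def bh_fdr(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept.

    adj_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_list, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# full cross-study analysis


def meta_analyze(
    studies,
    genes=None,
    adjust_age: bool = True,
    b_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fisher + effect-size meta-analysis over a study collection.

    Per study, a moderated t-test of obese vs non-obese (age-adjusted
    when ages are available) gives the p-value entering Fisher's
    method; per study SMDs are pooled under the auto fixed/random rule.
    ``b_perm > 0`` adds a permutation p-value for the pooled z. Returns
    one row per gene with Fisher statistic/p/FDR, per-gene study count,
    pooled SMD with CI, z, p, FDR, Q, I2 and model.
    """
    de_tables = []
    for study in studies:
        covs = [study.age] if (adjust_age and study.age is not None) else None
        de = moderated_t(study.expression, study.group, covariates=covs)
        de_tables.append(de)
    if genes is None:
        genes = sorted(set().union(*(set(t.index) for t in de_tables)))
    rows = []
    for gene in genes:
        pvals = [
            t.loc[gene, "p"] for t in de_tables if gene in t.index
        ]
        chi2, fisher_p = fisher_combine(pvals)
        effects, variances = [], []
        for study in studies:
            if gene not in study.expression.index:
                continue
            x = study.expression.loc[gene].to_numpy(dtype=float)
            grp = study.group.to_numpy()
            g, v = smd(x[grp == 1], x[grp == 0])
            effects.append(g)
            variances.append(v)
        pe = pooled_effect(effects, variances, rule="auto")
        rows.append(
            {
                "gene_id": gene,
                "k": len(pvals),
                "fisher_stat": chi2,
                "fisher_p": fisher_p,
                "smd": pe["pooled"],
                "ci_low": pe["ci_low"],
                "ci_high": pe["ci_high"],
                "z": pe["z"],
                "smd_p": pe["p"],
                "Q": pe["Q"],
                "I2": pe["I2"],
                "model": pe["model"],
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out["fisher_fdr"] = bh_fdr(out["fisher_p"])
    out["smd_fdr"] = bh_fdr(out["smd_p"])
    if b_perm > 0:
        perm = [
            permutation_p(studies, gene, b=b_perm, seed=seed + i)
            for i, gene in enumerate(out.index)
        ]
        out["perm_p"] = perm
        out["perm_fdr"] = bh_fdr(out["perm_p"])
    return out
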
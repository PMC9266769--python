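"""Per-gene differential expression on RNA-seq counts.

The model is the standard negative-binomial GLM for counts
``K_ij ~ NB(mean = s_j * mu_ij, dispersion alpha_i)`` with
``Var = mu + alpha * mu^2`` and a log link, fitted per gene by IRLS with
the log size factor as offset.  Coefficients are reported in log2 units
and tested with a Wald z statistic; p-values are BH-adjusted.

Normalisation uses median-of-ratios size factors; dispersions come from
a method-of-moments estimate shrunk in log space toward a fitted
``alpha(mu) = a0 + a1/mu`` trend.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CountMatrix, DEResult, DesignSpec

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
ALPHA_FLOOR = 1e-8
P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# filtering


def filter_low_counts(
    cm: CountMatrix, min_total: int | str = "auto", primary_factor: str = "group"
) -> CountMatrix:
    """Remove genes whose total count across all samples is below a minimum.

    ``min_total="auto"`` uses the size of the smallest level of
    ``primary_factor`` — i.e. at least one count per sample of the
    smallest sample group.
    """
    if min_total == "auto":
        if primary_factor not in cm.samples.columns:
            raise ValueError(f"factor {primary_factor!r} not in sample table")
        min_total = int(cm.samples[primary_factor].value_counts().min())
    min_total = int(min_total)
    keep = cm.counts.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError(f"no gene has at least {min_total} total counts")
    logger.info("count filter >= %d: kept %d / %d genes", min_total, keep.sum(), len(keep))
    return cm.subset_genes(cm.counts.index[keep])


def filter_unannotated(cm: CountMatrix) -> CountMatrix:
    """Keep genes with a full complement of annotations.

    Requires non-missing ``chromosome``, ``full_name`` and ``entrez``
    (cross-reference) entries in the annotation table.
    """
    if cm.annotation is None:
        raise ValueError("count matrix carries no annotation table")
    ann = cm.annotation
    required = [c for c in ("chromosome", "full_name", "entrez") if c in ann.columns]
    keep = ann[required].notna().all(axis=1)
    for col in required:
        if ann[col].dtype == object:
            keep &= ann[col].astype(str).str.len() > 0
    logger.info("annotation filter: kept %d / %d genes", keep.sum(), len(keep))
    return cm.subset_genes(cm.counts.index[keep])


# ---------------------------------------------------------------------------
# normalisation and dispersion


def estimate_size_factors(
    counts: pd.DataFrame, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the size factor is the median over reference genes
    of the ratio of its count to the gene's geometric mean across
    samples.  Reference genes are those with all-positive counts; when
    none exists a pseudo-reference built from positive counts only can
    be enabled with ``allow_pseudo_reference``.
    """
    k = counts.to_numpy(dtype=float)
    positive = (k > 0).all(axis=1)
    if positive.any():
        logk = np.log(k[positive])
        ref = logk.mean(axis=1)  # log geometric mean per gene
        s = np.exp(np.median(logk - ref[:, None], axis=0))
    elif allow_pseudo_reference:
        with np.errstate(divide="ignore"):
            logk = np.where(k > 0, np.log(k), np.nan)
        ok = (~np.isnan(logk)).sum(axis=1) > 0
        if not ok.any():
            raise ValueError("count matrix is all zero")
        logk = logk[ok]
        ref = np.nanmean(logk, axis=1)
        s = np.exp(np.nanmedian(logk - ref[:, None], axis=0))
    else:
        raise ValueError(
            "no gene has positive counts in every sample; pass "
            "allow_pseudo_reference=True to use a positive-count pseudo-reference"
        )
    if not np.all(s > 0):
        raise ValueError("non-positive size factor estimated")
    return pd.Series(s, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``alpha(mu) = a0 + a1/mu`` with outlier trimming."""
    use = (alpha > ALPHA_FLOOR * 10) & (mu > 0)
    if use.sum() < 2:
        a = float(np.median(alpha)) if len(alpha) else 0.01
        return max(a, 1e-6), 0.0
    x, y = 1.0 / mu[use], alpha[use]
    for _ in range(3):
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = np.abs(y - A @ coef)
        keep = resid <= 3 * np.median(resid) + 1e-12
        if keep.all() or keep.sum() < 2:
            break
        x, y = x[keep], y[keep]
    a0 = max(float(coef[0]), 1e-6)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series | None = None,
    shrink: bool = True,
) -> tuple[pd.Series, tuple[float, float]]:
    """Per-gene NB dispersion by method of moments, with trend shrinkage.

    Moments are taken on normalised counts ``y = K/s``; when ``groups``
    is given, the variance pools within-level deviations so planted
    group effects do not inflate the estimate.  The moment estimator is
    ``alpha = (Var(y) - mean(1/s) * mean(y)) / mean(y)^2`` floored at
    1e-8; a trend ``alpha(mu) = a0 + a1/mu`` is fitted across genes and,
    with ``shrink=True``, each log dispersion is averaged equally with
    the log trend value (genes at the floor are left at the floor).

    Returns the dispersion series and the fitted ``(a0, a1)`` trend.
    """
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float) / s
    n = y.shape[1]
    mu = y.mean(axis=1)
    if groups is None:
        resid = y - mu[:, None]
        dof = n - 1
    else:
        g = pd.Categorical(groups.loc[counts.columns])
        resid = np.empty_like(y)
        for code in range(len(g.categories)):
            cols = g.codes == code
            if cols.sum() < 2:
                raise ValueError(
                    f"level {g.categories[code]!r} has fewer than 2 samples"
                )
            sub = y[:, cols]
            resid[:, cols] = sub - sub.mean(axis=1, keepdims=True)
        dof = n - len(g.categories)
    var = (resid**2).sum(axis=1) / max(dof, 1)
    xim = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - xim * mu) / mu**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.maximum(raw, ALPHA_FLOOR)
    a0, a1 = _fit_dispersion_trend(mu, raw)
    if shrink:
        trend = a0 + np.divide(a1, mu, out=np.full_like(mu, np.inf), where=mu > 0)
        at_floor = raw <= ALPHA_FLOOR
        alpha = np.exp(0.5 * (np.log(raw) + np.log(np.maximum(trend, ALPHA_FLOOR))))
        alpha[at_floor] = ALPHA_FLOOR
    else:
        alpha = raw
    return pd.Series(alpha, index=counts.index, name="dispersion"), (a0, a1)


# ---------------------------------------------------------------------------
# NB GLM with Wald test


def _design_matrix(
    samples: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Treatment-coded design matrix plus the contrast vector.

    Reference level is alphabetically first unless ``design.reference``
    is set.  The contrast vector extracts ``contrast[0] - contrast[1]``
    on the primary-factor coefficients.
    """
    fac = samples[design.factor].astype(str)
    levels = sorted(fac.unique())
    ref = design.reference or levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not present")
    for lvl in design.contrast:
        if lvl not in levels:
            raise ValueError(f"contrast level {lvl!r} not present in {design.factor!r}")
    cols: list[np.ndarray] = [np.ones(len(fac))]
    names = ["intercept"]
    coef_of = {ref: None}
    for lvl in levels:
        if lvl == ref:
            continue
        coef_of[lvl] = len(names)
        cols.append((fac == lvl).to_numpy(dtype=float))
        names.append(f"{design.factor}[{lvl}]")
    if design.covariate is not None:
        cov = samples[design.covariate].astype(str)
        clevels = sorted(cov.unique())
        for lvl in clevels[1:]:
            cols.append((cov == lvl).to_numpy(dtype=float))
            names.append(f"{design.covariate}[{lvl}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    c = np.zeros(X.shape[1])
    for lvl, sign in zip(design.contrast, (1.0, -1.0)):
        idx = coef_of[lvl]
        if idx is not None:
            c[idx] += sign
    return X, names, c


def fit_nb_wald(
    cm: CountMatrix,
    design: DesignSpec,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> DEResult:
    """Fit per-gene NB GLMs and Wald-test the contrast coefficient.

    All genes share the design matrix, so the IRLS iterations are
    vectorised across genes.  The offset is ``log(s_j)``; coefficients
    are converted to log2 units for reporting.  The Wald statistic is
    ``beta_hat / SE(beta_hat)`` against the zero null, with a two-sided
    normal p-value, BH-adjusted across all fitted genes.  Genes that do
    not converge are flagged and carry NaN test results.
    """
    counts = cm.counts
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions, trend = estimate_dispersions(
            counts, size_factors, groups=cm.samples[design.factor]
        )
    else:
        trend = None
    X, _, cvec = _design_matrix(cm.samples, design)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    k = counts.to_numpy(dtype=float)
    alpha = dispersions.loc[counts.index].to_numpy(dtype=float)[:, None]
    G, n = k.shape
    p = X.shape[1]
    offset = np.log(s)[None, :]

    # initialise with a log-linear least-squares fit on pseudocounts
    z0 = np.log((k + 0.5) / s)
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T  # (G, p)

    # means are floored at min_mu and the working response is built from
    # the floored mean, so genes with a sample group at zero counts
    # (complete separation) reach a finite LFC with an informative SE
    # instead of drifting to infinity
    min_mu = 0.5

    def clamped_mu(b):
        return np.maximum(np.exp(np.clip(b @ X.T + offset, -30, 30)), min_mu)

    def deviance(b, rows=slice(None)):
        mu = clamped_mu(b)
        kk, aa = k[rows], alpha[rows]
        # -2 * NB log likelihood, dropping beta-independent terms
        return -2.0 * (kk * np.log(mu) - (kk + 1.0 / aa) * np.log1p(aa * mu)).sum(axis=1)

    dev = deviance(beta)
    active = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        mu = clamped_mu(beta)
        W = mu / (1.0 + alpha * mu)
        z = np.log(mu) - offset + (k - mu) / mu
        XtWX = np.einsum("ji,gj,jk->gik", X, W[active], X)
        XtWz = np.einsum("ji,gj,gj->gi", X, W[active], z[active])
        XtWX += np.eye(p)[None, :, :] * 1e-6
        new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        delta = np.max(np.abs(new - beta[active]), axis=1)
        beta[active] = np.clip(new, -30 / LN2, 30 / LN2)
        new_dev = deviance(beta[active], active)
        dev_change = np.abs(new_dev - dev[active]) / (np.abs(new_dev) + 0.1)
        still = (delta > tol) & (dev_change > tol)
        idx = np.flatnonzero(active)
        dev[active] = new_dev
        active[idx[~still]] = False
        if not active.any():
            break
    converged = ~active
    if active.any():
        logger.warning("%d genes did not converge in %d IRLS iterations",
                       int(active.sum()), max_iter)

    mu = clamped_mu(beta)
    W = mu / (1.0 + alpha * mu)
    XtWX = np.einsum("ji,gj,jk->gik", X, W, X) + np.eye(p)[None, :, :] * 1e-10
    cov = np.linalg.inv(XtWX)
    se_ln = np.sqrt(np.einsum("i,gij,j->g", cvec, cov, cvec))
    b_ln = beta @ cvec
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = b_ln / se_ln
    pvals = 2.0 * sps.norm.sf(np.abs(stat))
    pvals = np.maximum(pvals, P_FLOOR)
    pvals[~converged] = np.nan
    stat = np.where(converged, stat, np.nan)

    table = pd.DataFrame(
        {
            "baseMean": (k / s).mean(axis=1),
            "log2FC": b_ln / LN2,
            "SE": se_ln / LN2,
            "stat": stat,
            "p": pvals,
            "q": benjamini_hochberg(pvals),
            "passed_filter": True,
            "converged": converged,
        },
        index=counts.index,
    )
    table.loc[~converged, ["log2FC", "SE"]] = np.nan
    return DEResult(
        table=table,
        size_factors=size_factors,
        dispersions=dispersions,
        design=design,
        dispersion_trend=trend,
    )


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1).

    NaN entries are propagated and do not count toward the number of
    tests; values outside (0, 1] raise.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv <= 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


# ---------------------------------------------------------------------------
# variance stabilising transformation


def vst(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    trend: tuple[float, float],
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Variance stabilising transformation for NB counts.

    With the dispersion trend ``alpha(mu) = a0 + a1/mu`` the closed-form
    transform of the normalised count ``q = K/s`` is::

        v(q) = log2( (1 + a1 + 2*a0*q + 2*sqrt(a0*q*(1 + a1 + a0*q))) / (4*a0) )

    which is finite at 0 and approaches ``log2 q`` (plus a constant) for
    large counts, so a two-fold change maps to a difference of 1.
    ``method="shifted_log"`` falls back to ``log2(q + 1)``.
    """
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    q = counts.to_numpy(dtype=float) / s
    a0, a1 = trend
    if method == "shifted_log" or a0 <= 0:
        v = np.log2(q + 1.0)
    elif method == "asymptotic":
        v = np.log2(
            (1.0 + a1 + 2.0 * a0 * q + 2.0 * np.sqrt(a0 * q * (1.0 + a1 + a0 * q)))
            / (4.0 * a0)
        )
    else:
        raise ValueError(f"unknown VST method {method!r}")
    return pd.DataFrame(v, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``x``.  The
    p-value is exact (enumeration) when ``n1 + n2 <= 12`` and there are
    no ties, otherwise the normal approximation with tie and continuity
    correction is used.  Identical pooled values give ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n1 = x.size
    W = float(sps.rankdata(pooled)[:n1].sum())
    if np.all(pooled == pooled[0]):
        return W, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return W, float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# gender x inflammation stratified follow-up


def gender_stratified_union(
    de_by_stratum: dict[str, DEResult], q_threshold: float = 0.05
) -> pd.Index:
    """Union of gender-DE genes across sample strata."""
    genes: set = set()
    for res in de_by_stratum.values():
        genes |= set(res.significant(q_threshold).index)
    return pd.Index(sorted(genes))


def gender_stratified_procedure(
    cm: CountMatrix,
    de_by_stratum: dict[str, DEResult],
    vst_values: pd.DataFrame,
    group_factor: str = "group",
    gender_factor: str = "gender",
    inflamed_level: str = "UC.I",
    male_level: str = "male",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Follow-up of gender-DE genes in relation to inflammation.

    Takes per-stratum gender DE results (one ``DEResult`` per sample
    group), forms the union of gender-DE genes, and re-tests each of
    them for association with inflammation using a per-gene two-sample
    Wilcoxon test on VST values (inflamed vs non-inflamed samples),
    separately within males and within females.  Y-linked genes are
    evaluated in males only.  P-values are BH-adjusted per gender and
    each gene is classified as concordant / male-only / female-only
    up- or downregulation.
    """
    genes = gender_stratified_union(de_by_stratum, q_threshold)
    genes = genes.intersection(vst_values.index)
    if cm.annotation is not None and "chromosome" in cm.annotation.columns:
        chrom = cm.annotation["chromosome"].reindex(genes).astype(str)
    else:
        chrom = pd.Series("", index=genes)
    inflamed = cm.samples[group_factor] == inflamed_level
    rows = []
    for gene in genes:
        row: dict = {"gene": gene, "chromosome": chrom.loc[gene]}
        y_linked = chrom.loc[gene].upper() in {"Y", "CHRY"}
        for gender in sorted(cm.samples[gender_factor].astype(str).unique()):
            is_male = gender == male_level
            key = "male" if is_male else "female"
            if y_linked and not is_male:
                row[f"{key}_p"] = np.nan
                row[f"{key}_delta"] = np.nan
                continue
            sel = cm.samples[gender_factor].astype(str) == gender
            gi = vst_values.loc[gene, (sel & inflamed).to_numpy()]
            gn = vst_values.loc[gene, (sel & ~inflamed).to_numpy()]
            if len(gi) < 2 or len(gn) < 2:
                logger.warning("stratum %s has <2 samples per side for %s", gender, gene)
                row[f"{key}_p"] = np.nan
                row[f"{key}_delta"] = np.nan
                continue
            _, pval = wilcoxon_two_sample(gi.to_numpy(), gn.to_numpy())
            row[f"{key}_p"] = pval
            row[f"{key}_delta"] = float(np.median(gi) - np.median(gn))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["chromosome", "male_p", "male_delta", "female_p", "female_delta"]
    )
    for key in ("male", "female"):
        if f"{key}_p" in out.columns:
            out[f"{key}_q"] = benjamini_hochberg(out[f"{key}_p"])
        else:
            out[f"{key}_p"] = np.nan
            out[f"{key}_q"] = np.nan
            out[f"{key}_delta"] = np.nan

    def classify(r) -> str:
        def sig(key):
            return (not np.isnan(r[f"{key}_q"])) and r[f"{key}_q"] <= q_threshold

        def direction(key):
            return "up" if r[f"{key}_delta"] > 0 else "down"

        m, f = sig("male"), sig("female")
        if m and f:
            if direction("male") == direction("female"):
                return f"concordant_{direction('male')}"
            return "discordant"
        if m:
            return f"male_only_{direction('male')}"
        if f:
            return f"female_only_{direction('female')}"
        return "ns"

    out["category"] = out.apply(classify, axis=1) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# fold-change helpers


def log2fc_to_fold(log2fc: float) -> float:
    """Fold change corresponding to a log2 fold change (e.g. 3.32 -> ~10)."""
    return float(2.0 ** np.abs(log2fc))


def fold_to_log2fc(fold: float) -> float:
    """log2 fold change corresponding to a fold change (e.g. 10 -> ~3.32)."""
    if fold <= 0:
        raise ValueError("fold change must be positive")
    return float(np.log2(fold))
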
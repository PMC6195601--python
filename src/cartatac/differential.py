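"""Covariate-adjusted negative-binomial differential testing.

Per-feature NB log-linear models compare the damaged (iMT) against the intact
(oLT) compartment with an offset for the RLE effective library size and any
per-sample quality covariates (mean-centered) in the design.  Dispersions are
method-of-moments estimates shrunk 50/50 toward the across-feature median;
inference is a Wald test on the compartment coefficient, adjusted with
Benjamini-Hochberg.  The same machinery is reused for gene expression counts
(without the accessibility QC covariate).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .atlas import effective_library_size, rle_size_factors

DISPERSION_FLOOR = 1e-4
DIRECTION_LABELS = {
    "accessibility": ("more_accessible", "less_accessible"),
    "expression": ("up", "down"),
}


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1).

    NaN entries (untested features) are passed through as NaN and do not
    count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ps = p[ok]
    m = ps.size
    if m:
        order = np.argsort(ps, kind="mergesort")
        ranked = ps[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.minimum(adj, 1.0)
        out[ok] = vals
    return out


def _moment_dispersions(counts: np.ndarray, norm: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-feature NB dispersion (Var = mu + alpha*mu^2) by pooled within-group
    moments on normalized counts, shrunk 50/50 toward the median."""
    z = counts / norm[None, :]
    raw = np.full(counts.shape[0], np.nan)
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for g in np.unique(groups):
        sel = groups == g
        n = int(sel.sum())
        if n < 2:
            continue
        m = z[:, sel].mean(axis=1)
        v = z[:, sel].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m ** 2
        w = n - 1
        good = np.isfinite(a)
        num[good] += w * a[good]
        den[good] += w
    ok = den > 0
    raw[ok] = num[ok] / den[ok]
    raw = np.clip(raw, DISPERSION_FLOOR, None)
    common = np.nanmedian(raw) if np.isfinite(raw).any() else DISPERSION_FLOOR
    shrunk = 0.5 * np.where(np.isfinite(raw), raw, common) + 0.5 * common
    return np.clip(shrunk, DISPERSION_FLOOR, None)


def build_design(meta: pd.DataFrame, covariates=(), log_covariate: bool = False,
                 paired: bool = False):
    """Design matrix: intercept, iMT indicator, centered covariates, and
    optionally patient fixed effects."""
    n = len(meta)
    cols = {"intercept": np.ones(n)}
    cols["compartment_iMT"] = (meta["compartment"].values == "iMT").astype(float)
    for cov in covariates:
        x = meta[cov].values.astype(float)
        if log_covariate:
            x = np.log(x)
        cols[cov] = x - x.mean()
    if paired:
        patients = pd.unique(meta["patient"])
        for p in patients[1:]:
            cols[f"patient_{p}"] = (meta["patient"].values == p).astype(float)
    X = pd.DataFrame(cols, index=meta["sample"].values)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name a minimal offending column for the error message
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X.values[:, :j]) < j:
                raise ValueError(f"singular design: column {X.columns[j-1]!r} is collinear")
    return X


def fit_nb_glm(counts: pd.DataFrame, meta: pd.DataFrame, covariates=("dhs_score",),
               log_covariate: bool = False, paired: bool = False,
               size_factors: pd.Series | None = None, maxiter: int = 100) -> pd.DataFrame:
    """Per-feature NB GLM Wald test of iMT vs oLT.

    Returns a frame indexed by feature with columns ``log2fc`` (iMT over oLT),
    ``pvalue``, ``dispersion`` and ``converged``.  All-zero features are
    flagged (``converged`` False, ``pvalue`` NaN) and excluded from testing.
    """
    for comp in ("oLT", "iMT"):
        if (meta["compartment"] == comp).sum() < 2:
            raise ValueError(f"need >= 2 samples in compartment {comp}")
    counts = counts[list(meta["sample"])]
    if size_factors is None:
        size_factors = rle_size_factors(counts)
    eff = effective_library_size(counts, size_factors).values
    offset = np.log(eff)
    norm = eff / np.exp(np.mean(np.log(eff)))
    X = build_design(meta, covariates=covariates, log_covariate=log_covariate, paired=paired)
    y_all = counts.values.astype(float)
    groups = meta["compartment"].values
    disp = _moment_dispersions(y_all, norm, groups)
    j = int(list(X.columns).index("compartment_iMT"))

    log2fc = np.zeros(len(counts))
    pval = np.full(len(counts), np.nan)
    converged = np.zeros(len(counts), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, y in enumerate(y_all):
            if not y.any():
                continue
            fam = sm.families.NegativeBinomial(alpha=float(disp[i]))
            try:
                res = sm.GLM(y, X.values, family=fam, offset=offset).fit(
                    maxiter=maxiter, tol=1e-8)
                beta = res.params[j]
                se = res.bse[j]
                if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
                    raise ValueError("degenerate fit")
                log2fc[i] = beta / np.log(2)
                pval[i] = 2 * stats.norm.sf(abs(beta / se))
                converged[i] = bool(getattr(res, "converged", True))
            except Exception:
                log2fc[i] = 0.0
                pval[i] = 1.0
                converged[i] = False
    # non-converged fits are reported as null per contract
    log2fc[~converged & ~np.isnan(pval)] = 0.0
    pval[~converged & ~np.isnan(pval)] = 1.0
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pval, "dispersion": disp,
                         "converged": converged}, index=counts.index)


def classify(table: pd.DataFrame, threshold: float = 0.05,
             kind: str = "accessibility") -> pd.DataFrame:
    """Attach BH FDR and a direction label; significant means FDR <= threshold."""
    up_label, down_label = DIRECTION_LABELS[kind]
    out = table.copy()
    out["fdr"] = bh_fdr(out["pvalue"].values)
    sig = out["fdr"].values <= threshold
    direction = np.where(~np.isfinite(out["fdr"].values), "ns",
                         np.where(sig & (out["log2fc"].values > 0), up_label,
                                  np.where(sig & (out["log2fc"].values < 0), down_label, "ns")))
    out["direction"] = direction
    return out


def summarize_directions(table: pd.DataFrame, kind: str = "accessibility") -> dict:
    up_label, down_label = DIRECTION_LABELS[kind]
    n_up = int((table["direction"] == up_label).sum())
    n_down = int((table["direction"] == down_label).sum())
    return {"n_significant": n_up + n_down, f"n_{up_label}": n_up, f"n_{down_label}": n_down}


def differential_table(counts: pd.DataFrame, meta: pd.DataFrame, threshold: float = 0.05,
                       covariates=("dhs_score",), kind: str = "accessibility",
                       **kwargs) -> pd.DataFrame:
    """Fit, adjust and classify in one call; the standard entry point."""
    fitted = fit_nb_glm(counts, meta, covariates=covariates, **kwargs)
    return classify(fitted, threshold=threshold, kind=kind)
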
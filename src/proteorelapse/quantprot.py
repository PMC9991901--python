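"""Cohort-level protein statistics.

Gene-symbol-centric quantification, complete-case filtering, paired
differential abundance with an empirical-Bayes moderated t (variances shrunk
toward a scaled inverse-chi-square prior fitted by moment matching on the
log sample variances), Wilcoxon matched-pairs and Spearman tests, PCA,
hypergeometric gene-set over-representation, and the mitochondrial-DNA
depth-ratio analysis of paired diagnosis/relapse samples.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


# ------------------------------------------------------------ gene-centric quant

def gene_centric_quant(
    peptide_matrix: pd.DataFrame, peptide_genes: pd.Series
) -> pd.DataFrame:
    """Gene x sample matrix of median peptide-level log2 ratios.

    ``peptide_matrix`` is peptide x sample (log2 ratios); ``peptide_genes``
    maps each peptide to a ``;``-separated list of gene symbols. Peptides
    shared between genes are dropped; a gene with no unique peptide in a
    sample gets a missing value.
    """
    genes = peptide_genes.reindex(peptide_matrix.index)
    unique = genes[genes.notna() & ~genes.astype(str).str.contains(";")]
    mat = peptide_matrix.loc[unique.index].copy()
    mat["__gene__"] = unique.astype(str)
    return mat.groupby("__gene__").median().rename_axis("gene")


def complete_case_filter(matrix: pd.DataFrame, cohort_samples: list[str]) -> pd.DataFrame:
    """Rows with no missing value across the cohort's samples."""
    sub = matrix[cohort_samples]
    return matrix.loc[sub.notna().all(axis=1)]


# ------------------------------------------------------------ moderated t

def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = _trigamma(y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of ``log(s2)`` against the theoretical
    moments of a scaled F distribution, returning ``(d0, s0_sq)``; infinite
    ``d0`` means all variances are shrunk to a common value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("variance prior fit needs >=2 positive sample variances")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(_trigamma(df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t(diffs: pd.DataFrame, prior_df: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated one-sample t on paired differences.

    Rows are features, columns are pairs (values d_i = relapse - diagnosis on
    the log2 scale). Per row the mean difference and sample variance are
    combined with a fitted inverse-chi-square prior:
    ``s2_post = (d0*s0^2 + dg*s2) / (d0 + dg)``,
    ``t = mean / sqrt(s2_post / n)`` on ``d0 + dg`` degrees of freedom;
    p-values are two-sided, BH-adjusted across rows.

    ``prior_df`` overrides the fitted d0 (0 recovers the classical paired t;
    ``inf`` pools all variances).
    """
    x = diffs.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(x).any():
        raise ValueError("diffs must be complete; filter rows first")
    m = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    dg = float(n - 1)

    if prior_df is not None:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2[s2 > 0])) if np.isfinite(d0) and d0 > 0 else float(s2.mean())
    else:
        try:
            d0, s0_sq = fit_variance_prior(s2, dg)
        except ValueError:
            warnings.warn("degenerate variances; falling back to classical paired t")
            d0, s0_sq = 0.0, 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = dg
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(s2_post / n)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "gene": diffs.index.to_numpy(),
            "log2fc": m,
            "t": t,
            "p_value": p,
            "fdr": bh_adjust(p),
            "direction": np.where(m > 0, "up", np.where(m < 0, "down", "none")),
        }
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def paired_differences(
    matrix: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Relapse minus diagnosis per feature and pair (columns = patient ids)."""
    d = matrix[pairs["relapse"].tolist()].to_numpy(dtype=float) - matrix[
        pairs["diagnosis"].tolist()
    ].to_numpy(dtype=float)
    return pd.DataFrame(d, index=matrix.index, columns=pairs["patient_id"].tolist())


# ------------------------------------------------------------ classical tests

def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test (two-sided).

    Zero differences are dropped per convention. Exact enumeration-based
    p-values for n <= 25 without ties; normal approximation with tie and
    continuity correction otherwise. All-zero differences yield P = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors with >= 4 pairs")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; P = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=(method == "approx"))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, float(res.pvalue)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked) with t-approximation P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined")
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ------------------------------------------------------------ PCA

def pca_overview(matrix: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores of a row-centered SVD plus explained-variance fractions."""
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("PCA needs a complete matrix")
    centered = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(k, len(s))
    scores = pd.DataFrame(
        (vt[:k].T * s[:k]),
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    explained = (s**2) / (s**2).sum()
    return scores, explained[:k]


# ------------------------------------------------------------ gene sets

def geneset_enrichment(
    hits: set[str], background: set[str], gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Hypergeometric over-representation per gene set.

    Enrichment score is the observed/expected overlap ratio
    ``(k/n) / (K/N)``; P is the hypergeometric upper tail; FDR is BH across
    sets. Requires hits to be a subset of the background.
    """
    if not hits <= background:
        raise ValueError("hit genes must be a subset of the background")
    N, n = len(background), len(hits)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & background
        K = len(in_bg)
        k = len(in_bg & hits)
        if n == 0 or K == 0:
            score, p = 0.0, 1.0
        else:
            score = (k / n) / (K / N)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"gene_set": name, "set_size": K, "overlap": k, "score": score, "p_value": p})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p_value"]) if len(df) else []
    return df


# ------------------------------------------------------------ mtDNA ratio

def mtdna_ratio(depth: pd.DataFrame, pairs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Relapse/diagnosis mitochondrial depth-ratio percentages per pair.

    Per sample ``r = mt_depth / nuclear_depth``; each pair contributes
    ``100 * r_relapse / r_diagnosis``. The one-sample Wilcoxon signed-rank
    test compares the pair values against the theoretical median 100
    (exact for n <= 25). Pairs with a missing mate are skipped and logged.
    """
    d = depth.set_index("sample_id")
    if (d[["mt_depth", "nuclear_depth"]] <= 0).any().any():
        raise ValueError("depths must be strictly positive")
    rows = []
    for row in pairs.itertuples():
        if row.diagnosis not in d.index or row.relapse not in d.index:
            logger.info("pair %s missing a depth summary; skipped", row.patient_id)
            continue
        r_d = d.loc[row.diagnosis, "mt_depth"] / d.loc[row.diagnosis, "nuclear_depth"]
        r_r = d.loc[row.relapse, "mt_depth"] / d.loc[row.relapse, "nuclear_depth"]
        rows.append({"patient_id": row.patient_id, "ratio_pct": 100.0 * r_r / r_d})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no complete pairs with depth summaries")
    values = table["ratio_pct"].to_numpy()
    if np.allclose(values, 100.0):
        p = 1.0
    elif len(values) < 4:
        warnings.warn("fewer than 4 pairs: signed-rank test undefined")
        p = np.nan
    else:
        _, p = wilcoxon_paired(values, np.full_like(values, 100.0))
    return table, float(p)
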
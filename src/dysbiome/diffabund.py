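"""Taxon-level screening: rank tests, fold changes, effect sizes, growth fits.

Covers the univariate Kruskal-Wallis screen, Benjamini-Hochberg FDR,
log-linear two-group fold-change contrasts (total-sum scaling, log2 with a
per-taxon half-minimum pseudocount, pooled-variance t), a simplified
two-class LDA effect-size procedure, taxon-taxon Pearson correlations, and
ordinary least-squares fits of log10 CFU against time.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, to_relative

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "kruskal_wallis_table",
    "bh_fdr",
    "loglm_diffabund",
    "lda_effect_size",
    "taxon_correlation",
    "GrowthFit",
    "cfu_growth_fit",
]


@dataclass(frozen=True)
class TestResult:
    taxon: str
    statistic: float  # Kruskal-Wallis H
    p_value: float
    q_value: float | None = None


def kruskal_wallis(values, groups, taxon: str = "") -> TestResult:
    """Kruskal-Wallis rank-sum test with mid-rank tie correction.

    p-values come from the chi-square approximation with (a - 1) degrees of
    freedom. A data vector with all values identical has H = 0 and p = 1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape[0] != g.shape[0]:
        raise ValueError("values and groups must have the same length")
    names = np.unique(g)
    if len(names) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    samples = [v[g == name] for name in names]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(v == v[0]):
        return TestResult(taxon, 0.0, 1.0)
    h, p = stats.kruskal(*samples)
    return TestResult(taxon, float(h), float(p))


def kruskal_wallis_table(table: CountTable, groups) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis screen with BH q-values."""
    g = _group_vector(table, groups)
    rows = []
    for taxon in table.taxon_ids:
        res = kruskal_wallis(table.data.loc[taxon].to_numpy(), g, taxon=taxon)
        rows.append((taxon, res.statistic, res.p_value))
    df = pd.DataFrame(rows, columns=["taxon", "statistic", "p_value"]).set_index("taxon")
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_vector(table: CountTable, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        return groups.loc[table.sample_ids].to_numpy()
    if isinstance(groups, dict):
        return np.array([groups[s] for s in table.sample_ids])
    arr = np.asarray(groups)
    if arr.shape[0] != table.n_samples:
        raise ValueError("group vector length does not match sample count")
    return arr


def loglm_diffabund(
    table: CountTable,
    group_a,
    group_b,
    contrast_name: str = "B_vs_A",
) -> pd.DataFrame:
    """Two-group log-linear fold-change screen across taxa.

    Per taxon: total-sum normalization, log2(relative abundance +
    pseudocount) with the pseudocount set to half the smallest nonzero
    relative abundance of that taxon across all samples of the table (not
    just the contrasted ones), then Log2FC = mean(B) - mean(A) with a
    pooled-variance two-sample t-test.
    q-values are BH across tested taxa. Taxa absent from both groups are
    reported with missing statistics. Note: this fixes one reasonable
    normalization; exact numeric agreement with other log-linear
    implementations is not expected.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("contrast groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each contrast group needs at least 2 samples")
    rel = to_relative(table) if table.unit == "counts" else table
    full = rel.data.to_numpy()
    A = rel.data[group_a].to_numpy()
    B = rel.data[group_b].to_numpy()
    na, nb = len(group_a), len(group_b)
    rows = []
    for k, taxon in enumerate(rel.taxon_ids):
        nonzero = full[k][full[k] > 0]
        if nonzero.size == 0 or (A[k].sum() == 0 and B[k].sum() == 0):
            rows.append((taxon, contrast_name, np.nan, np.nan, np.nan))
            continue
        pc = nonzero.min() / 2.0
        la, lb = np.log2(A[k] + pc), np.log2(B[k] + pc)
        lfc = lb.mean() - la.mean()
        var_a, var_b = la.var(ddof=1), lb.var(ddof=1)
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        se = np.sqrt(pooled * (1 / na + 1 / nb))
        if se == 0:
            p = 1.0 if lfc == 0 else 0.0
        else:
            t = lfc / se
            p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
        rows.append((taxon, contrast_name, float(lfc), float(se), float(p)))
    df = pd.DataFrame(
        rows, columns=["taxon", "contrast", "log2fc", "se", "p_value"]
    ).set_index("taxon")
    tested = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    q[tested.to_numpy()] = bh_fdr(df.loc[tested, "p_value"].to_numpy())
    df["q_value"] = q
    return df


def lda_effect_size(
    table: CountTable,
    classes,
    alpha: float = 0.05,
    cutoff: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-class discriminant effect sizes after a Kruskal-Wallis screen.

    Stage 1 keeps taxa with BH-FDR q < ``alpha``. Stage 2 scales relative
    abundances to a per-million range and, over ``n_boot`` bootstrap rounds
    that each draw two-thirds of every class, measures the absolute
    class-mean difference; for a single feature this coincides with the
    displacement of the class means along its (unit-normalized) Fisher
    discriminant axis. The reported LDA score is log10 of the bootstrap mean
    effect (clipped below at 1, so scores are >= 0). A taxon "passes" when
    q < alpha and |score| > cutoff.

    This is a deliberately simplified, deterministic-under-seed effect-size
    screen: the useful surface is which taxa pass, not score-exact agreement
    with any other tool.
    """
    g = _group_vector(table, classes)
    names = np.unique(g)
    if len(names) != 2:
        raise ValueError(f"exactly 2 classes required, got {len(names)}")
    n1, n2 = (g == names[0]).sum(), (g == names[1]).sum()
    if n1 < 3 or n2 < 3:
        raise ValueError("each class needs at least 3 samples")
    rel = to_relative(table) if table.unit == "counts" else table
    screen = kruskal_wallis_table(rel, g)
    ppm = rel.values * 1e6
    idx1, idx2 = np.where(g == names[0])[0], np.where(g == names[1])[0]
    rng = np.random.default_rng(seed)
    k1, k2 = max(2, int(np.ceil(2 * n1 / 3))), max(2, int(np.ceil(2 * n2 / 3)))
    effects = np.zeros((n_boot, rel.n_taxa))
    for b in range(n_boot):
        s1 = rng.choice(idx1, size=k1, replace=False)
        s2 = rng.choice(idx2, size=k2, replace=False)
        effects[b] = np.abs(ppm[:, s1].mean(axis=1) - ppm[:, s2].mean(axis=1))
    mean_effect = effects.mean(axis=0)
    scores = np.log10(np.maximum(mean_effect, 1.0))
    enriched = np.where(
        ppm[:, idx1].mean(axis=1) >= ppm[:, idx2].mean(axis=1), names[0], names[1]
    )
    df = pd.DataFrame(
        {
            "taxon": rel.taxon_ids,
            "lda_score": scores,
            "enriched": enriched,
            "statistic": screen["statistic"].to_numpy(),
            "p_value": screen["p_value"].to_numpy(),
            "q_value": screen["q_value"].to_numpy(),
        }
    ).set_index("taxon")
    df["passes"] = (df["q_value"] < alpha) & (df["lda_score"].abs() > cutoff)
    return df


def taxon_correlation(table: CountTable, focal_taxon: str, other_taxa=None) -> pd.DataFrame:
    """Pearson correlation of a focal taxon with other taxa across samples.

    Computed on relative abundances. Zero-variance vectors yield a missing
    correlation (NaN), reported rather than dropped.
    """
    if focal_taxon not in table.data.index:
        raise KeyError(f"focal taxon {focal_taxon!r} not in table")
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    rel = to_relative(table) if table.unit == "counts" else table
    x = rel.data.loc[focal_taxon].to_numpy()
    others = list(other_taxa) if other_taxa is not None else [
        t for t in rel.taxon_ids if t != focal_taxon
    ]
    rows = []
    for taxon in others:
        y = rel.data.loc[taxon].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((taxon, np.nan))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, _ = stats.pearsonr(x, y)
            rows.append((taxon, float(r)))
    return pd.DataFrame(rows, columns=["taxon", "pearson_r"]).set_index("taxon")


@dataclass(frozen=True)
class GrowthFit:
    treatment: str
    slope: float       # log10 CFU per hour
    intercept: float
    slope_se: float
    p_value: float
    r_squared: float
    n_obs: int


def cfu_growth_fit(cfu: pd.DataFrame, metadata: pd.DataFrame | None = None) -> list[GrowthFit]:
    """Per-treatment OLS of log10(CFU) on time, pooling plates and individuals.

    Zero counts cannot be log-transformed and are dropped with a warning.
    Requires at least two distinct timepoints per treatment. Individuals are
    pooled as fixed effects are not modeled; between-individual variation
    inflates the residual, not the slope.
    """
    df = cfu.copy()
    if "treatment" not in df.columns or "timepoint_h" not in df.columns:
        if metadata is None:
            raise ValueError("cfu table lacks treatment/timepoint_h and no metadata given")
        df = df.join(metadata[["treatment", "timepoint_h"]], on="sample_id")
    zeros = df["cfu_count"] <= 0
    if zeros.any():
        warnings.warn(
            f"dropping {int(zeros.sum())} zero CFU observation(s) before log transform",
            UserWarning,
            stacklevel=2,
        )
        df = df[~zeros]
    fits = []
    for trt, grp in df.groupby("treatment", sort=True):
        t = grp["timepoint_h"].to_numpy(dtype=float)
        if np.unique(t).size < 2:
            raise ValueError(f"treatment {trt!r} has a single timepoint; cannot fit a slope")
        y = np.log10(grp["cfu_count"].to_numpy(dtype=float))
        res = stats.linregress(t, y)
        fits.append(
            GrowthFit(
                treatment=str(trt),
                slope=float(res.slope),
                intercept=float(res.intercept),
                slope_se=float(res.stderr),
                p_value=float(res.pvalue),
                r_squared=float(res.rvalue**2),
                n_obs=int(len(grp)),
            )
        )
    return fits
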
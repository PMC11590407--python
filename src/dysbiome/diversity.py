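"""Alpha diversity, sample dissimilarities, ordination and PERMANOVA.

Alpha indices are observed richness, bias-corrected Chao1 and Shannon
entropy (log base 2 by default). Beta diversity supports Bray-Curtis and
Jensen-Shannon distance on proportions and Jaccard on presence/absence; all
three lie in [0, 1]. Ordination is classical principal-coordinates analysis
(Gower double-centering); group differences are tested with a permutation
PERMANOVA whose p-value counts the observed statistic in both numerator and
denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.spatial.distance import jensenshannon as _sp_jensenshannon

from .tables import CountTable

__all__ = [
    "AlphaDiversityRecord",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "jaccard",
    "jensen_shannon",
    "DissimilarityMatrix",
    "beta_diversity",
    "PcoaResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "pairwise_permanova",
]

METRICS = ("braycurtis", "jaccard", "jensenshannon")


# ---------------------------------------------------------------- alpha

@dataclass(frozen=True)
class AlphaDiversityRecord:
    sample_id: str
    observed: int
    chao1: float
    shannon: float
    log_base: float
    singletons: int
    doubletons: int


def alpha_diversity(counts, sample_id: str = "", log_base: float = 2.0) -> AlphaDiversityRecord:
    """Observed richness, bias-corrected Chao1 and Shannon entropy.

    Chao1 uses the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)),
    which is defined even when no doubletons are observed.
    """
    x = np.asarray(counts)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError(f"sample {sample_id!r} has no counts")
    nz = x[x > 0]
    s_obs = int(nz.size)
    f1 = int((nz == 1).sum())
    f2 = int((nz == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = nz / total
    shannon = float(-(p * (np.log(p) / np.log(log_base))).sum())
    return AlphaDiversityRecord(sample_id, s_obs, float(chao1), shannon, log_base, f1, f2)


def alpha_diversity_table(table: CountTable, log_base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha diversity as a DataFrame indexed by sample id."""
    records = [
        alpha_diversity(table.column(s), sample_id=s, log_base=log_base)
        for s in table.sample_ids
    ]
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("sample_id")
    return df


# ----------------------------------------------------------------- beta

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum x + sum y)."""
    return float(_sp_braycurtis(np.asarray(x, float), np.asarray(y, float)))


def jaccard(x, y) -> float:
    """Jaccard dissimilarity on presence/absence: 1 - |shared|/|union|."""
    a = np.asarray(x) > 0
    b = np.asarray(y) > 0
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return float(1.0 - (a & b).sum() / union)


def jensen_shannon(x, y) -> float:
    """Jensen-Shannon distance, log base 2 (so the range is [0, 1])."""
    return float(_sp_jensenshannon(np.asarray(x, float), np.asarray(y, float), base=2.0))


_METRIC_FUNCS = {
    "braycurtis": bray_curtis,
    "jaccard": jaccard,
    "jensenshannon": jensen_shannon,
}


@dataclass
class DissimilarityMatrix:
    """Symmetric, zero-diagonal pairwise sample dissimilarities."""

    data: np.ndarray
    ids: list[str]
    metric: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError(f"matrix shape {self.data.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("sample ids must be unique")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, sample_id: str) -> int:
        try:
            return self.ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def between(self, a: str, b: str) -> float:
        return float(self.data[self.index(a), self.index(b)])

    def filter(self, ids) -> "DissimilarityMatrix":
        idx = [self.index(i) for i in ids]
        return DissimilarityMatrix(self.data[np.ix_(idx, idx)], list(ids), self.metric)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def beta_diversity(table: CountTable, metric: str) -> DissimilarityMatrix:
    """All-pairs dissimilarity between sample columns.

    Bray-Curtis and Jensen-Shannon are computed on proportions (pass the
    table through ``to_relative`` first); Jaccard uses presence/absence and
    accepts either unit.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric in ("braycurtis", "jensenshannon") and table.unit != "proportions":
        raise ValueError(f"{metric} requires proportions; call to_relative first")
    X = table.values.T  # samples x taxa
    n = X.shape[0]
    func = _METRIC_FUNCS[metric]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = func(X[i], X[j])
    return DissimilarityMatrix(D, table.sample_ids, metric)


# ----------------------------------------------------------------- pcoa

@dataclass
class PcoaResult:
    eigenvalues: np.ndarray          # all eigenvalues, descending
    coordinates: pd.DataFrame        # samples x positive axes
    proportion_explained: np.ndarray  # per positive axis
    n_negative: int


def pcoa(dm: DissimilarityMatrix, eps: float = 1e-10) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    Gower-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues. Negative eigenvalues -- a
    signature of non-Euclidean metrics such as Bray-Curtis -- are counted
    and reported, not corrected.
    """
    n = dm.n
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    d2 = dm.data**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = np.max(np.abs(eigvals)) if eigvals.size else 1.0
    tol = eps * max(scale, 1.0)
    pos = eigvals > tol
    n_negative = int((eigvals < -tol).sum())
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    # deterministic axis orientation: largest-magnitude loading positive
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[pos].sum()
    proportion = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    frame = pd.DataFrame(
        coords,
        index=dm.ids,
        columns=[f"PC{i+1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(eigvals, frame, proportion, n_negative)


# ------------------------------------------------------------ permanova

@dataclass
class PermanovaResult:
    statistic: float          # pseudo-F
    r_squared: float
    p_value: float
    n_permutations: int
    ss_total: float
    ss_within: float
    ss_between: float
    df_between: int
    df_within: int
    groups: tuple = ()


def _align_labels(dm: DissimilarityMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        missing = [i for i in dm.ids if i not in grouping.index]
        if missing:
            raise ValueError(f"grouping missing sample(s): {missing}")
        return grouping.loc[dm.ids].to_numpy()
    if isinstance(grouping, dict):
        return np.array([grouping[i] for i in dm.ids])
    arr = np.asarray(grouping)
    if arr.shape[0] != dm.n:
        raise ValueError("grouping length does not match matrix size")
    return arr


def _ss_within_batch(d2: np.ndarray, onehot: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """SS_within for a batch of one-hot label matrices (P, N, a)."""
    M = np.einsum("ij,pja->pia", d2, onehot)
    per_group = np.einsum("pia,pia->pa", onehot, M) / (2.0 * counts)
    return per_group.sum(axis=1)


def permanova(
    dm: DissimilarityMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    strata=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Partitions SS_total = sum_{i<j} D_ij^2 / N into within- and
    between-group components and compares pseudo-F =
    [SS_between/(a-1)] / [SS_within/(N-a)] against free label permutations
    (or, when ``strata`` maps samples to blocks, permutations restricted to
    within each block). The permutation p-value includes the observed
    statistic: p = (1 + #{F_perm >= F_obs}) / (n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    labels_raw = _align_labels(dm, grouping)
    names, labels = np.unique(labels_raw, return_inverse=True)
    a, n = len(names), dm.n
    if a < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    counts = np.bincount(labels, minlength=a)
    if (counts < 2).any():
        small = [str(names[g]) for g in np.where(counts < 2)[0]]
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")

    d2 = dm.data**2
    ss_total = d2.sum() / (2.0 * n)
    eye = np.eye(a)
    ss_within = float(_ss_within_batch(d2, eye[labels][None], counts)[0])
    if ss_within <= 1e-12 * max(ss_total, 1.0):
        raise ValueError("zero within-group sum of squares: pseudo-F is degenerate")
    ss_between = ss_total - ss_within
    df_between, df_within = a - 1, n - a
    f_obs = (ss_between / df_between) / (ss_within / df_within)

    rng = np.random.default_rng(seed)
    if strata is None:
        perms = np.array([rng.permutation(labels) for _ in range(n_permutations)])
    else:
        strata_arr = _align_labels(dm, strata)
        perms = np.tile(labels, (n_permutations, 1))
        for block in np.unique(strata_arr):
            idx = np.where(strata_arr == block)[0]
            for p in range(n_permutations):
                perms[p, idx] = perms[p, idx[rng.permutation(idx.size)]]
    ss_w_perm = _ss_within_batch(d2, eye[perms], counts)
    with np.errstate(divide="ignore"):
        f_perm = ((ss_total - ss_w_perm) / df_between) / (ss_w_perm / df_within)
    p_value = (1.0 + (f_perm >= f_obs - 1e-12).sum()) / (n_permutations + 1.0)

    return PermanovaResult(
        statistic=float(f_obs),
        r_squared=float(ss_between / ss_total),
        p_value=float(p_value),
        n_permutations=n_permutations,
        ss_total=float(ss_total),
        ss_within=float(ss_within),
        ss_between=float(ss_between),
        df_between=df_between,
        df_within=df_within,
        groups=tuple(str(g) for g in names),
    )


def pairwise_permanova(
    dm: DissimilarityMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """PERMANOVA on every group pair with Benjamini-Hochberg q-values."""
    from .diffabund import bh_fdr

    labels = _align_labels(dm, grouping)
    names = sorted(set(map(str, labels)), key=str)
    labels = np.array([str(x) for x in labels])
    if len(names) < 2:
        raise ValueError("pairwise PERMANOVA requires at least 2 groups")
    rng = np.random.default_rng(seed)
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            mask = np.isin(labels, [g1, g2])
            ids = [s for s, m in zip(dm.ids, mask) if m]
            sub = dm.filter(ids)
            res = permanova(
                sub,
                labels[mask],
                n_permutations=n_permutations,
                seed=int(rng.integers(2**31)),
            )
            rows.append((g1, g2, res.statistic, res.r_squared, res.p_value, res))
    df = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4]) for r in rows],
        columns=["group_a", "group_b", "pseudo_f", "r_squared", "p_value"],
    )
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    df.attrs["results"] = [r[5] for r in rows]
    return df
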
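"""Association stage: site ANOVA, LULC-vs-water-quality Pearson matrices,
PCA with Kaiser-type retention, and hierarchical clustering of sites.

Variables mix units (uS/cm, mg/L, MPN/100 mL), so PCA runs on the
correlation matrix (columns standardized to mean 0, SD 1) and clustering on
standardized columns with Euclidean distance and Ward linkage by default.
Pearson p values are two-sided from the exact t transform; significance is
reported in the conventional star tiers (ns, p<0.05, p<0.01), per cell,
without multiple-testing correction by default (a Benjamini–Hochberg option
is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.stats import false_discovery_control


@dataclass
class AnovaResult:
    F: float
    p: float
    group_summary: pd.DataFrame  # per site: n, mean, sd
    note: str = ""


def anova_by_site(records, variable: str) -> AnovaResult:
    """One-way fixed-effects ANOVA of ``variable`` across sites.

    ``records`` is a list of WaterQualityRecord or a DataFrame with
    ``site_id`` and the variable as columns.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["site_id", variable]].dropna()
    else:
        df = pd.DataFrame(
            [
                {"site_id": r.site_id, variable: r.values[variable]}
                for r in records
                if variable in r.values
            ]
        )
    groups = {sid: g[variable].to_numpy(float) for sid, g in df.groupby("site_id")}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two sites with data")
    for sid, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"site {sid} has fewer than 2 records for {variable}")
    summary = pd.DataFrame(
        {
            "site_id": list(groups),
            "n": [len(v) for v in groups.values()],
            "mean": [v.mean() for v in groups.values()],
            "sd": [v.std(ddof=1) for v in groups.values()],
        }
    )
    note = ""
    if all(v.std() == 0 for v in groups.values()):
        means = [v.mean() for v in groups.values()]
        if len(set(means)) > 1:
            note = "zero within-group variance with unequal means; p reported as the 0 limit"
            return AnovaResult(F=np.inf, p=0.0, group_summary=summary, note=note)
        return AnovaResult(F=0.0, p=1.0, group_summary=summary, note="all groups identical")
    F, p = sps.f_oneway(*groups.values())
    if F == 0:
        p = 1.0
    return AnovaResult(F=float(F), p=float(p), group_summary=summary, note=note)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with the two-sided t-transform p value.

    Returns (r, p, n). Zero variance in either vector yields (nan, nan, n).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def significance_tier(p: float) -> str:
    if not np.isfinite(p):
        return "undefined"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def correlation_matrix(
    compositions: pd.DataFrame,
    metrics: pd.DataFrame,
    scale: str,
    season: str,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Pearson matrix between LULC class percentages and water-quality
    variables (and/or WQI), one row per (variable, class) cell.

    ``compositions`` is the tidy table from :func:`riverwq.geo.composition_table`
    (filtered here to ``scale`` and ``season``); ``metrics`` has one row per
    site (``site_id`` column) and one column per variable. Cells are
    pairwise complete; a zero-variance column yields an undefined r (NaN),
    never 0.
    """
    comp = compositions[
        (compositions["scale"] == scale) & (compositions["season"] == season)
    ]
    if comp.empty:
        raise ValueError(f"no composition rows for scale={scale!r}, season={season!r}")
    comp = comp.set_index("site_id")
    metrics = metrics.set_index("site_id") if "site_id" in metrics.columns else metrics
    common = comp.index.intersection(metrics.index)
    if len(common) < 3:
        raise ValueError(f"need >=3 common sites, got {len(common)}")
    comp = comp.loc[common]
    metrics = metrics.loc[common]

    class_cols = [c for c in comp.columns if c not in ("scale", "season", "n_valid", "n_nodata")]
    rows = []
    for var in metrics.columns:
        for cls in class_cols:
            r, p, n = pearson_with_p(metrics[var].to_numpy(), comp[cls].to_numpy())
            rows.append(
                {
                    "variable": var,
                    "lulc_class": cls,
                    "scale": scale,
                    "season": season,
                    "r": r,
                    "p": p,
                    "n": n,
                }
            )
    out = pd.DataFrame(rows)
    if bh_correction:
        finite = out["p"].notna()
        adj = out.loc[finite, "p"].to_numpy()
        out.loc[finite, "p"] = false_discovery_control(adj, method="bh")
    out["tier"] = out["p"].map(significance_tier)
    return out


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components (eigenvectors of R)
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    n_retained: int
    scores: pd.DataFrame  # rows x components
    means: pd.Series
    sds: pd.Series

    @property
    def retained(self) -> list[str]:
        return list(self.loadings.columns[: self.n_retained])


def run_pca(metrics: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix with eigenvalue >= 1 retention.

    Columns are standardized (mean 0, SD 1, ddof=1); component loadings are
    the eigenvectors of the sample correlation matrix, signed so the
    largest-magnitude loading of each component is positive.
    """
    df = metrics.set_index("site_id") if "site_id" in metrics.columns else metrics
    df = df.astype(float)
    if len(df) < 3:
        raise ValueError("PCA needs at least 3 rows")
    sds = df.std(ddof=1)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance columns must be removed before PCA: {zero_var}")
    means = df.mean()
    Z = (df - means) / sds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: dominant loading positive
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    pcs = [f"PC{j + 1}" for j in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=df.columns, columns=pcs)
    pct = 100.0 * eigvals / eigvals.sum()
    scores = pd.DataFrame(Z.to_numpy() @ eigvecs, index=df.index, columns=pcs)
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigvals,
        pct_variance=pct,
        n_retained=int(np.sum(eigvals >= 1.0)),
        scores=scores,
        means=means,
        sds=sds,
    )


@dataclass
class ClusterResult:
    labels: dict[str, int]  # site_id -> 1..k, numbered by first appearance
    linkage: np.ndarray
    k: int
    method: str
    metric: str


def cluster_sites(
    metrics: pd.DataFrame,
    k: int = 5,
    method: str = "ward",
    metric: str = "euclidean",
    standardize: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of sites on (standardized) variables.

    Deterministic given input order; cluster labels are renumbered 1..k in
    order of first appearance along the site index, so a pure reordering of
    rows changes labels only up to this relabeling, never the partition.
    """
    df = metrics.set_index("site_id") if "site_id" in metrics.columns else metrics
    df = df.astype(float)
    n = len(df)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available sites")
    if df.isna().any().any():
        raise ValueError("missing values must be imputed before clustering")
    X = df.to_numpy()
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method=method, metric=metric)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = {}
    for sid, lab in zip(df.index, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[str(sid)] = relabel[lab]
    return ClusterResult(labels=labels, linkage=Z, k=k, method=method, metric=metric)
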
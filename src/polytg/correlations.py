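"""Feature-Tg correlation analyses and the four-method consensus vote.

Four complementary views of how each descriptor relates to Tg:

* pairwise Pearson correlation,
* Variable Importance Projection (VIP) over the leading principal
  components of the Tg-augmented feature matrix,
* membership in a cone around the Tg direction in PC1-3 loading space,
* random-forest impurity importance (which carries no sign).

Each method nominates its strongest features (top six by magnitude for the
ranked methods, cone membership for the loading plot) and the consensus
table counts how many methods selected each feature, with the aggregated
correlation sign.  A PCA variance comparison with/without Tg and a k-means
cluster Tg profile check that Tg is captured by the features at all.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

from .errors import DataError

logger = logging.getLogger(__name__)

TG_COLUMN = "Tg"


@dataclass
class FeatureTable:
    """Polymer ids, a descriptor matrix and (optionally) Tg in Celsius.

    ``standardize`` z-scores the retained columns; zero-variance columns are
    dropped with a logged warning because they carry no correlation
    information and would divide by zero.
    """

    ids: list[str]
    X: pd.DataFrame
    tg: pd.Series | None = None
    standardization: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.X):
            raise DataError("ids and X have different lengths")
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise DataError(f"missing values in feature columns {bad}")
        if self.tg is not None and len(self.tg) != len(self.X):
            raise DataError("tg and X have different lengths")

    @property
    def n(self) -> int:
        return len(self.X)

    def standardize(self) -> "FeatureTable":
        sd = self.X.std(ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = sd.index[~keep].tolist()
            logger.warning("dropping zero-variance columns: %s", dropped)
        X = self.X.loc[:, keep]
        mean, scale = X.mean(), X.std(ddof=1)
        Z = (X - mean) / scale
        params = pd.DataFrame({"mean": mean, "sd": scale})
        return FeatureTable(
            ids=self.ids, X=Z, tg=self.tg, standardization=params
        )


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: pd.DataFrame  # rows = variables, cols = PC1..PCk
    variance_fractions: np.ndarray
    include_tg: bool


@dataclass
class ClusterProfile:
    label: int
    mean_tg: float
    sd_tg: float
    member_ids: list[str]


@dataclass
class ConsensusRow:
    feature: str
    times_selected: int
    correlation_sign: str  # "+", "-", "+ and -", "n/a"


@dataclass
class CorrelationReport:
    pairwise: pd.Series
    vip: pd.Series
    loading_cone_members: dict[str, str]
    rf_importance: pd.Series
    pc_variances_without_tg: np.ndarray
    pc_variances_with_tg: np.ndarray
    cluster_profiles: list[ClusterProfile]
    consensus: list[ConsensusRow]
    feature_correlation_matrix: pd.DataFrame = field(default=None, repr=False)

    def consensus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Feature": r.feature,
                    "Times_Selected": r.times_selected,
                    "Correlation": r.correlation_sign,
                }
                for r in self.consensus
            ]
        )


def _augment_with_tg(table: FeatureTable) -> pd.DataFrame:
    if table.tg is None:
        raise DataError("table has no Tg column")
    X = table.X.copy()
    X[TG_COLUMN] = np.asarray(table.tg, dtype=float)
    return X


def run_pca(table: FeatureTable, include_tg: bool = False) -> PCAResult:
    """PCA on the z-scored feature matrix, optionally with Tg appended.

    Loadings are the unit-norm eigenvectors of the correlation matrix; the
    sign of each component is fixed by making its largest-magnitude loading
    positive, so results are deterministic.
    """
    if table.n < 3:
        raise DataError(f"PCA needs at least 3 rows, got {table.n}")
    frame = _augment_with_tg(table) if include_tg else table.X.copy()
    sd = frame.std(ddof=1)
    frame = frame.loc[:, sd > 0]
    Z = (frame - frame.mean()) / frame.std(ddof=1)
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    comps = pca.components_  # (k, p)
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] *= -1.0
            scores[:, k] *= -1.0
    loadings = pd.DataFrame(
        comps.T,
        index=frame.columns,
        columns=[f"PC{k + 1}" for k in range(comps.shape[0])],
    )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_fractions=pca.explained_variance_ratio_,
        include_tg=include_tg,
    )


def cluster_tg_profile(
    scores: np.ndarray,
    tg: pd.Series | np.ndarray,
    ids: list[str],
    k: int = 4,
    seed: int = 0,
    n_pcs: int | None = None,
) -> list[ClusterProfile]:
    """k-means on PC scores (Tg never enters the clustering), then the mean
    and spread of Tg within each cluster.

    Clusters are relabelled by ascending mean Tg so the profile is invariant
    to k-means' internal label permutation.
    """
    tg = np.asarray(tg, dtype=float)
    if k < 1:
        raise DataError("k must be >= 1")
    if k > scores.shape[0]:
        raise DataError(f"k={k} exceeds number of rows {scores.shape[0]}")
    use = scores if n_pcs is None else scores[:, :n_pcs]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(use)
    profiles = []
    for lab in range(k):
        mask = labels == lab
        members = [ids[i] for i in np.flatnonzero(mask)]
        profiles.append(
            ClusterProfile(
                label=lab,
                mean_tg=float(np.mean(tg[mask])),
                sd_tg=float(np.std(tg[mask], ddof=1)) if mask.sum() > 1 else 0.0,
                member_ids=members,
            )
        )
    profiles.sort(key=lambda p: p.mean_tg)
    for new_lab, p in enumerate(profiles):
        p.label = new_lab
    return profiles


def compute_vip(
    table: FeatureTable, n_pcs: int = 5, weighted: bool = True
) -> pd.Series:
    """Signed Variable Importance Projection of each feature onto Tg.

    VIP_j = sum over the first ``n_pcs`` components of
    w_k * L[j, k] * L[Tg, k], where L are the loadings of the Tg-augmented
    PCA and w_k the variance fraction of component k (``weighted=False``
    uses w_k = 1).  Acts as a pairwise correlation restricted to the
    dominant directions of the data.
    """
    res = run_pca(table, include_tg=True)
    avail = res.loadings.shape[1]
    if n_pcs > avail:
        warnings.warn(
            f"requested {n_pcs} PCs but only {avail} available; truncating"
        )
        n_pcs = avail
    L = res.loadings.iloc[:, :n_pcs]
    w = res.variance_fractions[:n_pcs] if weighted else np.ones(n_pcs)
    tg_row = L.loc[TG_COLUMN].to_numpy()
    vip = (L.to_numpy() * tg_row * w).sum(axis=1)
    out = pd.Series(vip, index=L.index)
    return out.drop(TG_COLUMN)


def loading_cone_select(
    loadings: pd.DataFrame, cone_half_angle_deg: float = 30.0
) -> dict[str, str]:
    """Features whose PC1-3 loading vector lies within a cone around the Tg
    loading direction (sign ``+``) or its antipode (sign ``-``).

    This is the computational counterpart of reading a shaded cone off a
    3-D loading plot.
    """
    if TG_COLUMN not in loadings.index:
        raise DataError("loadings must include the Tg row (PCA with Tg)")
    L3 = loadings.iloc[:, : min(3, loadings.shape[1])].to_numpy()
    idx = list(loadings.index)
    tg_vec = L3[idx.index(TG_COLUMN)]
    tg_norm = np.linalg.norm(tg_vec)
    out: dict[str, str] = {}
    cos_cone = np.cos(np.deg2rad(cone_half_angle_deg))
    for name, vec in zip(idx, L3):
        if name == TG_COLUMN:
            continue
        norm = np.linalg.norm(vec)
        if norm == 0 or tg_norm == 0:
            continue
        c = float(vec @ tg_vec / (norm * tg_norm))
        if c >= cos_cone:
            out[name] = "+"
        elif c <= -cos_cone:
            out[name] = "-"
    return out


def rf_importance(
    table: FeatureTable, n_trees: int = 500, seed: int = 0
) -> pd.Series:
    """Impurity-based random-forest importance of each feature for Tg,
    normalised to sum to one.  Importance is unsigned."""
    if table.tg is None:
        raise DataError("table has no Tg column")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(table.X.to_numpy(), np.asarray(table.tg, dtype=float))
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=table.X.columns)


def _top_by_magnitude(values: pd.Series, top_n: int) -> list[str]:
    """Features with the ``top_n`` largest |values|; ties with the
    boundary value are all included (with a logged warning)."""
    mag = values.abs().sort_values(ascending=False)
    if len(mag) <= top_n:
        return mag.index.tolist()
    cutoff = mag.iloc[top_n - 1]
    selected = mag[mag >= cutoff].index.tolist()
    if len(selected) > top_n:
        logger.warning(
            "tie at rank %d: selecting %d features", top_n, len(selected)
        )
    return selected


def consensus(
    pairwise: pd.Series,
    vip: pd.Series,
    cone_members: dict[str, str],
    rf_imp: pd.Series,
    top_n: int = 6,
) -> list[ConsensusRow]:
    """Combine the four correlation analyses into the vote table.

    Each ranked method (pairwise, VIP, RF) votes for its ``top_n`` features
    by magnitude; the loading-cone method votes for its members.  Signs come
    from the signed methods only (RF contributes none); features selected
    with conflicting signs are marked ``"+ and -"``, RF-only selections
    ``"n/a"``.
    """
    pairwise_sel = _top_by_magnitude(pairwise, top_n)
    vip_sel = _top_by_magnitude(vip, top_n)
    rf_sel = _top_by_magnitude(rf_imp, top_n)

    votes: dict[str, list[str]] = {}

    def _vote(feature: str, sign: str | None) -> None:
        votes.setdefault(feature, [])
        if sign is not None:
            votes[feature].append(sign)

    for f in pairwise_sel:
        _vote(f, "+" if pairwise[f] >= 0 else "-")
    for f in vip_sel:
        _vote(f, "+" if vip[f] >= 0 else "-")
    for f, sign in cone_members.items():
        _vote(f, sign)
    for f in rf_sel:
        _vote(f, None)

    n_methods = {
        f: (f in pairwise_sel)
        + (f in vip_sel)
        + (f in cone_members)
        + (f in rf_sel)
        for f in votes
    }
    rows = []
    for f, signs in votes.items():
        uniq = set(signs)
        if not uniq:
            sign = "n/a"
        elif uniq == {"+"}:
            sign = "+"
        elif uniq == {"-"}:
            sign = "-"
        else:
            sign = "+ and -"
        rows.append(ConsensusRow(f, n_methods[f], sign))
    rows.sort(
        key=lambda r: (-r.times_selected, -abs(pairwise.get(r.feature, 0.0)))
    )
    return rows


def pairwise_tg_correlation(table: FeatureTable) -> pd.Series:
    """Pearson correlation of each feature with Tg."""
    if table.tg is None:
        raise DataError("table has no Tg column")
    tg = np.asarray(table.tg, dtype=float)
    return table.X.apply(
        lambda col: float(np.corrcoef(col.to_numpy(), tg)[0, 1])
        if col.std(ddof=1) > 0
        else 0.0
    )


def correlation_report(
    table: FeatureTable,
    kmeans_k: int = 4,
    cone_half_angle_deg: float = 30.0,
    vip_pcs: int = 5,
    rf_trees: int = 500,
    top_n: int = 6,
    seed: int = 0,
) -> CorrelationReport:
    """Run the full correlation suite on a descriptor/Tg table."""
    pca_without = run_pca(table, include_tg=False)
    pca_with = run_pca(table, include_tg=True)
    profiles = cluster_tg_profile(
        pca_without.scores, table.tg, table.ids, k=kmeans_k, seed=seed
    )
    pairwise = pairwise_tg_correlation(table)
    vip = compute_vip(table, n_pcs=vip_pcs)
    cone = loading_cone_select(pca_with.loadings, cone_half_angle_deg)
    rf_imp = rf_importance(table, n_trees=rf_trees, seed=seed)
    rows = consensus(pairwise, vip, cone, rf_imp, top_n=top_n)
    corr_mat = table.X.corr()
    return CorrelationReport(
        pairwise=pairwise,
        vip=vip,
        loading_cone_members=cone,
        rf_importance=rf_imp,
        pc_variances_without_tg=pca_without.variance_fractions,
        pc_variances_with_tg=pca_with.variance_fractions,
        cluster_profiles=profiles,
        consensus=rows,
        feature_correlation_matrix=corr_mat,
    )
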
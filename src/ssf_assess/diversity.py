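"""Catch-composition diversity analysis.

Each survey response (fisher x period) becomes a row over the top-12 most
harvested species; rows are compared with Manhattan distance and grouped by
PAM k-medoids (BUILD + SWAP over the precomputed dissimilarity matrix).  The
number of clusters is chosen by three criteria — the within-dissimilarity
elbow, mean silhouette width, and the gap statistic — with a majority
consensus.  Clusters are then related to time (one-way ANOVA with Tukey HSD
on assigned year) and to composition (MANOVA, Pillai's trace), and each
cluster is summarized by its median year, mean composition, dominance and
Pielou evenness.  A "funnel" pattern — dominance strictly decreasing with
cluster median year — indicates homogenization of the catch over time.

k-medoids rather than centroid k-means is used because only the former can
consume an arbitrary precomputed distance matrix; Euclidean k-means remains
available through :class:`CompositionClusterer` for comparison.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CompositionMatrix", "ClusteringResult", "KSelectionReport",
    "ClusterTimeTest", "ClusterCompositionTest", "ClusterSummary",
    "CompositionClusterer",
    "build_composition_matrix", "manhattan_distance_matrix", "cluster_k",
    "select_k", "anova_cluster_year", "manova_cluster_species",
    "summarize_clusters",
]


@dataclass
class CompositionMatrix:
    """Responses x species catch matrix with row metadata.

    ``values`` holds per-species catch in kg, or row proportions in
    ``proportion`` mode (all-zero rows are excluded and counted in
    ``n_dropped``).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    mode: str
    n_dropped: int = 0
    boundary_tie: bool = False

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusteringResult:
    k: int
    assignment: np.ndarray
    medoid_rows: np.ndarray
    total_within_dissimilarity: float


@dataclass
class KSelectionReport:
    """Cluster-count selection curves and per-criterion choices."""

    k_grid: np.ndarray
    wss_curve: np.ndarray
    mean_silhouette: np.ndarray    # NaN at k = 1
    gap: np.ndarray
    gap_se: np.ndarray
    chosen_k: dict[str, int]
    consensus_k: int
    clusterings: dict[int, ClusteringResult] = field(default_factory=dict)


@dataclass
class ClusterTimeTest:
    anova_f: float
    df_between: int
    df_within: int
    p_value: float
    tukey_pairs: pd.DataFrame
    singleton_clusters: list[int] = field(default_factory=list)


@dataclass
class ClusterCompositionTest:
    pillai_trace: float
    approx_f: float
    df1: int
    df2: int
    p_value: float
    per_species_f: pd.DataFrame


@dataclass
class ClusterSummary:
    """Per-cluster composition summaries, ordered by median year."""

    table: pd.DataFrame            # cluster, n, median_year, dominance, evenness
    mean_compositions: pd.DataFrame  # cluster x species
    funnel: bool


# ---------------------------------------------------------------------------
# composition matrix and distances

def build_composition_matrix(species_df: pd.DataFrame, top_n: int = 12,
                             mode: str = "kg") -> CompositionMatrix:
    """Pivot species observations into a responses x top-N species matrix.

    ``species_df`` needs columns fisher_id, period_tag, year_assigned,
    species_id, catch_kg (see :func:`ssf_assess.survey.species_frame`).
    Column species are the ``top_n`` by total reported catch, ties broken by
    lexically smaller species_id (warned when the tie straddles the cutoff).
    """
    if mode not in ("kg", "proportion"):
        raise ValueError(f"unknown mode {mode!r}")
    if species_df.empty or not (species_df["catch_kg"] > 0).any():
        raise ValueError("no positive species catches to build a composition from")

    totals = (species_df.groupby("species_id")["catch_kg"].sum()
              .reset_index().sort_values(["catch_kg", "species_id"],
                                         ascending=[False, True], kind="stable"))
    if len(totals) > top_n and np.isclose(totals.catch_kg.iloc[top_n - 1],
                                          totals.catch_kg.iloc[top_n]):
        warnings.warn(f"tie at the top-{top_n} cutoff; lexically smaller species_id kept")
        boundary_tie = True
    else:
        boundary_tie = False
    if len(totals) < top_n:
        warnings.warn(f"only {len(totals)} species reported (< top_n = {top_n})")
    keep = list(totals.species_id.iloc[:top_n])

    wide = (species_df[species_df.species_id.isin(keep)]
            .pivot_table(index=["fisher_id", "period_tag"], columns="species_id",
                         values="catch_kg", aggfunc="sum", fill_value=0.0)
            .reindex(columns=keep, fill_value=0.0))
    # responses that reported none of the kept species contribute all-zero rows
    all_idx = species_df[["fisher_id", "period_tag"]].drop_duplicates()
    wide = wide.reindex(pd.MultiIndex.from_frame(all_idx), fill_value=0.0)

    years = (species_df.groupby(["fisher_id", "period_tag"])["year_assigned"]
             .first().reindex(wide.index))
    meta = pd.DataFrame({"fisher_id": [i[0] for i in wide.index],
                         "period_tag": [i[1] for i in wide.index],
                         "year_assigned": years.to_numpy()})
    values = wide.reset_index(drop=True)
    meta = meta.reset_index(drop=True)

    n_dropped = 0
    rowsum = values.sum(axis=1).to_numpy()
    if mode == "proportion":
        nz = rowsum > 0
        n_dropped = int((~nz).sum())
        if n_dropped:
            warnings.warn(f"excluded {n_dropped} all-zero row(s) in proportion mode")
        values = values.loc[nz].div(rowsum[nz], axis=0).reset_index(drop=True)
        meta = meta.loc[nz].reset_index(drop=True)
    return CompositionMatrix(values, meta, mode, n_dropped, boundary_tie)


def manhattan_distance_matrix(M: CompositionMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Manhattan (city-block) distances between responses."""
    X = M.values.to_numpy() if isinstance(M, CompositionMatrix) else np.asarray(M, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    return squareform(pdist(X, metric="cityblock"))


# ---------------------------------------------------------------------------
# PAM k-medoids

def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dnear = D[:, medoids[0]].copy()
    while len(medoids) < k:
        cand = np.setdiff1d(np.arange(n), medoids)
        gains = np.maximum(dnear[:, None] - D[:, cand], 0.0).sum(axis=0)
        j = cand[int(np.argmax(gains))]
        medoids.append(int(j))
        dnear = np.minimum(dnear, D[:, j])
    return np.array(sorted(medoids))


def _pam_swap(D: np.ndarray, medoids: np.ndarray, max_iter: int = 200) -> np.ndarray:
    n = D.shape[0]
    medoids = np.array(sorted(medoids))
    k = len(medoids)
    if k >= n or k < 1:
        return medoids
    for _ in range(max_iter):
        dm = D[:, medoids]                          # (n, k)
        order = np.argsort(dm, axis=1, kind="stable")
        nearest = order[:, 0]
        dnear = dm[np.arange(n), nearest]
        if k == 1:
            # optimum for k=1 is the global column-sum minimizer
            best = int(np.argmin(D.sum(axis=0)))
            return np.array([best])
        dsecond = dm[np.arange(n), order[:, 1]]
        cand = np.setdiff1d(np.arange(n), medoids)
        Dc = D[:, cand]                             # (n, m)
        G = np.minimum(Dc, dnear[:, None]) - dnear[:, None]
        T = np.tile(G.sum(axis=0), (k, 1))          # (k, m)
        for a in range(k):
            mask = nearest == a
            if mask.any():
                corr = (np.minimum(Dc[mask], dsecond[mask, None])
                        - np.minimum(Dc[mask], dnear[mask, None])).sum(axis=0)
                T[a] += corr
        flat = int(np.argmin(T))
        if T.flat[flat] < -1e-12:
            a, h = divmod(flat, len(cand))
            medoids = np.array(sorted(np.append(np.delete(medoids, a), cand[h])))
        else:
            break
    return medoids


def _assign(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    dm = D[:, medoids]
    labels = np.argmin(dm, axis=1)  # ties -> lowest medoid index (medoids sorted)
    cost = float(dm[np.arange(D.shape[0]), labels].sum())
    return labels, cost


#: exhaustive medoid search is used below this subset count (exact optimum
#: on small instances; BUILD+SWAP local search above it)
_EXHAUSTIVE_LIMIT = 2000


def cluster_k(D: np.ndarray, k: int,
              init_medoids: Optional[Sequence[int]] = None) -> ClusteringResult:
    """PAM k-medoids over a precomputed distance matrix.

    BUILD initialization followed by best-improvement SWAP until no single
    swap lowers the total within-cluster dissimilarity; instances with few
    candidate medoid subsets are solved exactly by enumeration instead.
    Deterministic: all ties break toward the lowest row index.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} outside [1, {n}]")
    if init_medoids is None and math.comb(n, k) <= _EXHAUSTIVE_LIMIT:
        best_m, best_c = None, np.inf
        for m in itertools.combinations(range(n), k):
            c = D[:, m].min(axis=1).sum()
            if c < best_c - 1e-12:
                best_m, best_c = m, c
        medoids = np.array(best_m)
    else:
        medoids = (np.array(sorted(init_medoids)) if init_medoids is not None
                   else _pam_build(D, k))
        medoids = _pam_swap(D, medoids)
    labels, cost = _assign(D, medoids)
    return ClusteringResult(k, labels, medoids, cost)


# ---------------------------------------------------------------------------
# choosing k

def _gap_reference_rows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    return rng.uniform(lo, hi, size=X.shape)


def select_k(M: CompositionMatrix | np.ndarray, D: Optional[np.ndarray] = None,
             k_max: int = 10, B: int = 50, seed: int = 0) -> KSelectionReport:
    """Choose the number of clusters by elbow, silhouette and gap statistic.

    All three criteria are computed from PAM on the same Manhattan distance
    matrix.  Elbow = k maximizing the second difference of the
    within-dissimilarity curve; silhouette = k maximizing mean silhouette
    width; gap = smallest k with gap(k) >= gap(k+1) - SE(k+1), where the
    reference distribution draws rows uniformly over each column's observed
    range (SE carries the sqrt(1 + 1/B) factor).  Consensus is the majority,
    ties resolved by the silhouette choice.
    """
    X = M.values.to_numpy() if isinstance(M, CompositionMatrix) else np.asarray(M, dtype=float)
    if D is None:
        D = manhattan_distance_matrix(X)
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    k_max = min(k_max, n)
    ks = np.arange(1, k_max + 1)

    if D.max() == 0:
        one = cluster_k(D, 1)
        return KSelectionReport(ks, np.zeros(len(ks)), np.full(len(ks), np.nan),
                                np.zeros(len(ks)), np.zeros(len(ks)),
                                {"elbow": 1, "silhouette": 1, "gap": 1}, 1, {1: one})

    def _curve(Dmat: np.ndarray) -> tuple[np.ndarray, dict[int, ClusteringResult]]:
        """WSS over k with warm starts so the curve is nonincreasing."""
        wss = np.empty(len(ks))
        results: dict[int, ClusteringResult] = {}
        prev: Optional[ClusteringResult] = None
        for i, k in enumerate(ks):
            cold = cluster_k(Dmat, int(k))
            best = cold
            if prev is not None and k <= Dmat.shape[0]:
                cand = np.setdiff1d(np.arange(Dmat.shape[0]), prev.medoid_rows)
                if len(cand):
                    dnear = Dmat[:, prev.medoid_rows].min(axis=1)
                    gains = np.maximum(dnear[:, None] - Dmat[:, cand], 0.0).sum(axis=0)
                    init = np.append(prev.medoid_rows, cand[int(np.argmax(gains))])
                    warm = cluster_k(Dmat, int(k), init_medoids=init)
                    if warm.total_within_dissimilarity < best.total_within_dissimilarity:
                        best = warm
            results[int(k)] = best
            wss[i] = best.total_within_dissimilarity
            prev = best
        return wss, results

    wss, clusterings = _curve(D)

    sil = np.full(len(ks), np.nan)
    for i, k in enumerate(ks):
        if 2 <= k <= n - 1:
            labels = clusterings[int(k)].assignment
            if len(np.unique(labels)) >= 2:
                sil[i] = float(silhouette_score(D, labels, metric="precomputed"))

    rng = np.random.default_rng(seed)
    eps = 1e-12
    logW = np.log(np.maximum(wss, eps))
    ref_logW = np.empty((B, len(ks)))
    for b in range(B):
        Xref = _gap_reference_rows(X, rng)
        Dref = manhattan_distance_matrix(Xref)
        ref_wss, _ = _curve(Dref)
        ref_logW[b] = np.log(np.maximum(ref_wss, eps))
    gap = ref_logW.mean(axis=0) - logW
    gap_se = ref_logW.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    # per-criterion choices
    if len(ks) >= 3:
        second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]   # at k = 2..k_max-1
        elbow_k = int(ks[1:-1][int(np.argmax(second_diff))])
    else:
        elbow_k = int(ks[-1])
    sil_valid = np.where(~np.isnan(sil))[0]
    sil_k = int(ks[sil_valid[int(np.argmax(sil[sil_valid]))]]) if len(sil_valid) else 1
    gap_k = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - gap_se[i + 1]:
            gap_k = int(ks[i])
            break

    chosen = {"elbow": elbow_k, "silhouette": sil_k, "gap": gap_k}
    votes = pd.Series(list(chosen.values())).value_counts()
    consensus = int(votes.index[0]) if votes.iloc[0] >= 2 else sil_k
    return KSelectionReport(ks, wss, sil, gap, gap_se, chosen, consensus, clusterings)


# ---------------------------------------------------------------------------
# cluster-vs-time and cluster-vs-composition tests

def anova_cluster_year(assignment: Sequence[int], years: Sequence[float]) -> ClusterTimeTest:
    """One-way ANOVA of assigned year by cluster, with Tukey HSD pairs."""
    labels = np.asarray(assignment)
    years = np.asarray(years, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    groups = [years[labels == u] for u in uniq]
    singletons = [int(u) for u, g in zip(uniq, groups) if len(g) == 1]
    f, p = stats.f_oneway(*groups)
    dfb, dfw = len(uniq) - 1, len(years) - len(uniq)
    tk = pairwise_tukeyhsd(years, labels)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return ClusterTimeTest(float(f), dfb, dfw, float(p), tukey, singletons)


def manova_cluster_species(M: CompositionMatrix | np.ndarray,
                           assignment: Sequence[int]) -> ClusterCompositionTest:
    """MANOVA of species composition across clusters (Pillai's trace).

    Pillai's trace V = tr(H (H + E)^-1) from the between (H) and within (E)
    cross-product matrices, with the standard F approximation.  Univariate
    per-species one-way F tests are returned as follow-ups.
    """
    X = M.values.to_numpy() if isinstance(M, CompositionMatrix) else np.asarray(M, dtype=float)
    cols = (M.species if isinstance(M, CompositionMatrix)
            else [f"v{j}" for j in range(X.shape[1])])
    labels = np.asarray(assignment)
    uniq = np.unique(labels)
    n, p = X.shape
    k = len(uniq)
    if k < 2:
        raise ValueError("need >= 2 clusters")
    if n <= p + k:
        warnings.warn("few rows relative to species + clusters; MANOVA may be rank-deficient")

    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for u in uniq:
        g = X[labels == u]
        d = g.mean(axis=0) - grand
        H += len(g) * np.outer(d, d)
        E += (g - g.mean(axis=0)).T @ (g - g.mean(axis=0))
    try:
        V = float(np.trace(np.linalg.solve(H + E, H)))
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "singular total cross-product matrix; drop collinear or constant "
            "species columns before MANOVA") from e

    s = min(p, k - 1)
    m = (abs(p - k + 1) - 1) / 2.0
    nn = (n - k - p - 1) / 2.0
    df1 = int(s * (2 * m + s + 1))
    df2 = int(s * (2 * nn + s + 1))
    denom = s - V
    approx_f = ((2 * nn + s + 1) / (2 * m + s + 1)) * (V / denom) if denom > 0 else np.inf
    p_value = float(stats.f.sf(approx_f, df1, df2)) if np.isfinite(approx_f) and df2 > 0 else 0.0

    rows = []
    for j, c in enumerate(cols):
        groups = [X[labels == u, j] for u in uniq]
        if all(np.ptp(g) == 0 for g in groups) and np.ptp(X[:, j]) == 0:
            fj, pj = 0.0, 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                fj, pj = stats.f_oneway(*groups)
        rows.append({"species_id": c, "f": float(fj), "p": float(pj)})
    return ClusterCompositionTest(V, float(approx_f), df1, df2, p_value,
                                  pd.DataFrame(rows))


def summarize_clusters(M: CompositionMatrix | np.ndarray,
                       assignment: Sequence[int],
                       years: Sequence[float]) -> ClusterSummary:
    """Per-cluster median year, mean composition, dominance and evenness.

    Dominance is the largest share of the (normalized) mean composition;
    evenness is Pielou's J of the mean composition (0 for a single-species
    composition).  The funnel flag is True when dominance is strictly
    decreasing across clusters ordered by median year.
    """
    X = M.values.to_numpy() if isinstance(M, CompositionMatrix) else np.asarray(M, dtype=float)
    cols = (M.species if isinstance(M, CompositionMatrix)
            else [f"v{j}" for j in range(X.shape[1])])
    labels = np.asarray(assignment)
    years = np.asarray(years, dtype=float)
    rows, comps = [], {}
    for u in np.unique(labels):
        g = X[labels == u]
        mean_comp = g.mean(axis=0)
        total = mean_comp.sum()
        p = mean_comp / total if total > 0 else np.full_like(mean_comp, 1.0 / len(mean_comp))
        pos = p[p > 0]
        dominance = float(pos.max()) if len(pos) else 1.0
        if len(pos) > 1:
            evenness = float(-(pos * np.log(pos)).sum() / np.log(len(pos)))
        else:
            evenness = 0.0
        comps[int(u)] = mean_comp
        rows.append({"cluster": int(u), "n": int(len(g)),
                     "median_year": float(np.median(years[labels == u])),
                     "dominance": dominance, "evenness": evenness})
    table = (pd.DataFrame(rows).sort_values(["median_year", "cluster"], kind="stable")
             .reset_index(drop=True))
    dom = table["dominance"].to_numpy()
    funnel = bool(len(dom) >= 2 and np.all(np.diff(dom) < 0))
    mean_comps = pd.DataFrame([comps[c] for c in table["cluster"]],
                              index=table["cluster"], columns=cols)
    return ClusterSummary(table, mean_comps, funnel)


# ---------------------------------------------------------------------------
# estimator

class CompositionClusterer(BaseEstimator, ClusterMixin):
    """PAM k-medoids over Manhattan distances with automatic k selection.

    Parameters
    ----------
    n_clusters : int or "auto"
        Fixed cluster count, or "auto" to choose by the three-criterion
        consensus (elbow, silhouette, gap).
    k_max : int
        Largest k examined when ``n_clusters="auto"``.
    gap_b : int
        Reference draws for the gap statistic.
    metric : {"manhattan", "euclidean"}
        Distance for the dissimilarity matrix (Euclidean provided for
        comparison with centroid k-means analyses).
    random_state : int
        Seed for the gap-statistic reference draws.

    Attributes
    ----------
    labels_ : cluster label per row
    medoid_indices_ : row indices of the medoids
    k_ : chosen number of clusters
    inertia_ : total within-cluster dissimilarity
    selection_report_ : KSelectionReport (only when ``n_clusters="auto"``)
    """

    def __init__(self, n_clusters: int | str = "auto", k_max: int = 10,
                 gap_b: int = 50, metric: str = "manhattan", random_state: int = 0):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.gap_b = gap_b
        self.metric = metric
        self.random_state = random_state

    def _distances(self, X: np.ndarray) -> np.ndarray:
        if self.metric == "manhattan":
            return manhattan_distance_matrix(X)
        if self.metric == "euclidean":
            return squareform(pdist(X, metric="euclidean"))
        raise ValueError(f"unknown metric {self.metric!r}")

    def fit(self, X, y=None) -> "CompositionClusterer":
        Xa = X.values.to_numpy() if isinstance(X, CompositionMatrix) else np.asarray(X, dtype=float)
        D = self._distances(Xa)
        if self.n_clusters == "auto":
            report = select_k(Xa, D, k_max=self.k_max, B=self.gap_b,
                              seed=self.random_state)
            self.selection_report_ = report
            result = report.clusterings[report.consensus_k]
        else:
            result = cluster_k(D, int(self.n_clusters))
        self.distance_matrix_ = D
        self.labels_ = result.assignment
        self.medoid_indices_ = result.medoid_rows
        self.k_ = result.k
        self.inertia_ = result.total_within_dissimilarity
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
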
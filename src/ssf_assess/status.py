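"""Length-based stock status from life-history invariants.

For a data-poor stock, three reference lengths can be chained from the
maximum observed length Lmax via published empirical relationships:

    log10(Linf) = 0.044  + 0.9841 * log10(Lmax)      (asymptotic length)
    log10(Lm)   = 0.8979 * log10(Linf) - 0.0782      (length at 50% maturity)
    log10(Lopt) = 1.0421 * log10(Linf) - 0.2742      (yield-optimal length)

The status indicator is the ratio of the median length-at-catch over the
last three fished years to Lm: a stock caught at or above its maturation
length (ratio >= 1) is tentatively healthy; one caught well below it is
being removed before reproducing.  Default class boundaries: ratio >= 1.00
healthy, ratio <= 0.53 seriously overexploited, overexploited in between.
Externally sourced Lm/Lopt (e.g. FishBase life-history values supplied in
the species table) always take precedence over the empirical chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .survey import SpeciesInfo

__all__ = [
    "LIFE_HISTORY_COEFFICIENTS", "STATUS_LABELS",
    "LifeHistoryEstimates", "StatusClassification", "StockStatusClassifier",
    "estimate_linf", "estimate_lm", "estimate_lopt",
    "catch_length_ratio", "classify_status", "classify_vs_lopt",
    "life_history_estimates", "assess_fishery", "status_class_summaries",
]

#: Versioned empirical life-history regression coefficients
#: (log10-scale intercept/slope chains from Lmax).
LIFE_HISTORY_COEFFICIENTS = {
    "version": "froese-binohlan-2000",
    "linf_from_lmax": {"intercept": 0.044, "slope": 0.9841},
    "lm_from_linf": {"intercept": -0.0782, "slope": 0.8979},
    "lopt_from_linf": {"intercept": -0.2742, "slope": 1.0421},
}

STATUS_LABELS = ("healthy", "overexploited", "seriously_overexploited")

#: Default ratio boundaries: >= healthy_min is healthy, <= serious_max is
#: seriously overexploited.  These close the gaps in the published class
#: definition so every observed ratio gets a label.
DEFAULT_THRESHOLDS = {"healthy_min": 1.00, "serious_max": 0.53}


@dataclass(frozen=True)
class LifeHistoryEstimates:
    """Reference lengths for one species, with their provenance."""

    species_id: str
    linf_cm: float
    lm_cm: float
    lopt_cm: float
    lm_source: str      # "empirical" | "external"
    lopt_source: str

    def __post_init__(self) -> None:
        if not (0 < self.lm_cm < self.linf_cm and 0 < self.lopt_cm < self.linf_cm):
            raise ValueError(
                f"{self.species_id}: reference lengths must satisfy 0 < Lm, Lopt < Linf")


@dataclass(frozen=True)
class StatusClassification:
    species_id: str
    fishery_id: str
    lc_cm: float
    ratio: float
    label: str
    lc_vs_lopt: str     # "at_or_above" | "below"


def _chain(x: float, key: str) -> float:
    c = LIFE_HISTORY_COEFFICIENTS[key]
    return 10.0 ** (c["intercept"] + c["slope"] * math.log10(x))


def estimate_linf(lmax_cm: float) -> float:
    """Asymptotic length from maximum observed length."""
    if not lmax_cm > 0:
        raise ValueError("lmax_cm must be > 0")
    return _chain(lmax_cm, "linf_from_lmax")


def estimate_lm(linf_cm: float) -> float:
    """Length at 50% maturity from asymptotic length."""
    if not linf_cm > 0:
        raise ValueError("linf_cm must be > 0")
    return _chain(linf_cm, "lm_from_linf")


def estimate_lopt(linf_cm: float) -> float:
    """Yield-optimal harvest length from asymptotic length."""
    if not linf_cm > 0:
        raise ValueError("linf_cm must be > 0")
    return _chain(linf_cm, "lopt_from_linf")


def _round_half_up(x: float, nd: int) -> float:
    f = 10 ** nd
    return math.floor(x * f + 0.5) / f


def catch_length_ratio(lc_cm: float, lm_cm: float, *, rounded: bool = True) -> float:
    """Length-at-catch : length-at-maturity ratio (reported at 2 dp, half up)."""
    if not (lc_cm > 0 and lm_cm > 0):
        raise ValueError("lengths must be > 0")
    r = lc_cm / lm_cm
    return _round_half_up(r, 2) if rounded else r


def classify_status(ratio: float, *, healthy_min: float = DEFAULT_THRESHOLDS["healthy_min"],
                    serious_max: float = DEFAULT_THRESHOLDS["serious_max"]) -> str:
    """Label a length ratio healthy / overexploited / seriously overexploited."""
    if not ratio > 0:
        raise ValueError("ratio must be > 0")
    if ratio >= healthy_min:
        return "healthy"
    if ratio <= serious_max:
        return "seriously_overexploited"
    return "overexploited"


def classify_vs_lopt(median_lc_cm: float, lopt_cm: float) -> str:
    """Whether the stock is caught at/above or below its optimal length."""
    if not (median_lc_cm > 0 and lopt_cm > 0):
        raise ValueError("lengths must be > 0")
    return "at_or_above" if median_lc_cm >= lopt_cm else "below"


def life_history_estimates(info: SpeciesInfo) -> LifeHistoryEstimates:
    """Reference lengths for one species, external values taking precedence.

    Requires ``lmax_cm`` unless both external lengths are supplied (then
    Linf still comes from Lmax when available, else from external Lm
    inverted through the chain for bookkeeping).
    """
    if info.lmax_cm is not None:
        linf = estimate_linf(info.lmax_cm)
    elif info.lm_external_cm is not None:
        c = LIFE_HISTORY_COEFFICIENTS["lm_from_linf"]
        linf = 10.0 ** ((math.log10(info.lm_external_cm) - c["intercept"]) / c["slope"])
    else:
        raise ValueError(f"{info.species_id}: need lmax_cm or external lengths")
    if info.lm_external_cm is not None:
        lm, lm_src = float(info.lm_external_cm), "external"
    else:
        lm, lm_src = estimate_lm(linf), "empirical"
    if info.lopt_external_cm is not None:
        lopt, lopt_src = float(info.lopt_external_cm), "external"
    else:
        lopt, lopt_src = estimate_lopt(linf), "empirical"
    return LifeHistoryEstimates(info.species_id, linf, lm, lopt, lm_src, lopt_src)


def assess_fishery(last_species_obs: pd.DataFrame,
                   species_table: Sequence[SpeciesInfo],
                   *, thresholds: Optional[dict] = None) -> pd.DataFrame:
    """Length-based status table for one fishery.

    ``last_species_obs`` holds last-period species observations (columns
    fishery_id, species_id, length_at_catch_cm).  Per species: median
    length-at-catch, reference lengths (external values preferred), the
    rounded ratio, its label, and the Lc-vs-Lopt flag.  Species lacking both
    Lmax and external lengths are flagged (label ``unassessed``) and carry
    NaN references.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    info_map = {s.species_id: s for s in species_table}
    rows = []
    for (fishery, sp), g in last_species_obs.groupby(["fishery_id", "species_id"], sort=True):
        lc = float(np.median(g["length_at_catch_cm"]))
        info = info_map.get(str(sp))
        if info is None or (info.lmax_cm is None and info.lm_external_cm is None):
            rows.append({"fishery_id": fishery, "species_id": sp, "lc_median_cm": lc,
                         "linf_cm": np.nan, "lm_cm": np.nan, "lm_source": "",
                         "lopt_cm": np.nan, "lopt_source": "", "ratio": np.nan,
                         "label": "unassessed", "lc_vs_lopt": "", "lmax_cm": np.nan})
            continue
        est = life_history_estimates(info)
        ratio = catch_length_ratio(lc, est.lm_cm)
        rows.append({
            "fishery_id": fishery, "species_id": sp, "lc_median_cm": lc,
            "linf_cm": est.linf_cm, "lm_cm": est.lm_cm, "lm_source": est.lm_source,
            "lopt_cm": est.lopt_cm, "lopt_source": est.lopt_source,
            "ratio": ratio,
            "label": classify_status(ratio, healthy_min=thr["healthy_min"],
                                     serious_max=thr["serious_max"]),
            "lc_vs_lopt": classify_vs_lopt(lc, est.lopt_cm),
            "lmax_cm": np.nan if info.lmax_cm is None else float(info.lmax_cm),
        })
    return pd.DataFrame(rows)


def status_class_summaries(status_table: pd.DataFrame) -> pd.DataFrame:
    """Mean ratio and Lmax summaries per status class.

    Returns one row per label present (excluding ``unassessed``) plus a
    combined ``not_seriously_overexploited`` row (healthy + overexploited),
    with mean ratio (as a percentage), and mean/median Lmax over species
    with a known Lmax.
    """
    t = status_table[status_table["label"] != "unassessed"]
    out = []

    def _row(name: str, sub: pd.DataFrame) -> dict:
        lmax = sub["lmax_cm"].dropna()
        return {"class": name, "n": int(len(sub)),
                "mean_ratio": float(sub["ratio"].mean()),
                "mean_ratio_pct": float(sub["ratio"].mean() * 100.0),
                "mean_lmax_cm": float(lmax.mean()) if len(lmax) else np.nan,
                "median_lmax_cm": float(lmax.median()) if len(lmax) else np.nan}

    for label in STATUS_LABELS:
        sub = t[t["label"] == label]
        if len(sub):
            out.append(_row(label, sub))
    non_so = t[t["label"] != "seriously_overexploited"]
    if len(non_so):
        out.append(_row("not_seriously_overexploited", non_so))
    return pd.DataFrame(out)


class StockStatusClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based classifier over length ratios Lc/Lm.

    A stateless threshold rule wrapped in the estimator interface so status
    classification composes with sklearn tooling.  ``fit`` only validates
    and records the class set.

    Parameters
    ----------
    healthy_min : float
        Smallest ratio labeled healthy.
    serious_max : float
        Largest ratio labeled seriously overexploited.
    """

    def __init__(self, healthy_min: float = DEFAULT_THRESHOLDS["healthy_min"],
                 serious_max: float = DEFAULT_THRESHOLDS["serious_max"]):
        self.healthy_min = healthy_min
        self.serious_max = serious_max

    def fit(self, X=None, y=None) -> "StockStatusClassifier":
        if not 0 < self.serious_max < self.healthy_min:
            raise ValueError("need 0 < serious_max < healthy_min")
        self.classes_ = np.array(STATUS_LABELS)
        return self

    def predict(self, X) -> np.ndarray:
        """Labels for an array of Lc/Lm ratios (column vector or 1-D)."""
        if not hasattr(self, "classes_"):
            self.fit()
        r = np.asarray(X, dtype=float).reshape(-1)
        return np.array([classify_status(v, healthy_min=self.healthy_min,
                                         serious_max=self.serious_max) for v in r])
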
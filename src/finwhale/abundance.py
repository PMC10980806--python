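"""Stratified design-based density and abundance estimation.

Given a fitted detection function, density in each stratum is estimated
by the Horvitz–Thompson estimator over detected groups,

    D_hat = sum_i s_i / mu_i / (2 L),

with ``s_i`` the group size, ``mu_i`` the per-observation effective
strip width (in km here) and ``L`` the stratum effort; group density
uses ``s_i = 1``.  Abundance is ``N_hat = D_hat * A``.  The coefficient
of variation combines, by the delta method, the between-transect
encounter-rate variance (the stratified "R2" estimator), the variance
of the average detectability, and the variance of mean group size.
Confidence intervals use the standard lognormal interval of
distance-sampling practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import DetectionFit
from .survey_data import Stratum, SurveyDataset

M_PER_KM = 1000.0


@dataclass
class StratumEstimate:
    """Encounter rate, density and abundance summary for one stratum."""

    stratum: str
    area_km2: float
    n_groups: int
    n_individuals: int
    k: int  # transects
    effort_km: float
    er_groups: float  # groups per km
    cv_er_groups: float
    er_individuals: float
    cv_er_individuals: float
    mean_group_size: float
    se_group_size: float
    density_groups: float  # groups per km^2
    cv_density_groups: float
    density_individuals: float  # whales per km^2
    cv_density: float
    abundance: float
    cv_abundance: float
    ci: tuple[float, float]
    var_abundance: float = float("nan")

    def as_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__ if f != "ci"}
        d["ci_lower"], d["ci_upper"] = self.ci
        return d


def encounter_rate(
    counts: np.ndarray, lengths_km: np.ndarray
) -> tuple[float, float, float]:
    """Encounter rate ``n / L`` with the between-transect R2 variance.

    ``counts`` holds detections per transect, ``lengths_km`` the
    transect lengths.  Returns ``(rate, variance, cv)``; with a single
    transect the variance is flagged unavailable (NaN).

        var(n/L) = k / (L^2 (k-1)) * sum_j l_j^2 (n_j/l_j - n/L)^2
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_km, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must align")
    if np.any(lengths <= 0):
        raise ValueError("transect lengths must be positive")
    k = counts.size
    L = lengths.sum()
    er = counts.sum() / L
    if k < 2:
        return float(er), float("nan"), float("nan")
    dev = counts / lengths - er
    var = k / (L**2 * (k - 1)) * np.sum(lengths**2 * dev**2)
    cv = np.sqrt(var) / er if er > 0 else float("nan")
    return float(er), float(var), float(cv)


def mean_group_size(sizes: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean of observed group sizes with its standard error."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("no groups observed")
    mean = float(sizes.mean())
    se = float(sizes.std(ddof=1) / np.sqrt(sizes.size)) if sizes.size > 1 else 0.0
    return mean, se


def lognormal_ci(n: float, cv: float, df: float | None = None) -> tuple[float, float]:
    """95% lognormal confidence interval ``(N/C, N*C)``.

    ``C = exp(q * sqrt(ln(1 + cv^2)))`` with ``q`` the 0.975 standard
    normal quantile, or the Student-t quantile when ``df`` is given.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if n <= 0:
        raise ValueError("estimate must be positive")
    q = stats.norm.ppf(0.975) if df is None else stats.t.ppf(0.975, df)
    c = np.exp(q * np.sqrt(np.log1p(cv**2)))
    return float(n / c), float(n * c)


def _stratum_tables(dataset: SurveyDataset, stratum: str):
    transects = dataset.transects[dataset.transects["stratum"] == stratum]
    sightings = dataset.sightings[dataset.sightings["stratum"] == stratum]
    if transects.empty:
        raise ValueError(f"no transects in stratum {stratum!r}")
    return transects, sightings


def _per_transect_counts(transects, sightings, weights=None):
    w = pd.Series(
        np.ones(len(sightings)) if weights is None else weights,
        index=sightings.index,
    )
    by = w.groupby(sightings["transect_id"]).sum()
    counts = by.reindex(transects["transect_id"], fill_value=0.0).to_numpy()
    return counts, transects["length_km"].to_numpy(dtype=float)


def estimate_density(
    fit: DetectionFit, dataset: SurveyDataset, stratum: str
) -> StratumEstimate:
    """Horvitz–Thompson density estimate for one stratum.

    ``fit`` must have been fitted on (a superset of) the dataset's
    sightings so per-observation ESWs align by position in
    ``dataset.sightings``.
    """
    if len(fit.esw_m) != len(dataset.sightings):
        raise ValueError("fit does not cover the dataset's sightings")
    transects, sightings = _stratum_tables(dataset, stratum)
    area = dataset.stratum(stratum).area_km2
    L = float(transects["length_km"].sum())
    k = len(transects)

    esw_km = pd.Series(fit.esw_m / M_PER_KM, index=dataset.sightings.index)
    mu = esw_km.loc[sightings.index].to_numpy()
    sizes = sightings["group_size"].to_numpy(dtype=float)
    n_s = len(sightings)
    n_ind = int(sizes.sum())

    counts_g, lengths = _per_transect_counts(transects, sightings)
    er_g, _, cv_er_g = encounter_rate(counts_g, lengths)
    counts_i, _ = _per_transect_counts(transects, sightings, weights=sizes)
    er_i, _, cv_er_i = encounter_rate(counts_i, lengths)

    cv_pa = fit.se_pa / fit.pa if fit.pa > 0 else float("nan")

    if n_s == 0:
        return StratumEstimate(
            stratum=stratum, area_km2=area, n_groups=0, n_individuals=0, k=k,
            effort_km=L, er_groups=0.0, cv_er_groups=float("nan"),
            er_individuals=0.0, cv_er_individuals=float("nan"),
            mean_group_size=float("nan"), se_group_size=float("nan"),
            density_groups=0.0, cv_density_groups=float("nan"),
            density_individuals=0.0, cv_density=float("nan"),
            abundance=0.0, cv_abundance=float("nan"), ci=(0.0, 0.0),
        )

    es, se_es = mean_group_size(sizes)
    cv_es = se_es / es

    if np.any(mu <= 0):
        raise ValueError("missing or non-positive per-observation ESW")
    d_groups = float(np.sum(1.0 / mu) / (2.0 * L))
    d_ind = float(np.sum(sizes / mu) / (2.0 * L))

    cv_dg = float(np.sqrt(np.nansum([cv_er_g**2, cv_pa**2])))
    cv_d = float(np.sqrt(np.nansum([cv_er_g**2, cv_pa**2, cv_es**2])))

    return StratumEstimate(
        stratum=stratum, area_km2=area, n_groups=n_s, n_individuals=n_ind, k=k,
        effort_km=L, er_groups=er_g, cv_er_groups=cv_er_g,
        er_individuals=er_i, cv_er_individuals=cv_er_i,
        mean_group_size=es, se_group_size=se_es,
        density_groups=d_groups, cv_density_groups=cv_dg,
        density_individuals=d_ind, cv_density=cv_d,
        abundance=float("nan"), cv_abundance=float("nan"), ci=(np.nan, np.nan),
    )


def estimate_abundance(
    estimate: StratumEstimate, area_km2: float | None = None, df: float | None = None
) -> StratumEstimate:
    """Scale a density estimate to abundance with a lognormal CI."""
    area = estimate.area_km2 if area_km2 is None else area_km2
    if area <= 0:
        raise ValueError("area must be positive")
    n_hat = estimate.density_individuals * area
    cv = estimate.cv_density
    if n_hat > 0 and np.isfinite(cv):
        ci = lognormal_ci(n_hat, cv, df=df)
        var = (cv * n_hat) ** 2
    else:
        ci = (0.0, 0.0)
        var = float("nan")
    return replace(
        estimate, area_km2=area, abundance=float(n_hat), cv_abundance=cv,
        ci=ci, var_abundance=var,
    )


def estimate_stratum(
    fit: DetectionFit, dataset: SurveyDataset, stratum: str, df: float | None = None
) -> StratumEstimate:
    """Density then abundance for one stratum (convenience chain)."""
    return estimate_abundance(estimate_density(fit, dataset, stratum), df=df)


def combine_strata(
    estimates: Sequence[StratumEstimate], name: str = "All", df: float | None = None
) -> StratumEstimate:
    """Pooled estimate over independent strata.

    Abundances add, variances add, and the pooled density is
    ``N_all / sum(A)``.  A single stratum is returned unchanged apart
    from the name.
    """
    if not estimates:
        raise ValueError("no estimates to combine")
    names = [e.stratum for e in estimates]
    if len(set(names)) != len(names):
        raise ValueError("overlapping strata in combination")
    if len(estimates) == 1:
        return replace(estimates[0], stratum=name)
    area = sum(e.area_km2 for e in estimates)
    n_hat = sum(e.abundance for e in estimates)
    var = float(np.nansum([e.var_abundance for e in estimates]))
    cv = float(np.sqrt(var) / n_hat) if n_hat > 0 else float("nan")
    L = sum(e.effort_km for e in estimates)
    n_groups = sum(e.n_groups for e in estimates)
    n_ind = sum(e.n_individuals for e in estimates)
    sizes_mean = n_ind / n_groups if n_groups else float("nan")
    ci = lognormal_ci(n_hat, cv, df=df) if n_hat > 0 else (0.0, 0.0)
    return StratumEstimate(
        stratum=name, area_km2=area, n_groups=n_groups, n_individuals=n_ind,
        k=sum(e.k for e in estimates), effort_km=L,
        er_groups=n_groups / L, cv_er_groups=float("nan"),
        er_individuals=n_ind / L, cv_er_individuals=float("nan"),
        mean_group_size=sizes_mean, se_group_size=float("nan"),
        density_groups=sum(e.density_groups * e.area_km2 for e in estimates) / area,
        cv_density_groups=float("nan"),
        density_individuals=n_hat / area, cv_density=cv,
        abundance=float(n_hat), cv_abundance=cv, ci=ci, var_abundance=var,
    )


def abundance_table(
    fit: DetectionFit, dataset: SurveyDataset, df: float | None = None
) -> pd.DataFrame:
    """Per-stratum and combined estimates as one tidy table."""
    per = [estimate_stratum(fit, dataset, s.name, df=df) for s in dataset.strata]
    rows = [e.as_dict() for e in per]
    if len(per) > 1:
        rows.append(combine_strata(per, df=df).as_dict())
    return pd.DataFrame(rows)
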
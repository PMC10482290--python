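"""Selection-response statistics.

Breeder's-equation machinery (selection differential S, intensity i,
response R, realised heritability h2 = slope of R on cumulative S through
the origin, with a generation-level bootstrap), the Vargha-Delaney A
effect size, the coefficient of variation, robust median/MAD summaries,
and the family-mean plasticity estimator (difference in family mean trait
between high- and low-nitrate treatments).

Sample standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class HeritabilityEstimate:
    """Realised heritability with bootstrap uncertainty."""

    h2: float
    bootstrap: np.ndarray
    ci_low: float
    ci_high: float
    n_bootstrap: int


def selection_differential(population_values, selected_values) -> float:
    """Mean of the selected parents minus the mean of the whole population."""
    population_values = np.asarray(population_values, dtype=float)
    selected_values = np.asarray(selected_values, dtype=float)
    if population_values.size == 0 or selected_values.size == 0:
        raise ValueError("empty input")
    return float(selected_values.mean() - population_values.mean())


def selection_intensity(S: float, trait_sd: float) -> float:
    """Selection differential in phenotypic standard-deviation units."""
    if trait_sd <= 0:
        raise ValueError("trait_sd must be positive")
    return S / trait_sd


def response_series(selected_means: pd.Series, control_means: pd.Series) -> pd.Series:
    """R_t = selected-population mean minus control-population mean, aligned
    on the generation index."""
    if not selected_means.index.equals(control_means.index):
        raise ValueError("generation indices misaligned between series")
    return selected_means - control_means


def fit_h2(cumS, R) -> float:
    """Zero-intercept least-squares slope of R on cumulative S."""
    cumS = np.asarray(cumS, dtype=float)
    R = np.asarray(R, dtype=float)
    den = (cumS ** 2).sum()
    if den == 0:
        raise ValueError("all-zero cumulative selection differential")
    return float((cumS * R).sum() / den)


def realised_heritability(cumS, R, n_bootstrap: int = 1000,
                          rng: np.random.Generator | None = None) -> HeritabilityEstimate:
    """Realised heritability with a generation-level bootstrap.

    Generations (pairs cumS_t, R_t) are resampled with replacement,
    the zero-intercept slope refitted, and the central 95% interval of
    the bootstrap distribution reported.  Resamples with an all-zero
    cumS (undefined slope) are dropped.
    """
    cumS = np.asarray(cumS, dtype=float)
    R = np.asarray(R, dtype=float)
    if len(cumS) != len(R):
        raise ValueError("series lengths differ")
    if len(cumS) < 2:
        raise ValueError("need at least 2 generations")
    h2 = fit_h2(cumS, R)
    rng = rng if rng is not None else np.random.default_rng()
    n = len(cumS)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    num = (cumS[idx] * R[idx]).sum(axis=1)
    den = (cumS[idx] ** 2).sum(axis=1)
    boot = num[den > 0] / den[den > 0]
    lo, hi = np.percentile(boot, [2.5, 97.5]) if boot.size else (np.nan, np.nan)
    return HeritabilityEstimate(h2=h2, bootstrap=boot, ci_low=float(lo),
                                ci_high=float(hi), n_bootstrap=n_bootstrap)


def selection_series(phenotypes: pd.DataFrame, selected_population: str,
                     control_population: str,
                     value_col: str = "branches") -> pd.DataFrame:
    """Per-generation S, i, cumS and R for one selected/control pair.

    Selection happens at generations 0..G-1 (flagged parents) and the
    response is read at generations 1..G as the difference of the selected
    and control population means.  Rows are indexed by the response
    generation t = 1..G with cumS_t the selection accumulated before t.
    """
    sel = phenotypes[phenotypes["population_id"] == selected_population]
    ctrl = phenotypes[phenotypes["population_id"] == control_population]
    if sel.empty or ctrl.empty:
        raise ValueError("empty selected or control population")
    gens = sorted(set(sel["generation"]) & set(ctrl["generation"]))
    parent_gens = gens[:-1]
    S, intensity = [], []
    for g in parent_gens:
        at = sel[sel["generation"] == g]
        s = selection_differential(at[value_col],
                                   at.loc[at["selected"], value_col])
        S.append(s)
        intensity.append(selection_intensity(s, at[value_col].std(ddof=1)))
    sel_means = sel.groupby("generation")[value_col].mean()
    ctrl_means = ctrl.groupby("generation")[value_col].mean()
    R = response_series(sel_means.loc[gens[1:]], ctrl_means.loc[gens[1:]])
    return pd.DataFrame({
        "generation": gens[1:], "S": S, "i": intensity,
        "cumS": np.cumsum(S), "R": R.to_numpy()})


def realised_heritability_from_phenotypes(
        phenotypes: pd.DataFrame, selected_population: str,
        control_population: str, value_col: str = "branches",
        n_bootstrap: int = 1000,
        rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, HeritabilityEstimate]:
    """Full breeder's-equation pipeline: series plus bootstrap h2."""
    series = selection_series(phenotypes, selected_population,
                              control_population, value_col)
    est = realised_heritability(series["cumS"], series["R"],
                                n_bootstrap=n_bootstrap, rng=rng)
    return series, est


def vargha_delaney_A(sample_x, sample_y) -> float:
    """Probability that a random draw from x exceeds one from y, ties at 0.5.

    A = [#(x > y) + 0.5 #(x = y)] / (n_x n_y), computed from rank sums.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float((r1 - x.size * (x.size + 1) / 2) / (x.size * y.size))


def coefficient_of_variation(values) -> float:
    """Sample SD divided by sample mean."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("zero mean")
    return float(values.std(ddof=1) / mean)


def robust_summary(values) -> tuple[float, float]:
    """Median and raw median absolute deviation (no 1.4826 scaling)."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    return float(med), float(np.median(np.abs(values - med)))


def family_plasticity(phenotypes: pd.DataFrame,
                      value_col: str = "branches") -> tuple[pd.DataFrame, float, float]:
    """Per-family plasticity and its population summary.

    ``phenotypes`` needs columns ``family_id``, ``treatment`` (HN/LN) and
    the trait column.  Per family: mean(HN) - mean(LN).  Summary: mean of
    the family deltas and their standard error across families.
    """
    means = (phenotypes.groupby(["family_id", "treatment"], observed=True)[value_col]
             .mean().unstack("treatment"))
    for t in ("HN", "LN"):
        if t not in means.columns or means[t].isna().any():
            missing = (means.index[means[t].isna()].tolist()
                       if t in means.columns else means.index.tolist())
            raise ValueError(
                f"families observed in only one treatment (missing {t}): "
                f"{missing[:5]}")
    deltas = (means["HN"] - means["LN"]).rename("delta").reset_index()
    d = deltas["delta"].to_numpy()
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan
    return deltas, mean, se
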
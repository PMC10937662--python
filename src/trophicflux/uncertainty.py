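"""Monte Carlo pedigree uncertainty and across-model comparison tests.

Each model parameter carries a pedigree coefficient of variation (CV)
expressing data quality (e.g. classes 0.1 / 0.5 / 0.8 for well-,
moderately and poorly sampled diets).  An ensemble draw samples every
CV-flagged parameter from Normal(base, cv * |base|), truncates
negatives to zero, renormalizes diet columns, and re-derives the
balance quantities.  Ensembles of metric values are then compared with
Welch (unequal-variance) two-tailed t-tests under a conservative
Bonferroni family correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import FoodWebModel, FoodWebError, PARAM_NAMES

__all__ = [
    "MonteCarloEnsemble",
    "WelchResult",
    "ComparisonTest",
    "perturb_model",
    "draw_ensemble",
    "ensemble_metrics",
    "welch_ttest",
    "welch_from_summary",
    "bonferroni",
    "compare_ensembles",
]

#: bounded retries for an all-zero diet column after truncation
_MAX_COLUMN_RETRIES = 100


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


@dataclass
class ComparisonTest:
    """One Welch test within a Bonferroni family."""

    metric: str
    t: float
    df: float
    p: float
    p_adjusted: float
    significant: bool


@dataclass
class MonteCarloEnsemble:
    """Seeded ensemble of perturbed models drawn from pedigree CVs."""

    base: FoodWebModel
    n: int
    seed: int
    models: list[FoodWebModel] = field(repr=False, default_factory=list)

    def metrics(self, metric_fn: Callable[[FoodWebModel], Mapping[str, float]]) -> pd.DataFrame:
        """Evaluate a metric function on every draw (rows = draws)."""
        records = [dict(metric_fn(m)) for m in self.models]
        out = pd.DataFrame.from_records(records)
        out.index.name = "draw"
        return out

    def summary(self, metric_fn) -> pd.DataFrame:
        vals = self.metrics(metric_fn)
        return vals.describe(percentiles=[0.25, 0.5, 0.75]).T


def _sample(rng, base: float, cv: float, lognormal: bool) -> float:
    if cv <= 0 or base == 0:
        return base
    if lognormal:
        sigma2 = np.log1p(cv ** 2)
        mu = np.log(abs(base)) - sigma2 / 2.0
        return float(np.sign(base) * rng.lognormal(mu, np.sqrt(sigma2)))
    return float(max(rng.normal(base, cv * abs(base)), 0.0))


def perturb_model(
    model: FoodWebModel,
    rng: np.random.Generator,
    mode: str = "parameters",
    lognormal: bool = False,
) -> FoodWebModel:
    """One Monte Carlo draw of a model.

    ``mode='parameters'`` (default) perturbs group parameters
    (biomass, pb, qb, ae) and diet cells; diet columns are
    renormalized, ae is clipped to [0, 1] and pb is capped at ae*qb so
    the draw remains a valid model.  ``mode='fates'`` is available via
    :func:`trophicflux.model.build_production_fate` on the drawn model;
    the diet cells *are* the predation structure of the production
    matrix, so parameter-level sampling propagates the quoted CVs to
    every fate element.
    """
    if mode != "parameters":
        raise FoodWebError(f"unknown sampling mode {mode!r}")
    out = model.copy()
    ped = model.pedigree
    for i, g in enumerate(out.groups):
        if g.group_type != "living":
            continue
        g.biomass = _sample(rng, g.biomass, ped.params[i, 0], lognormal)
        g.pb = _sample(rng, g.pb, ped.params[i, 1], lognormal)
        g.qb = _sample(rng, g.qb, ped.params[i, 2], lognormal)
        g.ae = min(_sample(rng, g.ae, ped.params[i, 3], lognormal), 1.0)
        if g.qb > 0:
            g.pb = min(g.pb, g.ae * g.qb)
        g.ee = None

    qb = out.param("qb")
    for j in np.flatnonzero(out.living & (qb > 0)):
        cvs = ped.diet[:, j]
        if not (cvs > 0).any():
            continue
        base_col = model.diet[:, j]
        for attempt in range(_MAX_COLUMN_RETRIES):
            col = np.array(
                [_sample(rng, base_col[i], cvs[i], lognormal) for i in range(model.n)]
            )
            s = col.sum()
            if s > 0:
                out.diet[:, j] = col / s
                break
        else:
            raise FoodWebError(
                f"diet column of group {out.groups[j].id} "
                f"({out.groups[j].name}) kept collapsing to zero after "
                f"{_MAX_COLUMN_RETRIES} redraws"
            )
    return out


def draw_ensemble(
    model: FoodWebModel,
    n: int,
    seed: int,
    mode: str = "parameters",
    lognormal: bool = False,
) -> MonteCarloEnsemble:
    """Draw ``n`` perturbed models; reproducible for a fixed seed.

    With every CV equal to zero each draw equals the base model
    exactly.
    """
    if n < 1:
        raise FoodWebError("ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    models = [perturb_model(model, rng, mode=mode, lognormal=lognormal) for _ in range(n)]
    return MonteCarloEnsemble(base=model, n=n, seed=seed, models=models)


def ensemble_metrics(
    model: FoodWebModel,
    n: int,
    seed: int,
    metric_fn: Callable[[FoodWebModel], Mapping[str, float]],
    mode: str = "parameters",
    lognormal: bool = False,
) -> pd.DataFrame:
    """Streaming variant: per-draw metric values without keeping models."""
    if n < 1:
        raise FoodWebError("ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        m = perturb_model(model, rng, mode=mode, lognormal=lognormal)
        records.append(dict(metric_fn(m)))
    out = pd.DataFrame.from_records(records)
    out.index.name = "draw"
    return out


# ---------------------------------------------------------------------------
# statistics


def welch_ttest(x: Iterable[float], y: Iterable[float]) -> WelchResult:
    """Two-tailed Welch (unequal-variance) t-test with Satterthwaite df."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise FoodWebError("each sample needs size >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return WelchResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0)
        return WelchResult(
            t=float(np.sign(x.mean() - y.mean()) * np.inf),
            df=float(len(x) + len(y) - 2),
            p=0.0,
            degenerate=True,
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    se2 = vx / len(x) + vy / len(y)
    df = se2 ** 2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch test from summary statistics (for published-table checks)."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    se2 = sd1 ** 2 / n1 + sd2 ** 2 / n2
    df = se2 ** 2 / (
        (sd1 ** 2 / n1) ** 2 / (n1 - 1) + (sd2 ** 2 / n2) ** 2 / (n2 - 1)
    )
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def bonferroni(p_values: Iterable[float], m: int | None = None) -> np.ndarray:
    """Conservative Bonferroni adjustment: min(1, m * p), order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise FoodWebError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise FoodWebError(
            f"family size m={m} smaller than the number of tests {len(p)}"
        )
    return np.minimum(1.0, m * p)


def compare_ensembles(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    m: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch-test every shared metric column across two ensembles.

    ``metrics_a`` / ``metrics_b`` hold per-draw metric values (one
    column per metric id, e.g. each focal group x footprint/reach).
    The Bonferroni family size defaults to the number of tests.
    Returns one row per metric: t, df, raw p, adjusted p, significance
    at ``alpha``.
    """
    cols_a, cols_b = list(metrics_a.columns), list(metrics_b.columns)
    if set(cols_a) != set(cols_b):
        raise FoodWebError(
            f"metric sets differ: {sorted(set(cols_a) ^ set(cols_b))}"
        )
    tests = []
    for c in cols_a:
        r = welch_ttest(metrics_a[c].to_numpy(), metrics_b[c].to_numpy())
        tests.append((c, r.t, r.df, r.p))
    raw = pd.DataFrame(tests, columns=["metric", "t", "df", "p"])
    raw["p_adjusted"] = bonferroni(raw["p"], m=m)
    raw["significant"] = raw["p_adjusted"] < alpha
    return raw
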
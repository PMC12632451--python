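"""Multi-hit model of carcinogenesis with heterogeneous mutation effects.

Each tissue lineage acquires carcinogenic mutations as a rate-v Poisson
process over a lifespan.  Every mutation draws an independent carcinogenic
effect from a Gamma distribution, and the lineage's transformation hazard
is the baseline rate multiplied by the product of its mutations' effects.
Between consecutive mutation arrivals the hazard is constant, so
transformation times are drawn exactly by competing exponentials — no time
discretisation.  Effects accumulate in log space to avoid overflow.

The model disregards selection in normal tissue: lineages are independent
and mutation counts are Poisson(v t) at age t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MultiHitModel:
    """Mutation arrival rate, baseline hazard and Gamma effect law."""

    v: float = 0.005              # mutations per lineage-year
    r_base: float = 1e-9          # transformation hazard with zero mutations
    effect_shape: float = 2.0     # Gamma shape of per-mutation effect
    effect_rate: float = 1.0      # Gamma rate (mean effect = shape/rate)
    lifespan: float = 80.0
    n_lineages: int = 100_000

    def __post_init__(self):
        if min(self.v, self.r_base, self.effect_shape, self.effect_rate,
               self.lifespan) < 0 or self.n_lineages < 1:
            raise ValueError("all model parameters must be positive")


@dataclass
class LineageOutcome:
    mutation_times: np.ndarray   # sorted arrival times (years)
    effects: np.ndarray          # per-mutation carcinogenic effects
    transformed: bool
    t_cancer: float | None


def simulate_lineages(
    model: MultiHitModel, seed: int | None = None, degenerate_effect: float | None = None
) -> list[LineageOutcome]:
    """Exact simulation of ``model.n_lineages`` independent lineages.

    ``degenerate_effect`` replaces the Gamma law with a point mass (used
    for oracle cross-checks).  Mutations arriving after transformation are
    discarded: an outcome's record stops at its cancer time.
    """
    rng = np.random.default_rng(seed)
    n = model.n_lineages
    counts = rng.poisson(model.v * model.lifespan, size=n)
    out = []
    log_rb = np.log(model.r_base) if model.r_base > 0 else -np.inf
    for k in counts:
        times = np.sort(rng.uniform(0.0, model.lifespan, size=k))
        if degenerate_effect is not None:
            effects = np.full(k, float(degenerate_effect))
        else:
            effects = rng.gamma(model.effect_shape, 1.0 / model.effect_rate, size=k)
        # piecewise-constant hazard between arrivals, in log space
        log_h = log_rb + np.concatenate([[0.0], np.cumsum(np.log(effects))])
        bounds = np.concatenate([[0.0], times, [model.lifespan]])
        durations = np.diff(bounds)
        threshold = rng.exponential()
        cum = np.cumsum(np.exp(log_h) * durations)
        idx = int(np.searchsorted(cum, threshold))
        if idx < len(durations):
            prev = cum[idx - 1] if idx > 0 else 0.0
            t_cancer = bounds[idx] + (threshold - prev) * np.exp(-log_h[idx])
            out.append(
                LineageOutcome(times[:idx], effects[:idx], True, float(t_cancer))
            )
        else:
            out.append(LineageOutcome(times, effects, False, None))
    return out


def cancer_summaries(outcomes, age_step: float = 5.0, lifespan: float | None = None):
    """Per-cancer table and the incidence curve on an age grid.

    Returns ``(table, incidence)``: ``table`` has one row per transformed
    lineage with columns t_cancer, n_drivers and mean_log_effect (NaN for
    zero-driver cancers); ``incidence`` has age-bin left edges and the
    transformation rate per lineage-year at risk in each bin.  Raises
    ``ValueError`` if no lineage transformed.
    """
    rows = [
        (o.t_cancer, len(o.effects),
         float(np.mean(np.log(o.effects))) if len(o.effects) else np.nan)
        for o in outcomes if o.transformed
    ]
    if not rows:
        raise ValueError("no transformed lineages")
    table = pd.DataFrame(rows, columns=["t_cancer", "n_drivers", "mean_log_effect"])
    if lifespan is None:
        ends = [o.t_cancer if o.transformed else None for o in outcomes]
        lifespan = max(
            max(e for e in ends if e is not None),
            max((o.mutation_times[-1] for o in outcomes if len(o.mutation_times)),
                default=0.0),
        )
        lifespan = float(np.ceil(lifespan / age_step) * age_step)
    edges = np.arange(0.0, lifespan + age_step, age_step)
    exit_times = np.array(
        [o.t_cancer if o.transformed else lifespan for o in outcomes]
    )
    events, _ = np.histogram(table["t_cancer"], bins=edges)
    # lineage-years at risk per bin
    at_risk = np.array([
        np.clip(exit_times - lo, 0.0, hi - lo).sum()
        for lo, hi in zip(edges[:-1], edges[1:])
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(at_risk > 0, events / at_risk, np.nan)
    incidence = pd.DataFrame(
        {"age": edges[:-1], "incidence": rate, "events": events,
         "lineage_years": at_risk}
    )
    return table, incidence


def expected_incidence(
    outcomes, model: MultiHitModel, age_step: float = 5.0
) -> pd.DataFrame:
    """Expected transformation rate per lineage-year on an age grid.

    Integrates each lineage's piecewise-constant hazard over every age bin
    and divides by lineage-years at risk.  Unlike the event counts of
    :func:`cancer_summaries`, this estimator has no shot noise from the
    rarity of transformation itself, so it resolves the incidence curve at
    realistic baseline rates (say 1e-9/year) where the expected number of
    observed transformations is far below one.  It neglects depletion of
    the at-risk pool, which is exact to the order of the cumulative hazard
    (here ~1e-7).
    """
    edges = np.arange(0.0, model.lifespan + age_step, age_step)
    expect = np.zeros(len(edges) - 1)
    at_risk = np.zeros(len(edges) - 1)
    log_rb = np.log(model.r_base) if model.r_base > 0 else -np.inf
    for o in outcomes:
        end = o.t_cancer if o.transformed else model.lifespan
        log_h = log_rb + np.concatenate(
            [[0.0], np.cumsum(np.log(o.effects))]
        )[: len(o.mutation_times) + 1]
        bounds = np.concatenate([[0.0], o.mutation_times, [end]])
        ov = np.clip(
            np.minimum(bounds[None, 1:], edges[1:, None])
            - np.maximum(bounds[None, :-1], edges[:-1, None]),
            0.0, None,
        )
        expect += ov @ np.exp(log_h)
        at_risk += np.clip(end - edges[:-1], 0.0, age_step)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(at_risk > 0, expect / at_risk, np.nan)
    return pd.DataFrame(
        {"age": edges[:-1], "incidence": rate, "expected_events": expect,
         "lineage_years": at_risk}
    )


def conditional_cancer_table(
    model: MultiHitModel,
    n_draw: int,
    seed: int | None = None,
    degenerate_effect: float | None = None,
) -> pd.DataFrame:
    """Exact sampler of the per-cancer law conditional on transformation,
    in the rare-transformation limit.

    When the cumulative hazard over a lifetime is small (as for the
    default baseline rate), the density of a cancer at age t with mutation
    history H is proportional to the hazard r_base * prod(effects before t)
    times the prior of H; the survival factor is 1 + O(cumulative hazard).
    That tilt factorises exactly:

    - age t has density proportional to exp(v (mu - 1) t) on [0, lifespan],
      where mu is the mean per-mutation effect,
    - the driver count k given t is Poisson(mu v t),
    - the k driver effects are i.i.d. size-biased draws, i.e.
      Gamma(shape + 1, rate) for a Gamma(shape, rate) effect law.

    This is the distribution an unconditional simulation converges to as
    lineages -> infinity, without spending lineages on the ~1e-7 event;
    :func:`conditional_cancer_table_from_outcomes` is the simulation-based
    cross-check.  Returns a table with columns t_cancer, n_drivers,
    mean_log_effect (NaN for zero-driver cancers).
    """
    rng = np.random.default_rng(seed)
    mu = (model.effect_shape / model.effect_rate
          if degenerate_effect is None else float(degenerate_effect))
    L, v = model.lifespan, model.v
    lam = v * (mu - 1.0)
    u = rng.random(n_draw)
    if abs(lam) < 1e-12:
        t = u * L
    else:
        t = np.log1p(u * np.expm1(lam * L)) / lam
    k = rng.poisson(mu * v * t)
    total = int(k.sum())
    if degenerate_effect is None:
        logs = np.log(rng.gamma(model.effect_shape + 1.0,
                                1.0 / model.effect_rate, size=total))
    else:
        logs = np.full(total, np.log(float(degenerate_effect)))
    cs = np.concatenate([[0.0], np.cumsum(logs)])
    ends = np.cumsum(k)
    with np.errstate(invalid="ignore", divide="ignore"):
        mle = np.where(k > 0, (cs[ends] - cs[ends - k]) / np.maximum(k, 1), np.nan)
    return pd.DataFrame(
        {"t_cancer": t, "n_drivers": k, "mean_log_effect": mle}
    )


def conditional_cancer_table_from_outcomes(
    outcomes, model: MultiHitModel, n_draw: int, seed: int | None = None
) -> pd.DataFrame:
    """Per-cancer table by importance resampling of simulated lineages.

    Each simulated history is weighted by its cumulative hazard (its
    transformation probability up to the survival factor), a history is
    resampled proportionally to weight, and the cancer age is drawn within
    the history proportionally to the hazard segments.  Converges to the
    same law as :func:`conditional_cancer_table`; kept as the
    mechanistic-simulation cross-check of the factorised sampler.
    """
    rng = np.random.default_rng(seed)
    log_rb = np.log(model.r_base) if model.r_base > 0 else -np.inf
    pool = []
    weights = np.empty(len(outcomes))
    for i, o in enumerate(outcomes):
        end = o.t_cancer if o.transformed else model.lifespan
        log_h = log_rb + np.concatenate([[0.0], np.cumsum(np.log(o.effects))])
        bounds = np.concatenate([[0.0], o.mutation_times, [end]])
        seg = np.exp(log_h) * np.diff(bounds)
        pool.append((bounds, seg, o.effects))
        weights[i] = seg.sum()
    if weights.sum() <= 0:
        raise ValueError("zero total transformation weight")
    idx = rng.choice(len(outcomes), size=n_draw, p=weights / weights.sum())
    t = np.empty(n_draw)
    nd = np.empty(n_draw, dtype=int)
    mle = np.full(n_draw, np.nan)
    for out_i, i in enumerate(idx):
        bounds, seg, effects = pool[i]
        j = int(rng.choice(len(seg), p=seg / seg.sum())) if len(seg) > 1 else 0
        t[out_i] = rng.uniform(bounds[j], bounds[j + 1])
        nd[out_i] = j
        if j:
            mle[out_i] = float(np.mean(np.log(effects[:j])))
    return pd.DataFrame({"t_cancer": t, "n_drivers": nd, "mean_log_effect": mle})


def normal_tissue_summaries(outcomes, age_grid):
    """Mean driver count among not-yet-transformed lineages by age, with
    the age-matched excess carried by cancers.

    Returns a DataFrame with columns age, mean_drivers_normal (over
    lineages still at risk at that age), n_normal, mean_drivers_cancer
    (cancers arising within the age bin ending at that age), n_cancer.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    mut_times = [o.mutation_times for o in outcomes]
    t_cancer = np.array(
        [o.t_cancer if o.transformed else np.inf for o in outcomes]
    )
    cancer_counts = np.array([len(o.effects) for o in outcomes], dtype=float)
    rows = []
    prev_edge = 0.0
    for a in age_grid:
        at_risk = t_cancer > a
        n_mut = np.array([
            np.searchsorted(mt, a) for mt, ok in zip(mut_times, at_risk) if ok
        ])
        in_bin = (t_cancer > prev_edge) & (t_cancer <= a)
        rows.append(
            {
                "age": a,
                "mean_drivers_normal": float(n_mut.mean()) if len(n_mut) else np.nan,
                "n_normal": int(at_risk.sum()),
                "mean_drivers_cancer": float(cancer_counts[in_bin].mean())
                if in_bin.any() else np.nan,
                "n_cancer": int(in_bin.sum()),
            }
        )
        prev_edge = a
    return pd.DataFrame(rows)


def prediction_correlations(table: pd.DataFrame) -> dict:
    """Spearman correlations behind the model's qualitative predictions:
    driver count vs. age, mean log effect vs. driver count, and mean log
    effect vs. age, among cancers with at least one driver."""
    t = table.dropna(subset=["mean_log_effect"])
    out = {}
    out["drivers_vs_age"] = float(
        stats.spearmanr(table["n_drivers"], table["t_cancer"]).statistic
    )
    out["effect_vs_drivers"] = float(
        stats.spearmanr(t["mean_log_effect"], t["n_drivers"]).statistic
    )
    out["effect_vs_age"] = float(
        stats.spearmanr(t["mean_log_effect"], t["t_cancer"]).statistic
    )
    return out
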
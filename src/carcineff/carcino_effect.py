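"""Per-gene carcinogenic-effect estimators.

A mutation's carcinogenic effect w is the per-cell hazard ratio for cancer
initiation, r1/r0.  Given the fraction y of cancer founders carrying the
mutation and the fraction x of normal-tissue cells carrying it, the odds
ratio

    w_hat = [y / (1 - y)] / [x / (1 - x)]

estimates the effect.  Four estimators are provided:

* ``estimate_matched`` — the plain odds ratio from a cancer cohort and a
  normal-tissue cohort, with donor-bootstrap confidence intervals;
* ``estimate_length_benchmark`` — relative effects (units 1/bp) for cohorts
  whose normal tissue shows no observable mutations, benchmarking the
  normal-tissue frequency by the gene's coding length;
* ``fit_hybrid_beta`` — a four-parameter (a, b, phi, w) joint likelihood for
  cancer mutation indicators and normal-tissue cell fractions with a
  detection floor, letting the normal-tissue frequency depend on age;
* ``fit_logistic_effect`` — logistic regression with age and mutation-burden
  covariates, with profile-likelihood confidence intervals for w.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort_io import CohortTable, FUNCTIONAL_CLASSES
from . import cellfraction

_CHI2_95_1DF_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.9207...


@dataclass
class EffectEstimate:
    """Per-gene carcinogenic effect with CI, method tag, and flags."""

    gene: str
    w_hat: float
    ci_low: float
    ci_high: float
    method: str
    n_cancer: int = 0
    n_normal: int = 0
    notes: tuple = ()


@dataclass
class HybridBetaParams:
    """Parameters of the hybrid Beta regression.

    ``1 / (1 + exp(a + b t))`` is the expected mutant cell fraction in
    normal tissue at age t; ``exp(phi)`` is the Beta precision; ``w`` the
    carcinogenic effect; ``x0`` the detection floor below which a true
    fraction is observed as zero.
    """

    a: float
    b: float
    phi: float
    w: float
    x0: float = 0.0


@dataclass
class LogisticParams:
    """Intercept / age slope / burden slope and carcinogenic effect."""

    a: float
    b: float
    c: float
    w: float


def odds_ratio(y: float, x: float, haldane: bool = False, n_y: int = 0, n_x: int = 0):
    """Odds ratio (y/(1-y)) / (x/(1-x)) with explicit zero/infinity handling.

    Returns ``(value, flags)``.  ``haldane`` applies the Haldane–Anscombe
    0.5 pseudo-count correction using the supplied denominators ``n_y``
    and ``n_x`` instead of reporting exact 0 / +inf.
    """
    for name, v in (("y", y), ("x", x)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if haldane:
        if n_y < 1 or n_x < 1:
            raise ValueError("haldane correction requires n_y and n_x >= 1")
        y = (y * n_y + 0.5) / (n_y + 1.0)
        x = (x * n_x + 0.5) / (n_x + 1.0)
    if x == 0.0 and y == 0.0:
        return np.nan, ("undefined",)
    if x == 0.0:
        return np.inf, ("infinite",)
    if y == 0.0:
        return 0.0, ("zero",)
    if y == 1.0:
        return np.inf, ("infinite",)
    if x == 1.0:
        return 0.0, ("zero",)
    return (y / (1.0 - y)) / (x / (1.0 - x)), ()


def _cancer_gene_stats(cancer: CohortTable, gene: str, classes, per_donor: bool):
    """Per-donor (n_units, n_mutated) arrays for the cancer frequency y."""
    mutated_ids = cancer.samples_with_gene(gene, classes)
    s = cancer.samples
    df = pd.DataFrame(
        {
            "donor": s["donor_id"].to_numpy(),
            "mut": s["sample_id"].isin(mutated_ids).to_numpy(dtype=float),
        }
    )
    if per_donor:
        g = df.groupby("donor")["mut"].max().to_frame("sum")
        g["count"] = 1.0
    else:
        g = df.groupby("donor")["mut"].agg(["sum", "count"])
    return g["sum"].to_numpy(), g["count"].to_numpy()


def estimate_matched(
    cancer: CohortTable,
    normal: CohortTable,
    genes,
    B: int = 1000,
    seed: int | None = None,
    classes=FUNCTIONAL_CLASSES,
    haldane: bool = False,
) -> list[EffectEstimate]:
    """Matched odds-ratio estimator with donor-bootstrap 95% CIs.

    y is the fraction of cancer samples with a qualifying mutation in the
    gene; x is the cohort-mean mutant cell fraction in normal tissue.  The
    bootstrap resamples donors independently in each cohort, B times.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    rng = np.random.default_rng(seed)
    out = []
    for gene in genes:
        mut_sum, mut_cnt = _cancer_gene_stats(cancer, gene, classes, per_donor=False)
        y = float(mut_sum.sum() / mut_cnt.sum())
        per_sample = cellfraction._per_sample_fractions(normal, gene, classes)
        fr_sum, fr_cnt = cellfraction._donor_values(normal, per_sample, per_donor=False)
        x = float(fr_sum.sum() / fr_cnt.sum())
        w, flags = odds_ratio(
            y, x, haldane=haldane, n_y=int(mut_cnt.sum()), n_x=int(fr_cnt.sum())
        )
        if "undefined" in flags:
            out.append(
                EffectEstimate(
                    gene, np.nan, np.nan, np.nan, "odds_ratio",
                    cancer.n_samples, normal.n_samples, flags + ("excluded",),
                )
            )
            continue
        nc, nn = len(mut_cnt), len(fr_cnt)
        ic = rng.integers(0, nc, size=(B, nc))
        inr = rng.integers(0, nn, size=(B, nn))
        yb = mut_sum[ic].sum(axis=1) / mut_cnt[ic].sum(axis=1)
        xb = fr_sum[inr].sum(axis=1) / fr_cnt[inr].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            wb = (yb / (1.0 - yb)) / (xb / (1.0 - xb))
        wb = np.where((xb == 0.0) & (yb > 0.0), np.inf, wb)
        wb = np.where((xb == 0.0) & (yb == 0.0), np.nan, wb)
        valid = wb[~np.isnan(wb)]
        if len(valid):
            lo, hi = np.percentile(valid, [2.5, 97.5])
        else:
            lo = hi = np.nan
        out.append(
            EffectEstimate(
                gene, w, float(lo), float(hi), "odds_ratio",
                cancer.n_samples, normal.n_samples, flags,
            )
        )
    return out


def estimate_length_benchmark(
    cancer: CohortTable, genes: pd.DataFrame, classes=FUNCTIONAL_CLASSES
) -> list[EffectEstimate]:
    """Relative carcinogenic effects (units 1/bp) benchmarked by gene length.

    Assumes a uniform mutation rate along the genome and negligible
    selection in the reference tissue, so a gene of coding length L is
    mutated in a fraction proportional to L of normal cells.  The relative
    effect is then L^-1 * f/(1-f) with f the observed mutated fraction of
    cancer samples; its 95% CI is the exact (Clopper–Pearson) binomial CI
    for f pushed through the same monotone map.
    """
    n = cancer.n_samples
    out = []
    for _, row in genes.iterrows():
        L = float(row["coding_length_bp"])
        if L <= 0:
            raise ValueError(f"coding length must be positive for {row['gene']}")
        k = len(cancer.samples_with_gene(row["gene"], classes))
        f_hat = k / n
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")

        def rel(f):
            return np.inf if f >= 1.0 else f / (1.0 - f) / L

        flags = ("infinite",) if f_hat >= 1.0 else ()
        out.append(
            EffectEstimate(
                row["gene"], rel(f_hat), rel(ci.low), rel(ci.high),
                "length_benchmark", n_cancer=n, notes=flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# hybrid Beta regression


def _hybrid_nll(theta, t_cancer, mutated, t_norm, frac, x0):
    """Negative log-likelihood of the hybrid model.

    theta = (a, b, phi, log w).  Cancer samples are Bernoulli with success
    probability w / (w + exp(a + b t)).  A normal sample's true fraction is
    Beta(e^phi mu, e^phi (1 - mu)) with mu = 1/(1 + exp(a + b t)); fractions
    below the detection floor x0 are observed as zero and contribute the
    Beta CDF at x0.
    """
    a, b, phi, logw = theta
    eta_c = a + b * t_cancer - logw          # log odds against mutation
    ll = -np.sum(np.logaddexp(0.0, np.where(mutated > 0, eta_c, -eta_c)))

    eta_n = a + b * t_norm
    mu = special.expit(-eta_n)
    prec = np.exp(phi)
    alpha = prec * mu
    beta_p = prec * (1.0 - mu)
    detected = frac > 0.0
    if np.any(~detected):
        ll += np.sum(
            stats.beta.logcdf(x0, alpha[~detected], beta_p[~detected])
        )
    if np.any(detected):
        ll += np.sum(
            stats.beta.logpdf(frac[detected], alpha[detected], beta_p[detected])
        )
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _numerical_hessian(f, x, eps=1e-4):
    x = np.asarray(x, dtype=float)
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    _ = f0
    return H


def fit_hybrid_beta(
    cancer_presence: pd.DataFrame,
    normal_fractions: pd.DataFrame,
    x0: float | None = None,
    init: HybridBetaParams | None = None,
    seed: int | None = None,
    n_starts: int = 5,
):
    """Joint MLE of the hybrid Beta regression for one gene.

    Parameters
    ----------
    cancer_presence : DataFrame with columns ``age`` and ``mutated`` (0/1).
    normal_fractions : DataFrame with columns ``age`` and ``fraction``
        (observed mutant cell fraction; 0 means below the detection floor).
    x0 : detection floor; defaults to the minimum positive observed fraction.
    init : optional starting parameters; otherwise moment-based.
    seed, n_starts : multi-start local optimisation with jittered starts.

    Returns ``(HybridBetaParams, loglik, ci)`` where ``ci`` is a Wald 95%
    interval for w from the numerical Hessian on log w.

    Raises ``RuntimeError`` (carrying best-so-far parameters in ``args``)
    if no start converges.
    """
    t_c = cancer_presence["age"].to_numpy(dtype=float)
    mut = cancer_presence["mutated"].to_numpy(dtype=float)
    t_n = normal_fractions["age"].to_numpy(dtype=float)
    frac = normal_fractions["fraction"].to_numpy(dtype=float)
    if x0 is None:
        pos = frac[frac > 0]
        x0 = float(pos.min()) if len(pos) else 1e-4

    xbar = max(frac.mean(), 1e-6)
    ybar = min(max(mut.mean(), 1e-6), 1 - 1e-6)
    if init is None:
        a0 = float(np.log(1.0 / xbar - 1.0))
        w0 = max((ybar / (1 - ybar)) / (xbar / (1 - xbar)), 1e-3)
        init = HybridBetaParams(a=a0, b=0.0, phi=np.log(30.0), w=w0, x0=x0)
    theta0 = np.array([init.a, init.b, np.clip(init.phi, -5, 15), np.log(init.w)])

    rng = np.random.default_rng(seed)
    args = (t_c, mut, t_n, frac, x0)
    best = None
    for k in range(n_starts):
        start = theta0 if k == 0 else theta0 + rng.normal(0, [1.0, 0.02, 0.5, 1.0])
        res = optimize.minimize(
            _hybrid_nll, start, args=args, method="L-BFGS-B",
            bounds=[(-30, 30), (-2, 2), (-5, 20), (-25, 25)],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        err = RuntimeError("hybrid Beta fit failed to converge")
        err.args = err.args + (best,)
        raise err
    a, b, phi, logw = best.x
    params = HybridBetaParams(a=a, b=b, phi=phi, w=float(np.exp(logw)), x0=x0)
    # Wald CI for w via the observed information on log w
    try:
        H = _numerical_hessian(lambda th: _hybrid_nll(th, *args), best.x)
        cov = np.linalg.inv(H)
        sd = float(np.sqrt(max(cov[3, 3], 0.0)))
        ci = (float(np.exp(logw - 1.96 * sd)), float(np.exp(logw + 1.96 * sd)))
    except np.linalg.LinAlgError:
        ci = (np.nan, np.nan)
    return params, -best.fun, ci


# ---------------------------------------------------------------------------
# logistic regression with age and burden covariates


def _logistic_nll(beta, X, mutated):
    eta = X @ beta
    return float(np.sum(np.logaddexp(0.0, np.where(mutated > 0, -eta, eta))))


def _fit_logistic(X, mutated, start=None):
    p = X.shape[1]
    start = np.zeros(p) if start is None else start
    res = optimize.minimize(
        _logistic_nll, start, args=(X, mutated), method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    return res


def fit_logistic_effect(samples: pd.DataFrame, init: LogisticParams | None = None):
    """MLE of the logistic carcinogenic-effect model with profile CI for w.

    ``samples`` has columns ``age`` (t), ``burden`` (m), ``group``
    (1 = cancer, 0 = normal) and ``mutated`` (0/1).  The model: a sample is
    mutated with probability w^chi / (w^chi + exp(a + b t + c m)), i.e.
    ordinary logistic regression where log w is the coefficient of the
    cancer indicator.  The 95% CI for w is profile-likelihood based: the
    endpoints are where the profiled log-likelihood drops by
    chi-squared_1(0.95)/2 from its maximum.

    Complete separation yields a boundary estimate (0 or +inf) flagged in
    the returned params via ``w`` and a warning.
    """
    for col in ("age", "burden", "group", "mutated"):
        if col not in samples.columns:
            raise ValueError(f"samples table missing column {col}")
    if samples["group"].nunique() < 2:
        raise ValueError("both cancer and normal groups must be represented")
    t = samples["age"].to_numpy(dtype=float)
    m = samples["burden"].to_numpy(dtype=float)
    chi = samples["group"].to_numpy(dtype=float)
    mutated = samples["mutated"].to_numpy(dtype=float)
    # columns: intercept -a, age -b, burden -c, chi +log w (sign folded below)
    X = np.column_stack([np.ones_like(t), t, m, chi])

    start = None
    if init is not None:
        start = np.array([-init.a, -init.b, -init.c, np.log(init.w)])
    res = _fit_logistic(X, mutated, start)
    neg_a, neg_b, neg_c, logw = res.x
    nll_min = res.fun

    def profile_nll(lw):
        offset = chi * lw
        sub = X[:, :3]

        def nll3(beta):
            eta = sub @ beta + offset
            return float(
                np.sum(np.logaddexp(0.0, np.where(mutated > 0, -eta, eta)))
            )

        r = optimize.minimize(nll3, res.x[:3], method="BFGS",
                              options={"maxiter": 500, "gtol": 1e-8})
        return r.fun

    target = nll_min + _CHI2_95_1DF_HALF

    def bracket_root(direction):
        step = 0.5
        prev = logw
        for _ in range(60):
            cand = prev + direction * step
            if profile_nll(cand) >= target:
                return optimize.brentq(
                    lambda lw: profile_nll(lw) - target, min(prev, cand),
                    max(prev, cand), xtol=1e-4,
                )
            prev = cand
            step *= 1.6
        return direction * np.inf

    if abs(logw) > 20:  # complete separation: boundary estimate
        warnings.warn("complete separation: w estimated at the boundary",
                      stacklevel=2)
        w = 0.0 if logw < 0 else np.inf
        params = LogisticParams(a=-neg_a, b=-neg_b, c=-neg_c, w=w)
        return params, (0.0, np.inf)

    lo = bracket_root(-1.0)
    hi = bracket_root(+1.0)
    params = LogisticParams(a=-neg_a, b=-neg_b, c=-neg_c, w=float(np.exp(logw)))
    ci = (float(np.exp(lo)), float(np.exp(hi)))
    return params, ci
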
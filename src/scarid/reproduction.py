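"""Reproductive biology: GSI cycle, sex ratios, maturity ogives.

Length-at-maturity follows the standard binary logistic model
logit(p) = a + beta*L with midpoint L50 = -a/beta, fitted by MCMC with
wide flat priors (beta restricted to the maturity-increasing sign).
Age-at-maturity uses the equivalent parameterisation
p = 1/(1 + exp(-r (A - A50))) fitted by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from scarid.io_core import AnalysisConfig, FishRecord

CHI2_CRIT_5PCT = 3.841  # chi-square, df=1, two-tailed 5%


def gsi(gw: float, tw: float) -> float:
    """Gonadosomatic index, percent: 100*GW/(TW-GW).

    The denominator is somatic weight; the index is invariant to a
    common rescaling of gonad and somatic weight.
    """
    if gw < 0:
        raise ValueError("gonad weight must be non-negative")
    if gw >= tw:
        raise ValueError("gonad exceeds somatic weight")
    return 100.0 * gw / (tw - gw)


def monthly_gsi_summary(
    records: Sequence[FishRecord], sex: str = "female"
) -> pd.DataFrame:
    """Mean, SD and n of GSI per calendar month for mature fish of one sex.

    All sampling years are pooled into 12 months. Months with no data
    are present but flagged empty (NaN mean), never zero.
    """
    rows = []
    for r in records:
        if (
            r.sex == sex
            and r.mature
            and r.gonad_weight is not None
            and r.total_weight is not None
            and r.gonad_weight < r.total_weight
            and r.capture_month is not None
        ):
            rows.append((r.capture_month, gsi(r.gonad_weight, r.total_weight)))
    df = pd.DataFrame(rows, columns=["month", "gsi"])
    out = pd.DataFrame(index=pd.RangeIndex(1, 13, name="month"))
    grouped = df.groupby("month")["gsi"]
    out["mean_gsi"] = grouped.mean()
    out["sd_gsi"] = grouped.std()
    out["n"] = grouped.size().reindex(out.index, fill_value=0).astype(int)
    out["empty"] = out["n"] == 0
    return out.reset_index()


def sex_ratio_tests(
    records: Sequence[FishRecord], bin_width: float = 5.0
) -> tuple[pd.DataFrame, dict]:
    """Per-length-bin male/female counts with chi-square tests against 1:1.

    Pearson chi-square with df=1 per bin, flagged significant above the
    5% two-tailed critical value 3.841; bins where one sex is absent are
    flagged ``ratio_with_zero`` (the statistic is still reported). The
    overall ratio is summarised as "1:x" male:female with x the nearest
    integer.
    """
    sexed = [r for r in records if r.sex in ("male", "female")]
    if not sexed:
        raise ValueError("no sexed fish")
    tl = np.array([r.total_length for r in sexed])
    male = np.array([r.sex == "male" for r in sexed])
    edges = np.arange(0.0, tl.max() + bin_width, bin_width)
    idx = np.digitize(tl, edges) - 1
    rows = []
    for b in np.unique(idx):
        m = int(np.sum(male[idx == b]))
        f = int(np.sum(~male[idx == b]))
        n = m + f
        if n == 0:
            continue
        chi2 = (m - f) ** 2 / n  # Pearson vs 1:1 with df=1
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b] + bin_width,
                "males": m,
                "females": f,
                "chi2": chi2,
                "p": float(stats.chi2.sf(chi2, df=1)),
                "significant": chi2 > CHI2_CRIT_5PCT,
                "ratio_with_zero": m == 0 or f == 0,
            }
        )
    per_bin = pd.DataFrame(rows)
    n_male, n_female = int(male.sum()), int((~male).sum())
    overall_chi2 = (n_male - n_female) ** 2 / (n_male + n_female)
    ratio = n_female / n_male if n_male else np.inf
    overall = {
        "males": n_male,
        "females": n_female,
        "pct_male": 100.0 * n_male / (n_male + n_female),
        "pct_female": 100.0 * n_female / (n_male + n_female),
        "ratio_string": f"1:{round(ratio)}" if np.isfinite(ratio) else "0:1",
        "chi2": overall_chi2,
        "p": float(stats.chi2.sf(overall_chi2, df=1)),
    }
    return per_bin, overall


@dataclass
class MaturityFit:
    """Posterior summary of the length-at-maturity logistic ogive."""

    a: float
    beta: float
    l50: float
    ci_low: float
    ci_high: float
    credible_level: float
    posterior_samples: int
    acceptance_rate: float
    ess: float
    lmin: float | None = None
    l100: float | None = None
    separation_warning: bool = False

    def proportion_mature(self, length: np.ndarray | float) -> np.ndarray:
        return expit(self.a + self.beta * np.asarray(length, dtype=float))


def _logistic_loglik(
    theta: np.ndarray, x: np.ndarray, y: np.ndarray
) -> float:
    a, b = theta
    eta = a + b * x
    # log Bernoulli: y*eta - log(1+exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_l50_bayes(
    lengths: Sequence[float],
    mature: Sequence[int],
    cfg: AnalysisConfig | None = None,
    seed: int | None = None,
) -> MaturityFit:
    """Bayesian logistic maturity ogive; L50 = -a/beta posterior summary.

    Flat priors: a unrestricted (wide), beta restricted to the
    maturity-increasing sign (beta > 0). Sampling uses an affine-invariant
    ensemble MCMC; the total number of post-burn-in draws, thinning and
    burn-in fraction come from ``cfg``. Reports the posterior mean of L50
    with an equal-tailed credible interval at ``cfg.credible_level``,
    plus acceptance rate and effective sample size as chain diagnostics.
    """
    import emcee

    cfg = cfg or AnalysisConfig()
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(mature, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("lengths and maturity flags must align and be non-empty")
    if y.min() == y.max():
        raise ValueError("need both mature and immature fish")
    separated = x[y == 0].max() < x[y == 1].min()
    if separated:
        warnings.warn("complete separation: posterior driven by priors in the gap")

    def log_prob(theta: np.ndarray) -> float:
        a, b = theta
        if not (0 < b < 100.0) or abs(a) > 1e4:
            return -np.inf
        return _logistic_loglik(theta, x, y)

    # start walkers around the MLE (or a crude moment guess under separation)
    res = optimize.minimize(
        lambda t: -_logistic_loglik(t, x, y),
        x0=np.array([-np.median(x) * 0.2, 0.2]),
        method="Nelder-Mead",
    )
    a0, b0 = res.x if res.x[1] > 0 else (-np.median(x) * 0.2, 0.2)
    b0 = min(max(b0, 1e-3), 50.0)

    nwalkers = 20
    nsteps = max(cfg.mcmc_iterations // nwalkers, 200)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    p0 = np.column_stack(
        [
            a0 + 0.05 * abs(a0 + 1) * rng.standard_normal(nwalkers),
            np.abs(b0 * (1 + 0.05 * rng.standard_normal(nwalkers))) + 1e-4,
        ]
    )
    sampler = emcee.EnsembleSampler(nwalkers, 2, log_prob)
    sampler.random_state = np.random.RandomState(
        int(rng.integers(0, 2**31 - 1))
    ).get_state()
    sampler.run_mcmc(p0, nsteps, progress=False)
    burn = int(cfg.burn_in_fraction * nsteps)
    thin = max(cfg.thin // nwalkers, 1)
    chain = sampler.get_chain(discard=burn, thin=thin, flat=True)
    l50_draws = -chain[:, 0] / chain[:, 1]
    alpha = (1.0 - cfg.credible_level) / 2.0
    lo, hi = np.quantile(l50_draws, [alpha, 1.0 - alpha])
    try:
        tau = float(np.max(sampler.get_autocorr_time(tol=0)))
        ess = float(chain.shape[0] * thin / max(tau, 1.0))
    except Exception:  # autocorr can fail on short chains
        ess = float(chain.shape[0])
    fit = MaturityFit(
        a=float(chain[:, 0].mean()),
        beta=float(chain[:, 1].mean()),
        l50=float(l50_draws.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        credible_level=cfg.credible_level,
        posterior_samples=int(chain.shape[0]),
        acceptance_rate=float(np.mean(sampler.acceptance_fraction)),
        ess=ess,
        lmin=float(x[y == 1].min()) if np.any(y == 1) else None,
        l100=smallest_all_mature_class(x, y),
        separation_warning=bool(separated),
    )
    return fit


def smallest_all_mature_class(
    lengths: np.ndarray, mature: np.ndarray, bin_width: float = 1.0
) -> float | None:
    """Descriptive L100: smallest length class at and above which every
    sampled fish is mature."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(mature, dtype=float)
    if not np.any(y == 1):
        return None
    immature_x = x[y == 0]
    if immature_x.size == 0:
        return float(np.floor(x.min() / bin_width) * bin_width)
    threshold = immature_x.max()
    above = x[x > threshold]
    if above.size == 0:
        return None
    return float(np.floor(above.min() / bin_width) * bin_width)


@dataclass
class AgeMaturityFit:
    """Logistic maturity-at-age ogive p = 1/(1+exp(-r (A - A50)))."""

    r: float
    a50: float
    amin: float | None
    a100: float | None
    n: int
    a50_se: float = float("nan")
    converged: bool = True

    def proportion_mature(self, age: np.ndarray | float) -> np.ndarray:
        return expit(self.r * (np.asarray(age, dtype=float) - self.a50))

    def ogive(self, ages: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": ages, "proportion_mature": self.proportion_mature(ages)}
        )


def fit_a50(ages: Sequence[float], mature: Sequence[int]) -> AgeMaturityFit:
    """Maximum-likelihood age-at-maturity ogive.

    Perfectly separated data have no finite MLE; the midpoint of the gap
    between oldest immature and youngest mature is reported with a large
    slope, which is the limit of the likelihood path.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(mature, dtype=float)
    if y.min() == y.max():
        raise ValueError("need both mature and immature fish")
    amin = float(x[y == 1].min())
    a100 = smallest_all_mature_class(x, y)
    if x[y == 0].max() < x[y == 1].min():
        mid = 0.5 * (x[y == 0].max() + x[y == 1].min())
        return AgeMaturityFit(
            r=np.inf, a50=float(mid), amin=amin, a100=a100, n=x.size, converged=True
        )

    def nll(theta: np.ndarray) -> float:
        r, a50 = theta
        return -_logistic_loglik(np.array([-r * a50, r]), x, y)

    res = optimize.minimize(
        nll, x0=np.array([1.0, float(np.median(x))]), method="Nelder-Mead"
    )
    r, a50 = res.x
    # SE of A50 from the numerically observed information (central differences)
    eps = 1e-4
    h = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.eye(2)[i] * eps
            e_j = np.eye(2)[j] * eps
            h[i, j] = (
                nll(res.x + e_i + e_j)
                - nll(res.x + e_i - e_j)
                - nll(res.x - e_i + e_j)
                + nll(res.x - e_i - e_j)
            ) / (4 * eps**2)
    try:
        a50_se = float(np.sqrt(np.linalg.inv(h)[1, 1]))
    except np.linalg.LinAlgError:
        a50_se = float("nan")
    return AgeMaturityFit(
        r=float(abs(r)),
        a50=float(a50),
        amin=amin,
        a100=a100,
        n=x.size,
        a50_se=a50_se,
        converged=bool(res.success),
    )
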
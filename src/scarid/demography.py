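"""Mortality, survival, generation time and length-based stock indicators.

Natural mortality uses the empirical maximum-age law
ln(M) = a + b ln(tmax); the default coefficients give the
M = 4.899 tmax^-0.916 estimator. Total mortality comes from the age
composition via the Chapman-Robson survival estimator (default) or a
log-linear catch curve on the descending limb; survival is S = e^-Z and
fishing mortality F = Z - M. Stock status is summarised by the optimum
length Lopt = 3 Linf / (3 + M/K) and three length-based catch
indicators: the share of mature fish (> L50), the share within +/-10% of
Lopt, and the share of "mega-spawners" (> 1.1 Lopt); F is compared with
the proxy FMSY = 0.922 M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FMSY_M_RATIO = 0.922  # FMSY proxy for perciform fishes


def natural_mortality(
    tmax: float, coeffs: tuple[float, float] = (float(np.log(4.899)), -0.916)
) -> float:
    """Empirical M from maximum age: M = exp(a + b ln tmax)."""
    if tmax <= 0:
        raise ValueError("tmax must be positive")
    a, b = coeffs
    return float(np.exp(a + b * np.log(tmax)))


@dataclass
class MortalityEstimate:
    z: float
    se: float
    method: str
    n: int
    age_full_recruitment: float


def total_mortality(
    age_frequencies: Mapping[int, int] | pd.Series,
    method: str = "chapman_robson",
) -> MortalityEstimate:
    """Z from an age-frequency sample, Chapman-Robson or catch curve.

    Both use ages at and beyond the modal (fully recruited) age.
    Chapman-Robson: S = T / (n + T - 1) with T the sum of recoded ages,
    Z = -ln S, SE by the delta method. Catch curve: OLS of ln(count) on
    age over the descending limb, Z = -slope. Needs >=3 age classes from
    the mode onward.
    """
    freq = pd.Series(dict(age_frequencies)).sort_index()
    freq = freq[freq > 0]
    if freq.empty:
        raise ValueError("empty age composition")
    mode_age = int(freq.idxmax())
    desc = freq[freq.index >= mode_age]
    if len(desc) < 3:
        raise ValueError("no descending limb: need >=3 classes at/beyond the mode")

    if method == "chapman_robson":
        recoded = desc.index.to_numpy() - mode_age
        counts = desc.to_numpy()
        n = int(counts.sum())
        t_sum = float((recoded * counts).sum())
        tbar = t_sum / n
        s = tbar / (1.0 + tbar - 1.0 / n)
        z = -np.log(s)
        # Chapman-Robson Var(S) = S (S - (T-1)/(n+T-2)); SE(Z) by delta method
        var_s = max(s * (s - (t_sum - 1.0) / (n + t_sum - 2.0)), 0.0)
        se = float(np.sqrt(var_s) / s)
        return MortalityEstimate(float(z), se, "chapman_robson", int(n), mode_age)
    if method == "catch_curve":
        ages = desc.index.to_numpy(dtype=float)
        lnc = np.log(desc.to_numpy(dtype=float))
        res = stats.linregress(ages, lnc)
        return MortalityEstimate(
            float(-res.slope), float(res.stderr), "catch_curve", int(desc.sum()), mode_age
        )
    raise ValueError(f"unknown method {method!r}")


def survival(z: float) -> float:
    """Annual survival fraction S = e^-Z."""
    if z < 0:
        raise ValueError("Z must be non-negative")
    return float(np.exp(-z))


def fishing_mortality(z: float, m: float) -> dict:
    """F = Z - M, floored at 0 with a warning when M exceeds Z."""
    if m < 0 or z < 0:
        raise ValueError("rates must be non-negative")
    f = z - m
    if f < 0:
        warnings.warn("M exceeds Z; fishing mortality floored at 0")
        f = 0.0
    return {
        "f": float(f),
        "f_over_z": float(f / z) if z > 0 else 0.0,
        "f_over_m": float(f / m) if m > 0 else np.inf,
    }


def generation_time(a50: float, z: float, longevity: float) -> float:
    """GT = A50 + Z (longevity - A50); Z here acts as a weighting in [0, 1]."""
    if longevity < a50:
        raise ValueError("longevity must be at least A50")
    return float(a50 + z * (longevity - a50))


def l_opt(linf: float, m: float, k: float) -> dict:
    """Optimum harvest length Lopt = 3 Linf / (3 + M/K), with +/-10% band."""
    if k <= 0:
        raise ValueError("K must be positive")
    if linf <= 0 or m < 0:
        raise ValueError("Linf must be positive, M non-negative")
    lopt = 3.0 * linf / (3.0 + m / k)
    return {"lopt": float(lopt), "band_low": 0.9 * lopt, "band_high": 1.1 * lopt}


def froese_indicators(
    lengths: Sequence[float], l50: float, lopt: float
) -> dict:
    """Three length-based catch indicators, in percent.

    I: mature fish (> L50); II: fish within +/-10% of Lopt;
    III: mega-spawners (> 1.1 Lopt). A healthy age structure carries
    roughly 30-40% mega-spawners.
    """
    tl = np.asarray(lengths, dtype=float)
    if tl.size == 0:
        raise ValueError("empty catch sample")
    return {
        "pct_mature": float(np.mean(tl > l50) * 100.0),
        "pct_opt": float(np.mean((tl >= 0.9 * lopt) & (tl <= 1.1 * lopt)) * 100.0),
        "pct_mega": float(np.mean(tl > 1.1 * lopt) * 100.0),
        "n": int(tl.size),
    }


def froese_table(
    lengths: Sequence[float],
    groups: Sequence[str] | None,
    l50: float,
    lopt: float,
) -> pd.DataFrame:
    """Indicator table: pooled row plus one row per gear/stratum subset."""
    tl = np.asarray(lengths, dtype=float)
    rows = [{"subset": "pooled", **froese_indicators(tl, l50, lopt)}]
    if groups is not None:
        g = np.asarray(groups, dtype=object)
        for name in pd.unique(g):
            sub = tl[g == name]
            if sub.size == 0:
                rows.append({"subset": str(name), "flagged_empty": True})
            else:
                rows.append({"subset": str(name), **froese_indicators(sub, l50, lopt)})
    return pd.DataFrame(rows)


def overfishing_ratio(f: float, m: float) -> dict:
    """F relative to the FMSY proxy 0.922 M; ratios above 1 flag overfishing."""
    if m <= 0:
        raise ValueError("M must be positive")
    ratio = f / (FMSY_M_RATIO * m)
    return {"f_over_fmsy": float(ratio), "overfishing": bool(ratio > 1.0)}


@dataclass
class DemographyReport:
    m: float
    z: float
    z_se: float
    z_method: str
    s: float
    f: float
    f_over_z: float
    f_over_m: float
    gt: float
    lopt: float
    pct_mature: float
    pct_opt: float
    pct_mega: float
    f_over_fmsy: float
    overfishing: bool
    tmax: float
    a50: float
    linf: float
    k: float
    l50: float

    def to_dict(self) -> dict:
        return asdict(self)


def demography_report(
    ages: Sequence[float],
    lengths: Sequence[float],
    linf: float,
    k: float,
    l50: float,
    a50: float,
    m_coefficients: tuple[float, float] = (float(np.log(4.899)), -0.916),
    z_method: str = "chapman_robson",
    longevity: float | None = None,
) -> DemographyReport:
    """Assemble the full demography/status summary from aged-catch data."""
    a = np.asarray(ages, dtype=float)
    tmax = float(longevity if longevity is not None else a.max())
    m = natural_mortality(tmax, m_coefficients)
    freq = pd.Series(a.astype(int)).value_counts().sort_index()
    zest = total_mortality(freq, method=z_method)
    s = survival(zest.z)
    fdict = fishing_mortality(zest.z, m)
    gt = generation_time(a50, min(zest.z, 1.0), tmax)
    lo = l_opt(linf, m, k)
    ind = froese_indicators(lengths, l50, lo["lopt"])
    over = overfishing_ratio(fdict["f"], m)
    return DemographyReport(
        m=m,
        z=zest.z,
        z_se=zest.se,
        z_method=zest.method,
        s=s,
        f=fdict["f"],
        f_over_z=fdict["f_over_z"],
        f_over_m=fdict["f_over_m"],
        gt=gt,
        lopt=lo["lopt"],
        pct_mature=ind["pct_mature"],
        pct_opt=ind["pct_opt"],
        pct_mega=ind["pct_mega"],
        f_over_fmsy=over["f_over_fmsy"],
        overfishing=over["overfishing"],
        tmax=tmax,
        a50=a50,
        linf=linf,
        k=k,
        l50=l50,
    )
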
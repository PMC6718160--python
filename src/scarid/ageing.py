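"""Otolith-reading quality control and annulus-periodicity analysis.

Reader-agreement statistics follow the standard precision conventions:
APE (average percent error) averages per-fish mean absolute deviation
from the fish's mean read, relative to that mean; CV averages the
per-fish coefficient of variation. For two readings CV >= APE
algebraically (the SD dominates the mean absolute deviation).
Disagreement profiles (PD, IRD) and the marginal-increment ratio (MIR)
support ring-periodicity inference: an annual cycle in monthly mean MIR
with a single minimum marks the annulus-completion window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from scarid.io_core import OtolithRecord, pair_readings


@dataclass
class ReadingComparison:
    ape: float  # percent
    cv: float  # percent
    n_fish: int
    pd_by_age: pd.DataFrame | None = None  # per age class: PD, IRD


def ape_cv(readings: Mapping[str, Sequence[float]]) -> ReadingComparison:
    """Average percent error and CV across fish with >=2 age readings.

    Fish whose mean read is zero are excluded (the relative error is
    undefined for them). Raises if no fish has two readings.
    """
    apes, cvs = [], []
    for reads in readings.values():
        x = np.asarray(reads, dtype=float)
        if x.size < 2:
            continue
        m = x.mean()
        if m == 0:
            continue
        apes.append(np.mean(np.abs(x - m)) / m * 100.0)
        cvs.append(x.std(ddof=1) / m * 100.0)
    if not apes:
        raise ValueError("no fish with multiple non-zero readings")
    return ReadingComparison(
        ape=float(np.mean(apes)), cv=float(np.mean(cvs)), n_fish=len(apes)
    )


def disagreement_profiles(
    readings: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """PD and IRD per age class (class = first reading's age).

    PD is the fraction of fish in the class whose two reads differ;
    IRD the mean absolute read difference.
    """
    rows = []
    for reads in readings.values():
        x = list(reads)
        if len(x) < 2:
            continue
        rows.append((x[0], abs(x[0] - x[1])))
    df = pd.DataFrame(rows, columns=["age_class", "abs_diff"])
    if df.empty:
        return pd.DataFrame(columns=["age_class", "pd", "ird", "n"])
    out = (
        df.groupby("age_class")
        .agg(
            pd=("abs_diff", lambda d: float(np.mean(d > 0))),
            ird=("abs_diff", "mean"),
            n=("abs_diff", "size"),
        )
        .reset_index()
    )
    return out


def readings_by_fish(
    otoliths: Sequence[OtolithRecord],
) -> dict[str, list[float]]:
    """Ring counts per fish ordered by reading_id, for ape_cv et al."""
    paired = pair_readings(otoliths)
    return {
        fid: [float(by_read[k].ring_count) for k in sorted(by_read)]
        for fid, by_read in paired.items()
    }


def marginal_increment_ratio(oto: OtolithRecord) -> float:
    """MIR = (edge radius - last ring) / (last ring - second-to-last ring).

    Needs >=2 rings and a positive last increment; scale-invariant under
    common rescaling of all radii.
    """
    if oto.ring_count < 2:
        raise ValueError("need at least 2 rings for MIR")
    r_last, r_prev = oto.ring_radii[-1], oto.ring_radii[-2]
    if r_last - r_prev <= 0:
        raise ValueError("zero last increment")
    return (oto.otolith_radius - r_last) / (r_last - r_prev)


def mir_seasonality(
    otoliths: Sequence[OtolithRecord],
    lengths_by_fish: Mapping[str, float] | None = None,
    max_length: float = 50.0,
    reading_id: int = 2,
    month_pairs: Sequence[tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[int]]:
    """Monthly mean MIR with Welch t-tests between month pairs.

    Only fish below ``max_length`` cm TL enter (older fish have closely
    spaced outer rings). Returns (monthly table, t-test table, annulus
    window = months attaining the minimum monthly mean, ties included at
    1% resolution). Months with n < 2 are excluded from tests.
    """
    rows = []
    for o in otoliths:
        if o.reading_id != reading_id or o.capture_month is None:
            continue
        if lengths_by_fish is not None:
            tl = lengths_by_fish.get(o.fish_id)
            if tl is None or tl >= max_length:
                continue
        try:
            rows.append((o.capture_month, marginal_increment_ratio(o)))
        except ValueError:
            continue
    df = pd.DataFrame(rows, columns=["month", "mir"])
    monthly = pd.DataFrame(index=pd.RangeIndex(1, 13, name="month"))
    g = df.groupby("month")["mir"]
    monthly["mean_mir"] = g.mean()
    monthly["sd_mir"] = g.std()
    monthly["n"] = g.size().reindex(monthly.index, fill_value=0).astype(int)
    monthly = monthly.reset_index()

    tests = []
    if month_pairs is None:
        month_pairs = [(m, m % 12 + 1) for m in range(1, 13)]
    for m1, m2 in month_pairs:
        x1 = df.loc[df["month"] == m1, "mir"].to_numpy()
        x2 = df.loc[df["month"] == m2, "mir"].to_numpy()
        if x1.size < 2 or x2.size < 2:
            continue
        t, p = stats.ttest_ind(x1, x2, equal_var=False)
        tests.append({"month_a": m1, "month_b": m2, "t": float(t), "p": float(p)})
    valid = monthly.dropna(subset=["mean_mir"])
    annulus: list[int] = []
    if not valid.empty:
        mmin = valid["mean_mir"].min()
        annulus = [
            int(m)
            for m, v in zip(valid["month"], valid["mean_mir"])
            if v <= mmin * 1.01 + 1e-12
        ]
    return monthly, pd.DataFrame(tests), annulus


def age_length_key(
    ages: Sequence[float], lengths: Sequence[float], bin_width: float = 5.0
) -> pd.DataFrame:
    """Counts by length bin (rows) and integer age (columns); totals = n."""
    a = np.asarray(ages, dtype=float)
    tl = np.asarray(lengths, dtype=float)
    if a.size != tl.size:
        raise ValueError("ages and lengths must align")
    bins = (np.floor(tl / bin_width) * bin_width).astype(float)
    key = pd.crosstab(bins, a.astype(int))
    key.index.name = "length_bin"
    key.columns.name = "age"
    return key


def otolith_weight_age_fit(
    weights: Sequence[float], ages: Sequence[float]
) -> dict:
    """OLS line of otolith weight (g) on age (years) with residuals."""
    w = np.asarray(weights, dtype=float)
    a = np.asarray(ages, dtype=float)
    if w.size < 3:
        raise ValueError("need at least 3 weight-age pairs")
    if np.ptp(a) == 0:
        raise ValueError("degenerate: all ages identical")
    res = stats.linregress(a, w)
    fitted = res.intercept + res.slope * a
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "n": int(w.size),
        "residuals": w - fitted,
    }
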
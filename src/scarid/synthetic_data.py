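"""Synthetic fish populations with the statistical structure of reef-fish landings.

The generator draws integer ages from a truncated geometric law (total
mortality Z), grows each fish along its own von Bertalanffy trajectory
(one multiplicative deviation per fish, so trajectories are smooth and
mean length-at-age matches the curve), assigns sex by a length-based
protogynous transition (female first, switching to male with logistic
probability, plus a small primary-male fraction for diandry), maturity
by a logistic ogive in length, gonad weight from a two-peak seasonal
gonadosomatic cycle, and otolith ring radii through a single allometric
length-radius law so that biological-intercept back-calculation is exact
by construction. Two otolith readings per fish get independent integer
reader errors truncated at +/-3 rings. Cross-shelf strata are assigned by
gear selectivity curves: inshore gear retains small fish, offshore gear
large fish.

Everything is driven by one ``numpy`` Generator seeded from
``SimConfig.seed``; outputs are byte-identical across runs at a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Sequence
import warnings

import numpy as np
from scipy.special import expit

from scarid.io_core import FishRecord, OtolithRecord

ANNULUS_TIME = 11.5  # month-of-year when the annual ring completes (Nov-Dec)


def vbgf(age: np.ndarray | float, linf: float, k: float, t0: float) -> np.ndarray:
    """von Bertalanffy length at age: L = Linf (1 - exp(-K (t - t0)))."""
    return linf * (1.0 - np.exp(-k * (np.asarray(age, dtype=float) - t0)))


@dataclass
class SimConfig:
    """Study conditions for one simulated landing sample.

    Growth defaults are the pooled-sexes estimates for a large, slow
    growing parrotfish (Linf 85.28 cm, K 0.14 yr^-1, t0 0.16 yr,
    longevity 22 yr); maturity midpoint 38.5 cm; total mortality
    0.9 yr^-1; annual rings complete in November-December; spawning
    peaks in February-March and August-September; overall sex ratio
    calibrated to 1 male : 8 females.
    """

    n_fish: int = 455
    true_linf: float = 85.28
    true_k: float = 0.14
    true_t0: float = 0.16
    length_cv: float = 0.08
    total_mortality_z: float = 0.9
    min_age: int = 1
    max_age: int = 22
    # "exponential": catch-at-age with rate Z (landing samples);
    # "uniform": equal representation of every age class, emulating the
    # length-stratified otolith subsample design (similar numbers per
    # 5-cm length class).
    age_distribution: str = "exponential"
    # maturity ogive (females)
    l50_true: float = 38.5
    maturity_slope: float = 0.40
    # protogynous sex change; default midpoint frozen from
    # calibrate_sexchange_l50 so the expected landed sex ratio is 1:8
    sexchange_l50: float = 65.7
    sexchange_slope: float = 0.15
    primary_male_prob: float = 0.02
    # seasonal gonad cycle
    gsi_peak_months: tuple[int, ...] = (2, 3, 8, 9)
    gsi_base: float = 0.8
    gsi_amplitude: float = 3.5
    gsi_cv: float = 0.40
    annulus_months: tuple[int, int] = (11, 12)
    # otolith readings: ring-count error SD at the reference age, scaled
    # linearly with age (outer rings of old fish are closely spaced and
    # hardest to resolve, so disagreement grows with age)
    reader_error_sd: float = 1.0
    reader_age_ref: float = 8.0
    # selectivity: per-stratum logistic {l50 (cm), slope (cm^-1)};
    # negative slope retains small fish. None = full retention.
    # fleet_weights scale each stratum's relative fishing effort, so the
    # landed sample is dominated by the offshore fleet as in real landings.
    selectivity: dict[str, tuple[float, float]] | None = field(
        default_factory=lambda: {
            "inshore": (38.0, 0.40),
            "offshore": (52.0, 0.30),
        }
    )
    fleet_weights: dict[str, float] = field(
        default_factory=lambda: {"inshore": 0.2, "offshore": 0.8}
    )
    # length-weight (power law, g vs cm) and evisceration
    weight_a: float = 0.0136
    weight_b: float = 3.05
    weight_cv: float = 0.08
    eviscerated_fraction: float = 0.0
    # otolith allometry: TL = oto_coef * R^c  (R in mm)
    oto_coef: float = 7.0
    abi_exponent_true: float = 1.2
    # otolith weight linear in age (g)
    oto_weight_intercept: float = 0.05
    oto_weight_slope: float = 0.12
    oto_weight_sd: float = 0.0
    id_prefix: str = "F"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_linf <= 0 or self.true_k <= 0:
            raise ValueError("growth parameters must be positive")
        if self.total_mortality_z <= 0:
            raise ValueError("total_mortality_z must be positive")
        for p in (self.primary_male_prob, self.length_cv, self.eviscerated_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.selectivity is not None:
            for stratum, pair in self.selectivity.items():
                if len(pair) != 2 or pair[0] <= 0:
                    raise ValueError(f"invalid selectivity for {stratum!r}")

    def retention_curves(self, tl: np.ndarray) -> dict[str, np.ndarray]:
        """Effort-weighted per-stratum retention probabilities at length."""
        if self.selectivity is None:
            return {}
        out = {}
        for stratum, (l50, slope) in self.selectivity.items():
            w = self.fleet_weights.get(stratum, 1.0)
            out[stratum] = w * expit(slope * (np.asarray(tl, dtype=float) - l50))
        return out

    def retention(self, tl: np.ndarray) -> np.ndarray:
        """Overall landed-retention probability (effort-weighted mean)."""
        curves = self.retention_curves(tl)
        if not curves:
            return np.ones_like(np.asarray(tl, dtype=float))
        total_w = sum(
            self.fleet_weights.get(s, 1.0) for s in self.selectivity
        )
        return sum(curves.values()) / total_w

    def otolith_radius_at_length(self, tl: np.ndarray | float) -> np.ndarray:
        """Invert the allometry TL = coef * R^c to core-to-edge radius (mm)."""
        return (np.asarray(tl, dtype=float) / self.oto_coef) ** (
            1.0 / self.abi_exponent_true
        )

    def biological_intercept_radius(self, l_bi: float) -> float:
        """Otolith radius on the allometric law at the intercept length."""
        return float(self.otolith_radius_at_length(l_bi))


def _draw_ages(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Integer ages: truncated geometric with rate Z, or uniform."""
    ages = np.arange(cfg.min_age, cfg.max_age + 1)
    if cfg.age_distribution == "uniform":
        return rng.choice(ages, size=n)
    if cfg.age_distribution != "exponential":
        raise ValueError(f"unknown age_distribution {cfg.age_distribution!r}")
    p = np.exp(-cfg.total_mortality_z * ages)
    return rng.choice(ages, size=n, p=p / p.sum())


def _seasonal_gsi_mean(cfg: SimConfig, months: np.ndarray) -> np.ndarray:
    """Multi-peak seasonal mean GSI: circular Gaussian bumps at peak months."""
    mu = np.full(months.shape, cfg.gsi_base, dtype=float)
    for peak in cfg.gsi_peak_months:
        d = np.abs(months - peak)
        d = np.minimum(d, 12 - d)
        mu += cfg.gsi_amplitude / len(cfg.gsi_peak_months) * np.exp(-0.5 * d**2)
    return mu


def _male_probability(cfg: SimConfig, tl: np.ndarray) -> np.ndarray:
    p_change = expit(cfg.sexchange_slope * (tl - cfg.sexchange_l50))
    return cfg.primary_male_prob + (1.0 - cfg.primary_male_prob) * p_change


def calibrate_sexchange_l50(
    cfg: SimConfig, target_male_fraction: float = 1.0 / 9.0, n_mc: int = 200_000
) -> float:
    """Solve for the sex-change midpoint giving a target overall male fraction.

    Expectation is taken over the landed length distribution implied by
    ``cfg`` (ages, growth, noise, selectivity), estimated by a fixed-seed
    Monte-Carlo draw; root found by bisection. Used once to freeze the
    default ``sexchange_l50``.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(cfg.seed)
    ages = _draw_ages(rng, cfg, n_mc).astype(float)
    ages += rng.uniform(0, 1, n_mc)
    dev = np.clip(rng.normal(0.0, cfg.length_cv, n_mc), -3 * cfg.length_cv, None)
    tl = vbgf(ages, cfg.true_linf, cfg.true_k, cfg.true_t0) * (1.0 + dev)
    tl = tl[tl > 0]
    if cfg.selectivity is not None:
        tl = tl[rng.uniform(size=tl.size) < cfg.retention(tl)]

    def gap(x: float) -> float:
        p = cfg.primary_male_prob + (1 - cfg.primary_male_prob) * expit(
            cfg.sexchange_slope * (tl - x)
        )
        return float(p.mean()) - target_male_fraction

    return float(brentq(gap, 10.0, 200.0))


def simulate_population(
    cfg: SimConfig,
) -> tuple[list[FishRecord], list[OtolithRecord]]:
    """Draw one landed sample: fish records plus two otolith readings each.

    Ring radii at integer ages are back-computed through the single
    allometric length-radius law from each fish's own growth trajectory,
    so the margin tracks months since the annulus window and the
    biological-intercept back-calculation is exact when given the
    generator's exponent.
    """
    if cfg.n_fish < 30:
        warnings.warn("n_fish < 30: downstream estimators will be unstable")
    rng = np.random.default_rng(cfg.seed)

    # Oversample then thin by selectivity until n_fish retained.
    rings = np.empty(0, dtype=int)
    months = np.empty(0, dtype=int)
    dev = np.empty(0)
    for _ in range(200):
        need = cfg.n_fish - rings.size
        if need <= 0:
            break
        m = max(4 * need, 200)
        a_new = _draw_ages(rng, cfg, m)
        mo_new = rng.integers(1, 13, m)
        dv_new = np.clip(
            rng.normal(0.0, cfg.length_cv, m), -3 * cfg.length_cv, None
        )
        frac = ((mo_new - ANNULUS_TIME) % 12) / 12.0
        tl_new = vbgf(a_new + frac, cfg.true_linf, cfg.true_k, cfg.true_t0) * (
            1.0 + dv_new
        )
        ok = tl_new > 1.0
        if cfg.selectivity is not None:
            ok &= rng.uniform(size=m) < cfg.retention(tl_new)
        rings = np.concatenate([rings, a_new[ok]])
        months = np.concatenate([months, mo_new[ok]])
        dev = np.concatenate([dev, dv_new[ok]])
    if rings.size < cfg.n_fish:
        raise RuntimeError("selectivity retained too few fish; check curves")
    rings, months, dev = rings[: cfg.n_fish], months[: cfg.n_fish], dev[: cfg.n_fish]
    n = cfg.n_fish

    frac = ((months - ANNULUS_TIME) % 12) / 12.0
    age = rings + frac
    tl = vbgf(age, cfg.true_linf, cfg.true_k, cfg.true_t0) * (1.0 + dev)

    # stratum by relative (effort-weighted) selectivity, gear by stratum
    if cfg.selectivity is not None and len(cfg.selectivity) > 1:
        names = list(cfg.selectivity)
        curves = cfg.retention_curves(tl)
        weights = np.stack([curves[nm] for nm in names])
        weights = weights / np.clip(weights.sum(axis=0), 1e-300, None)
        u = rng.uniform(size=n)
        idx = (np.cumsum(weights, axis=0) < u).sum(axis=0)
        stratum = np.array(names, dtype=object)[idx]
    elif cfg.selectivity is not None:
        stratum = np.array(list(cfg.selectivity) * n, dtype=object)[:n]
    else:
        stratum = np.array(["inshore", "offshore"], dtype=object)[
            rng.integers(0, 2, n)
        ]
    gear = np.where(
        stratum == "offshore", "spear", np.where(rng.uniform(size=n) < 0.5, "gillnet", "spear")
    )

    # sex (protogynous) and maturity
    male = rng.uniform(size=n) < _male_probability(cfg, tl)
    p_mat = expit(cfg.maturity_slope * (tl - cfg.l50_true))
    mature = np.where(male, True, rng.uniform(size=n) < p_mat)

    # weights and seasonal gonad cycle
    tw = (
        cfg.weight_a
        * tl**cfg.weight_b
        * np.exp(rng.normal(0.0, cfg.weight_cv, n) - cfg.weight_cv**2 / 2)
    )
    gsi_mu = _seasonal_gsi_mean(cfg, months.astype(float))
    sigma = np.sqrt(np.log1p(cfg.gsi_cv**2))
    gsi = gsi_mu * np.exp(rng.normal(0.0, sigma, n) - sigma**2 / 2)
    gsi = np.where(male, 1.0 * np.exp(rng.normal(0.0, sigma, n)), gsi)
    gw = np.where(mature, gsi * tw / (100.0 + gsi), np.nan)

    eviscerated = rng.uniform(size=n) < cfg.eviscerated_fraction
    years = rng.integers(2010, 2014, n)
    days = rng.integers(1, 29, n)

    stage_pool = ["developing", "spawning_capable", "regressing", "regenerating"]
    fish: list[FishRecord] = []
    otoliths: list[OtolithRecord] = []
    for i in range(n):
        fid = f"{cfg.id_prefix}{i + 1:05d}"
        fish.append(
            FishRecord(
                fish_id=fid,
                total_length=round(float(tl[i]), 2),
                total_weight=None if eviscerated[i] else round(float(tw[i]), 2),
                sex="male" if male[i] else "female",
                stage=(
                    stage_pool[rng.integers(0, 4)] if mature[i] else "immature"
                ),
                gonad_weight=(
                    None if np.isnan(gw[i]) else round(float(gw[i]), 4)
                ),
                capture_date=date(int(years[i]), int(months[i]), int(days[i])),
                stratum=str(stratum[i]),
                gear=str(gear[i]),
                eviscerated=bool(eviscerated[i]),
            )
        )

        ring_ages = np.arange(1, rings[i] + 1, dtype=float)
        ring_tl = vbgf(ring_ages, cfg.true_linf, cfg.true_k, cfg.true_t0) * (
            1.0 + dev[i]
        )
        radii = cfg.otolith_radius_at_length(ring_tl)
        edge = float(cfg.otolith_radius_at_length(tl[i]))
        ow = (
            cfg.oto_weight_intercept
            + cfg.oto_weight_slope * float(age[i])
            + (rng.normal(0.0, cfg.oto_weight_sd) if cfg.oto_weight_sd > 0 else 0.0)
        )
        sd_i = cfg.reader_error_sd * rings[i] / cfg.reader_age_ref
        for reading_id in (1, 2):
            otoliths.append(
                OtolithRecord(
                    fish_id=fid,
                    reading_id=reading_id,
                    ring_radii=tuple(_read_radii(rng, radii, edge, sd_i)),
                    otolith_radius=edge,
                    otolith_weight=round(max(ow, 0.01), 4),
                    capture_month=int(months[i]),
                )
            )
    return fish, otoliths


def _read_radii(
    rng: np.random.Generator,
    true_radii: np.ndarray,
    edge: float,
    error_sd: float,
) -> np.ndarray:
    """One reader's ring set: integer count error truncated at +/-3 rings.

    Under-counts drop outermost rings (older rings are closely spaced and
    hardest to resolve); over-counts interpolate spurious rings into the
    marginal zone.
    """
    if error_sd <= 0:
        return true_radii.copy()
    err = int(np.clip(np.rint(rng.normal(0.0, error_sd)), -3, 3))
    n_read = max(len(true_radii) + err, 1)
    if n_read <= len(true_radii):
        return true_radii[:n_read].copy()
    extra = n_read - len(true_radii)
    last = true_radii[-1] if len(true_radii) else 0.0
    fake = last + (edge - last) * np.arange(1, extra + 1) / (extra + 1)
    return np.concatenate([true_radii, fake])


def simulate_two_fleets(
    cfg_inshore: SimConfig, cfg_offshore: SimConfig
) -> tuple[list[FishRecord], list[OtolithRecord]]:
    """Combine an inshore and an offshore fleet into one labelled sample.

    Each config is simulated as a single-stratum fleet (its own growth,
    ages and selectivity); the inshore fleet is typically truncated at
    young ages. Overlapping fish ids raise ``ValueError``.
    """
    cfg_in = replace(
        cfg_inshore,
        selectivity=(
            {"inshore": cfg_inshore.selectivity["inshore"]}
            if cfg_inshore.selectivity and "inshore" in cfg_inshore.selectivity
            else None
        ),
        id_prefix=cfg_inshore.id_prefix if cfg_inshore.id_prefix != "F" else "I",
    )
    cfg_off = replace(
        cfg_offshore,
        selectivity=(
            {"offshore": cfg_offshore.selectivity["offshore"]}
            if cfg_offshore.selectivity and "offshore" in cfg_offshore.selectivity
            else None
        ),
        id_prefix=cfg_offshore.id_prefix if cfg_offshore.id_prefix != "F" else "O",
    )
    fish_in, oto_in = simulate_population(cfg_in)
    fish_off, oto_off = simulate_population(cfg_off)
    for r in fish_in:
        r.stratum = "inshore"
        r.gear = r.gear or "gillnet"
    for r in fish_off:
        r.stratum = "offshore"
        r.gear = "spear"
    ids_in = {r.fish_id for r in fish_in}
    if ids_in & {r.fish_id for r in fish_off}:
        raise ValueError("overlapping fish_ids between fleets")
    return fish_in + fish_off, oto_in + oto_off


def decimal_ages_from_readings(
    otoliths: Sequence[OtolithRecord],
    reading_used: str = "2",
    annulus_time: float = ANNULUS_TIME,
) -> dict[str, float]:
    """Ring count plus the fraction of a year since the annulus window.

    Standard decimal-age assignment: a fish captured ``m`` months after
    the annulus completes carries age ``rings + m/12``. Fish without a
    capture month fall back to the integer ring count.
    """
    ages = ages_from_readings(otoliths, reading_used)
    month = {o.fish_id: o.capture_month for o in otoliths}
    out = {}
    for fid, a in ages.items():
        m = month.get(fid)
        frac = ((m - annulus_time) % 12) / 12.0 if m is not None else 0.0
        out[fid] = a + frac
    return out


def ages_from_readings(
    otoliths: Sequence[OtolithRecord], reading_used: str = "2"
) -> dict[str, float]:
    """Per-fish age (ring count) from reading 1, 2 or the rounded mean."""
    by_fish: dict[str, dict[int, int]] = {}
    for o in otoliths:
        by_fish.setdefault(o.fish_id, {})[o.reading_id] = o.ring_count
    out: dict[str, float] = {}
    for fid, reads in by_fish.items():
        if reading_used == "mean":
            out[fid] = float(np.rint(np.mean(list(reads.values()))))
        else:
            want = int(reading_used)
            if want in reads:
                out[fid] = float(reads[want])
    return out
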
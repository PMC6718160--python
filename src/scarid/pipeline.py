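"""End-to-end orchestration: simulate/load -> reproduction -> ageing ->
growth -> demography, with per-stage tables, a consolidated JSON result
and a plain-text summary written into one run directory.

All randomness flows from a single root seed split per stage, so a rerun
with the same config and seed reproduces every output exactly
(timestamps excluded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scarid import io_core
from scarid.io_core import AnalysisConfig, FishRecord, OtolithRecord
from scarid import ageing, demography, growth, reproduction
from scarid.synthetic_data import (
    SimConfig,
    ages_from_readings,
    decimal_ages_from_readings,
    simulate_population,
)

logger = logging.getLogger("scarid")

STAGES = ("reproduction", "ageing", "growth", "demography")


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the root seed."""
    import zlib

    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def _build_configs(raw: dict, seed: int | None) -> tuple[AnalysisConfig, SimConfig, dict]:
    ana_keys = {f for f in AnalysisConfig.__dataclass_fields__}
    sim_keys = {f for f in SimConfig.__dataclass_fields__}
    ana_raw = {k: v for k, v in raw.get("analysis", {}).items() if k in ana_keys}
    sim_raw = {k: v for k, v in raw.get("simulate", {}).items() if k in sim_keys}
    if "m_coefficients" in ana_raw:
        ana_raw["m_coefficients"] = tuple(ana_raw["m_coefficients"])
    if seed is not None:
        ana_raw["seed"] = seed
        sim_raw["seed"] = seed
    ana = AnalysisConfig(**ana_raw)
    sim = SimConfig(**sim_raw)
    meta = {k: v for k, v in raw.items() if k not in ("analysis", "simulate")}
    return ana, sim, meta


def run_pipeline(
    config_path: str | Path | None = None,
    outdir: str | Path = "scarid_run",
    seed: int | None = None,
    simulate: bool | None = None,
) -> dict:
    """Run every stage and write tables, JSON result and text summary.

    A stage failure marks that stage and its dependents skipped (with the
    reason recorded); independent earlier stages still produce output.
    Returns the consolidated result dictionary.
    """
    raw = load_config(config_path) if config_path else {}
    ana, sim, meta = _build_configs(raw, seed)
    do_simulate = meta.get("simulate_data", True) if simulate is None else simulate
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result: dict = {
        "provenance": {
            "seed": int(ana.seed),
            "config": {
                "analysis": asdict(ana),
                "simulate": asdict(sim) if do_simulate else None,
            },
            "version": __import__("scarid").__version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "stages": {},
    }

    # ------------------------------------------------------------- inputs
    # Two samples mirror the field design: the landing sample (catch-at-age
    # composition, gear selectivity) feeds reproduction, mortality and the
    # length-based indicators; a length-stratified ageing subsample with
    # every age class represented feeds reader QC, periodicity and growth.
    if do_simulate:
        sim = replace(sim, seed=_stage_seed(ana.seed, "simulate"))
        fish, otoliths = simulate_population(sim)
        sim_ageing = replace(
            sim,
            n_fish=int(meta.get("n_ageing", 401)),
            age_distribution="uniform",
            selectivity=None,
            id_prefix="A",
            seed=_stage_seed(ana.seed, "simulate_ageing"),
        )
        fish_ageing, oto_ageing = simulate_population(sim_ageing)
        io_core.write_fish_table(fish, outdir / "fish.csv")
        io_core.write_otolith_table(otoliths, outdir / "otoliths.csv")
        io_core.write_fish_table(fish_ageing, outdir / "fish_ageing.csv")
        io_core.write_otolith_table(oto_ageing, outdir / "otoliths_ageing.csv")
    else:
        fish_path = meta.get("fish_table")
        oto_path = meta.get("otolith_table")
        fish = io_core.read_fish_table(fish_path) if fish_path else []
        otoliths = io_core.read_otolith_table(oto_path) if oto_path else []
        fish_ageing, oto_ageing = fish, otoliths

    # impute eviscerated weights when possible
    try:
        lw = io_core.fit_length_weight(fish, model=meta.get("length_weight_model", "linear"))
        io_core.impute_eviscerated_weights(fish, lw)
        result["length_weight"] = asdict(lw)
    except ValueError as exc:
        result["length_weight"] = {"skipped": str(exc)}

    # -------------------------------------------------------- reproduction
    try:
        result["stages"]["reproduction"] = _run_reproduction(fish, ana, outdir)
    except Exception as exc:  # failure recorded, later stages independent
        logger.exception("reproduction stage failed")
        result["stages"]["reproduction"] = {"skipped": f"failed: {exc}"}

    # ------------------------------------------------------------- ageing
    ages_by_fish: dict[str, float] = {}
    try:
        stage, ages_by_fish = _run_ageing(fish_ageing, oto_ageing, ana, outdir)
        result["stages"]["ageing"] = stage
    except Exception as exc:
        logger.exception("ageing stage failed")
        result["stages"]["ageing"] = {"skipped": f"failed: {exc}"}

    # ------------------------------------------------------------- growth
    growth_out = None
    if not ages_by_fish:
        result["stages"]["growth"] = {"skipped": "no ages available from ageing stage"}
    else:
        try:
            growth_out = _run_growth(fish_ageing, oto_ageing, ages_by_fish, ana, outdir)
            result["stages"]["growth"] = growth_out
        except Exception as exc:
            logger.exception("growth stage failed")
            result["stages"]["growth"] = {"skipped": f"failed: {exc}"}

    # --------------------------------------------------------- demography
    if growth_out is None or not ages_by_fish:
        result["stages"]["demography"] = {"skipped": "growth stage unavailable"}
    else:
        try:
            landing_ages = ages_from_readings(otoliths, ana.reading_used)
            result["stages"]["demography"] = _run_demography(
                fish,
                fish_ageing,
                landing_ages,
                ages_by_fish,
                result,
                ana,
                outdir,
            )
        except Exception as exc:
            logger.exception("demography stage failed")
            result["stages"]["demography"] = {"skipped": f"failed: {exc}"}

    with open(outdir / "result.json", "w", encoding="utf-8") as fh:
        json.dump(result, fh, indent=2, default=_jsonable)
    write_summary(result, outdir / "summary.txt")
    return result


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (datetime,)):
        return obj.isoformat()
    return str(obj)


def _run_reproduction(fish: list[FishRecord], ana: AnalysisConfig, outdir: Path) -> dict:
    monthly = reproduction.monthly_gsi_summary(fish, sex="female")
    monthly.to_csv(outdir / "gsi_monthly.csv", index=False)
    per_bin, overall = reproduction.sex_ratio_tests(fish, bin_width=ana.length_bin_width)
    per_bin.to_csv(outdir / "sex_ratio_bins.csv", index=False)

    females = [r for r in fish if r.sex == "female" and r.mature is not None]
    out: dict = {"sex_ratio": overall}
    peaks = monthly.dropna(subset=["mean_gsi"]).nlargest(2, "mean_gsi")["month"]
    out["gsi_peak_months"] = [int(m) for m in peaks]
    if females and len({r.mature for r in females}) == 2:
        lengths = [r.total_length for r in females]
        flags = [int(r.mature) for r in females]
        fit = reproduction.fit_l50_bayes(
            lengths, flags, ana, seed=_stage_seed(ana.seed, "l50")
        )
        out["maturity_length"] = asdict(fit)
        grid = np.linspace(min(lengths), max(lengths), 101)
        pd.DataFrame(
            {"length": grid, "proportion_mature": fit.proportion_mature(grid)}
        ).to_csv(outdir / "maturity_ogive_length.csv", index=False)
    else:
        out["maturity_length"] = {"skipped": "need immature and mature females"}
    return out


def _run_ageing(
    fish: list[FishRecord],
    otoliths: list[OtolithRecord],
    ana: AnalysisConfig,
    outdir: Path,
) -> tuple[dict, dict[str, float]]:
    reads = ageing.readings_by_fish(otoliths)
    qc = ageing.ape_cv(reads)
    profiles = ageing.disagreement_profiles(reads)
    profiles.to_csv(outdir / "reader_disagreement.csv", index=False)

    tl_by_fish = {r.fish_id: r.total_length for r in fish}
    monthly, ttests, annulus = ageing.mir_seasonality(
        otoliths,
        lengths_by_fish=tl_by_fish,
        max_length=ana.mir_max_length,
        reading_id=2 if ana.reading_used != "1" else 1,
    )
    monthly.to_csv(outdir / "mir_monthly.csv", index=False)
    ttests.to_csv(outdir / "mir_ttests.csv", index=False)

    ages_by_fish = ages_from_readings(otoliths, ana.reading_used)
    paired = [(ages_by_fish[f], tl_by_fish[f]) for f in ages_by_fish if f in tl_by_fish]
    alk = ageing.age_length_key(
        [p[0] for p in paired], [p[1] for p in paired], ana.length_bin_width
    )
    alk.to_csv(outdir / "age_length_key.csv")

    ow = {
        o.fish_id: o.otolith_weight
        for o in otoliths
        if o.otolith_weight is not None and o.reading_id == 2
    }
    wa_pairs = [(ow[f], ages_by_fish[f]) for f in ow if f in ages_by_fish]
    wfit = ageing.otolith_weight_age_fit(
        [p[0] for p in wa_pairs], [p[1] for p in wa_pairs]
    )
    wfit.pop("residuals", None)
    stage = {
        "ape": qc.ape,
        "cv": qc.cv,
        "n_fish": qc.n_fish,
        "annulus_months": annulus,
        "otolith_weight_age": wfit,
    }
    return stage, ages_by_fish


def _run_growth(
    fish: list[FishRecord],
    otoliths: list[OtolithRecord],
    ages_by_fish: dict[str, float],
    ana: AnalysisConfig,
    outdir: Path,
) -> dict:
    tl = {r.fish_id: r.total_length for r in fish}
    # decimal ages (ring count + months since annulus) for curve fitting
    dec_ages = decimal_ages_from_readings(otoliths, ana.reading_used)
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def subset(pred) -> tuple[np.ndarray, np.ndarray]:
        fids = [r.fish_id for r in fish if pred(r) and r.fish_id in dec_ages]
        return (
            np.array([dec_ages[f] for f in fids]),
            np.array([tl[f] for f in fids]),
        )

    groups["grouped"] = subset(lambda r: True)
    for sex in ("male", "female"):
        groups[sex] = subset(lambda r, s=sex: r.sex == s)
    for stratum in ("inshore", "offshore"):
        groups[stratum] = subset(lambda r, s=stratum: r.stratum == s)

    rows = []
    fits: dict[str, growth.GrowthFit] = {}
    for name, (a, l) in groups.items():
        try:
            fit = growth.fit_vbgf(a, l)
            fits[name] = fit
            rows.append(
                {
                    "group": name,
                    "linf": fit.linf,
                    "se_linf": fit.se_linf,
                    "k": fit.k,
                    "se_k": fit.se_k,
                    "t0": fit.t0,
                    "se_t0": fit.se_t0,
                    "residual_sd": fit.residual_sd,
                    "n": fit.n,
                    "boundary_warning": fit.boundary_warning,
                }
            )
        except (ValueError, RuntimeError) as exc:
            rows.append({"group": name, "skipped": str(exc)})
    pd.DataFrame(rows).to_csv(outdir / "growth_parameters.csv", index=False)

    out: dict = {
        "fits": {
            name: {k: v for k, v in asdict(f).items()} for name, f in fits.items()
        }
    }

    kim_rows = []
    for label, (g1, g2) in {
        "male_vs_female": ("male", "female"),
        "inshore_vs_offshore": ("inshore", "offshore"),
    }.items():
        if g1 in fits and g2 in fits:
            for res in growth.kimura_lrt(groups[g1], groups[g2]):
                kim_rows.append({"comparison": label, **asdict(res)})
    if kim_rows:
        pd.DataFrame(kim_rows).to_csv(outdir / "kimura_tests.csv", index=False)
        out["kimura"] = kim_rows

    # ABI back-calculation using reading 2 radii
    abi_cfg = ana
    lengths_all = [tl[f] for f in ages_by_fish if f in tl]
    reading = 2 if ana.reading_used != "1" else 1
    radii_pairs = [
        (tl[o.fish_id], o.otolith_radius)
        for o in otoliths
        if o.reading_id == reading and o.fish_id in tl
    ]
    if ana.abi_exponent_mode == "estimate" and len(radii_pairs) >= 10:
        est = growth.estimate_abi_exponent(
            [p[0] for p in radii_pairs], [p[1] for p in radii_pairs]
        )
        exponent = est["c"]
        out["abi_exponent"] = est
    else:
        exponent = ana.abi_exponent
        out["abi_exponent"] = {"c": exponent, "mode": "fixed"}
    if abi_cfg.biological_intercept_radius is None:
        # anchor at the smallest sampled fish on the fitted allometry
        lmin = min(lengths_all) if lengths_all else abi_cfg.biological_intercept_length
        coef = np.exp(out["abi_exponent"].get("log_coef", 0.0)) if "log_coef" in out["abi_exponent"] else None
        r_bi = (
            (abi_cfg.biological_intercept_length / coef) ** (1 / exponent)
            if coef
            else min(p[1] for p in radii_pairs) * 0.9
        )
        abi_cfg = replace(abi_cfg, biological_intercept_radius=float(r_bi))
        del lmin
    back_rows = []
    for o in otoliths:
        if o.reading_id != reading or o.fish_id not in tl:
            continue
        try:
            lengths_at_age = growth.back_calculate_abi(
                o, tl[o.fish_id], abi_cfg, exponent=exponent
            )
        except ValueError:
            continue
        for age_i, li in enumerate(lengths_at_age, start=1):
            back_rows.append({"fish_id": o.fish_id, "ring_age": age_i, "length": li})
    if back_rows:
        pd.DataFrame(back_rows).to_csv(outdir / "back_calculated_lengths.csv", index=False)
        out["n_back_calculated"] = len(back_rows)
    return out


def _run_demography(
    fish: list[FishRecord],
    fish_ageing: list[FishRecord],
    landing_ages: dict[str, float],
    ages_by_fish: dict[str, float],
    result: dict,
    ana: AnalysisConfig,
    outdir: Path,
) -> dict:
    growth_stage = result["stages"].get("growth", {})
    fit = growth_stage.get("fits", {}).get("grouped")
    if fit is None:
        raise ValueError("no pooled growth fit")
    repro = result["stages"].get("reproduction", {})
    mat = repro.get("maturity_length", {})
    l50 = mat.get("l50", np.nan)

    # Z from the landing-sample age composition; longevity from every aged
    # fish (the stratified ageing subsample covers the old classes).
    tl = {r.fish_id: r.total_length for r in fish}
    fids = [f for f in landing_ages if f in tl]
    ages = [landing_ages[f] for f in fids]
    longevity = max(
        [*ages, *(ages_by_fish.values())] or [np.nan]
    )

    females = [r for r in fish_ageing if r.sex == "female" and r.mature is not None]
    fem_by_id = {r.fish_id: r for r in females}
    am_pairs = [
        (ages_by_fish[f], int(fem_by_id[f].mature))
        for f in ages_by_fish
        if f in fem_by_id
    ]
    if am_pairs and len({m for _, m in am_pairs}) == 2:
        afit = reproduction.fit_a50([a for a, _ in am_pairs], [m for _, m in am_pairs])
        a50 = afit.a50
        ogive = afit.ogive(np.arange(0, int(longevity) + 1))
        ogive.to_csv(outdir / "maturity_ogive_age.csv", index=False)
        age_maturity = {k: (None if v is None else float(v)) for k, v in asdict(afit).items()}
    else:
        a50 = float(np.nan)
        age_maturity = {"skipped": "need immature and mature aged females"}

    if not np.isfinite(l50):
        raise ValueError("no L50 available from the reproduction stage")
    if not np.isfinite(a50):
        raise ValueError("no A50 available")

    report = demography.demography_report(
        ages,
        [r.total_length for r in fish],
        linf=fit["linf"],
        k=fit["k"],
        l50=l50,
        a50=a50,
        m_coefficients=ana.m_coefficients,
        z_method=ana.z_method,
        longevity=longevity,
    )
    gear_groups = [
        f"{r.stratum or 'unknown'}_{r.gear or 'unknown'}" for r in fish
    ]
    table = demography.froese_table(
        [r.total_length for r in fish], gear_groups, l50, report.lopt
    )
    table.to_csv(outdir / "froese_indicators.csv", index=False)
    return {"age_maturity": age_maturity, "report": report.to_dict()}


def write_summary(result: dict, path: str | Path) -> None:
    """Plain-text one-page summary of the run's headline quantities."""
    lines = ["run summary", "===========", ""]
    stages = result.get("stages", {})
    repro = stages.get("reproduction", {})
    if "sex_ratio" in repro:
        sr = repro["sex_ratio"]
        lines.append(
            f"sex ratio (male:female)   {sr['ratio_string']}"
            f"  ({sr['males']} male / {sr['females']} female)"
        )
    mat = repro.get("maturity_length", {})
    if "l50" in mat:
        lines.append(
            f"L50 (posterior mean)      {mat['l50']:.1f} cm"
            f"  [{mat['ci_low']:.1f}, {mat['ci_high']:.1f}]"
        )
    age = stages.get("ageing", {})
    if "ape" in age:
        lines.append(f"APE / CV                  {age['ape']:.2f}% / {age['cv']:.2f}%")
        if age.get("annulus_months"):
            lines.append(f"annulus window (months)   {age['annulus_months']}")
    gr = stages.get("growth", {})
    if "fits" in gr and "grouped" in gr["fits"]:
        f = gr["fits"]["grouped"]
        lines.append(
            f"VBGF (pooled)             Linf={f['linf']:.2f} cm"
            f"  K={f['k']:.3f}/yr  t0={f['t0']:.2f} yr"
        )
    dem = stages.get("demography", {})
    if "report" in dem:
        r = dem["report"]
        lines.append(
            f"M / Z / F                 {r['m']:.3f} / {r['z']:.3f} / {r['f']:.3f} per yr"
        )
        lines.append(f"survival S = e^-Z         {r['s']:.3f}")
        lines.append(f"generation time           {r['gt']:.1f} yr")
        lines.append(
            f"Lopt                      {r['lopt']:.1f} cm"
            f"  (mature {r['pct_mature']:.1f}%, opt {r['pct_opt']:.1f}%,"
            f" mega-spawners {r['pct_mega']:.1f}%)"
        )
        lines.append(
            f"F/FMSY                    {r['f_over_fmsy']:.2f}"
            f"  ({'overfishing' if r['overfishing'] else 'within limits'})"
        )
    for name in STAGES:
        st = stages.get(name, {})
        if "skipped" in st:
            lines.append(f"{name}: skipped ({st['skipped']})")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
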
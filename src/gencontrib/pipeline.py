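"""End-to-end analysis pipeline: genealogy -> presence -> IGC ->
stabilization -> fitness proxies -> hierarchical models -> report.

Each stage writes plain CSV/JSON artifacts into the run directory plus a
manifest entry (inputs hash, config, seed, package version), so any stage
can be inspected or re-used; rerunning a completed stage with unchanged
inputs is a no-op.  The stabilization scan walks birth decades in order and
stops at the first non-stabilized cohort, which is all that is needed to
locate the per-parish cutoff; individuals born before the cutoff form the
focal set for the proxy models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .igc import (
    cohort_stabilization,
    expected_contribution_vector,
    generation_time,
    igc_series_from_intervals,
    igc_wide_frame,
)
from .migration import (
    build_presence,
    classify_migration,
    migration_rates,
    presence_intervals,
)
from .pedigree import (
    load_genealogy,
    pedigree_summary,
    pedigree_table_from_frame,
    write_genealogy,
)
from .proxies import (
    adulthood_threshold,
    compute_proxies,
    extinction_stages,
    lineage_fates,
    offspring_mean_igc,
)
from .simulate import SimConfig, simulate_population
from .zib import (
    MCMCSettings,
    ModelSpec,
    bayes_r2,
    fit_model,
    interaction_pruning,
    prob_direction,
    r2_difference,
)

logger = logging.getLogger("gencontrib")

PROXIES = ("lifespan", "lrs", "lrs_sa", "grandoffspring")


@dataclass
class PipelineConfig:
    """Every stated constant of the analysis in one place."""

    input_path: str | None = None          # genealogy CSV; None -> simulate
    out_dir: str = "runs/run"
    parishes: tuple[str, ...] = ("ParishA", "ParishB")
    final_year: int = 1990
    cohort_width: int = 10
    stabilization_threshold: float = 0.95
    window_generations: float = 2.0
    adulthood_percentile: float = 5.0
    percentile_method: str = "linear"
    censor_horizon: int = 0
    year_range: tuple[int, int] | None = None   # default: data span to final_year
    models: tuple[str, ...] = PROXIES + ("null", "bias")
    interaction_policy: str = "prune"      # "prune" or "never"
    mcmc_profile: str = "fast"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.pop("sim", {}).items()})
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(sim=sim, **raw)

    def mcmc_settings(self) -> MCMCSettings:
        return MCMCSettings.full() if self.mcmc_profile == "full" else MCMCSettings.fast()


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data = (
            json.loads(self.path.read_text()) if self.path.exists()
            else {"version": __version__, "stages": {}}
        )

    def fresh(self, stage: str, inputs_hash: str, outputs: list[Path]) -> bool:
        entry = self.data["stages"].get(stage)
        return bool(
            entry
            and entry.get("inputs_hash") == inputs_hash
            and all(p.exists() for p in outputs)
        )

    def record(self, stage: str, inputs_hash: str, outputs: list[Path],
               **extra) -> None:
        self.data["stages"][stage] = {
            "inputs_hash": inputs_hash,
            "outputs": [str(p) for p in outputs],
            **extra,
        }
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


@dataclass
class PipelineResult:
    out_dir: Path
    genealogy: pd.DataFrame
    summary: dict
    rates: dict
    generation_times: dict
    stabilization: dict          # parish -> StabilizationReport
    cutoffs: dict                # parish -> cutoff birth year (exclusive)
    proxies: pd.DataFrame
    fates: dict
    fits: dict                   # model label -> PosteriorFit
    r2: dict
    report: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir)
    cfg_hash = _hash_obj(dataclasses.asdict(config))

    # -- stage 1: genealogy ---------------------------------------------------
    gen_path = out_dir / "genealogy.csv"
    if config.input_path is not None:
        ped = load_genealogy(config.input_path)
        parishes = tuple(config.parishes)
        if not manifest.fresh("genealogy", cfg_hash, [gen_path]):
            write_genealogy(ped, gen_path)   # normalized copy of the input
            manifest.record("genealogy", cfg_hash, [gen_path])
    else:
        if not manifest.fresh("genealogy", cfg_hash, [gen_path]):
            df = simulate_population(config.sim, seed=config.seed)
            write_genealogy(pedigree_table_from_frame(df), gen_path)
            manifest.record("genealogy", cfg_hash, [gen_path], seed=config.seed)
        ped = pedigree_table_from_frame(pd.read_csv(gen_path, dtype={
            "id": str, "sire": str, "dam": str}))
        parishes = tuple(config.sim.parishes)
    summary = pedigree_summary(ped)
    (out_dir / "pedigree_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2))
    manifest.record("pedigree_summary", cfg_hash,
                    [out_dir / "pedigree_summary.json"])

    # -- stage 2: presence & migration ---------------------------------------
    statuses = classify_migration(ped, parishes)
    rates = migration_rates(statuses)
    (out_dir / "migration_rates.json").write_text(json.dumps(rates, indent=2))
    birth_years = [r.birth_year for r in ped if r.birth_year is not None]
    year_range = config.year_range or (min(birth_years), config.final_year)
    presence = {}
    intervals = {}
    for parish in parishes:
        intervals[parish] = presence_intervals(
            ped, statuses, parish, year_range, config.censor_horizon)
        presence[parish] = build_presence(
            ped, statuses, parish, year_range, config.censor_horizon)
        presence[parish].pop_size_frame().to_csv(
            out_dir / f"popsize_{parish}.csv", index=False)
    manifest.record("presence", cfg_hash,
                    [out_dir / f"popsize_{p}.csv" for p in parishes])

    # -- stage 3: IGC + stabilization scan ------------------------------------
    gen_times = {}
    reports = {}
    cutoffs = {}
    igc_all = {}
    for parish in parishes:
        gt, gt_se = generation_time(ped, parish, statuses)
        gen_times[parish] = {"mean": gt, "se": gt_se}
        pop = presence[parish].pop_size
        ivs = intervals[parish]
        # walk decades in order; stop at the first non-stabilized cohort
        by_decade: dict[int, list[str]] = {}
        for ind, st in statuses.items():
            if st.home_parish != parish:
                continue
            by = ped[ind].birth_year
            if by is None:
                continue
            dec = (by // config.cohort_width) * config.cohort_width
            by_decade.setdefault(dec, []).append(ind)
        series_here = {}
        scan_report = None
        for dec in sorted(by_decade):
            for ind in by_decade[dec]:
                st = statuses[ind]
                start = st.arrival_year or ped[ind].birth_year
                vec = expected_contribution_vector(ped, ind)
                series_here[ind] = igc_series_from_intervals(
                    vec, ivs, pop, parish, start, config.final_year)
            scan_report = cohort_stabilization(
                series_here, ped, parish, gt,
                cohort_width=config.cohort_width,
                final_year=config.final_year,
                threshold=config.stabilization_threshold,
                window_generations=config.window_generations,
            )
            this = [r for r in scan_report.cohorts if r.cohort_start == dec]
            if this and not this[0].stabilized:
                break
        reports[parish] = scan_report
        cutoffs[parish] = scan_report.cutoff_birth_year if scan_report else None
        igc_all.update(series_here)
        if scan_report is not None:
            scan_report.to_frame().to_csv(
                out_dir / f"stabilization_{parish}.csv", index=False)
    (out_dir / "stabilization.json").write_text(json.dumps(
        {
            "generation_times": gen_times,
            "cutoff_birth_year": cutoffs,
            "threshold": config.stabilization_threshold,
            "window_generations": config.window_generations,
        },
        indent=2,
    ))
    manifest.record("stabilization", cfg_hash, [out_dir / "stabilization.json"])

    # stabilized focal set: born before the parish cutoff
    focals = {}
    for parish in parishes:
        cut = cutoffs[parish]
        if cut is None:
            continue
        for ind, s in igc_all.items():
            if s.parish == parish and ped[ind].birth_year is not None \
                    and ped[ind].birth_year < cut:
                focals[ind] = s
    igc_wide_frame(focals).to_csv(out_dir / "igc_stabilized.csv")

    # -- stage 4: proxies ------------------------------------------------------
    thresholds = adulthood_threshold(
        ped, percentile=config.adulthood_percentile,
        method=config.percentile_method)
    # offspring of stabilized focals need their own final-year IGC (bias test)
    offspring_ids = {
        c for f in focals for c in ped.child_index.get(f, ())
    } - set(focals)
    igc_with_offspring = dict(focals)
    for child in offspring_ids:
        st = statuses.get(child)
        parish = st.home_parish if st else None
        if parish not in parishes:
            continue
        start = (st.arrival_year if st else None) or ped[child].birth_year
        if start is None:
            continue
        vec = expected_contribution_vector(ped, child)
        igc_with_offspring[child] = igc_series_from_intervals(
            vec, intervals[parish], presence[parish].pop_size, parish,
            start, config.final_year)
    prox = compute_proxies(ped, thresholds, focals, statuses,
                           cohort_width=config.cohort_width)
    mean_off = offspring_mean_igc(ped, igc_with_offspring, list(focals))
    prox = prox.merge(mean_off.rename("mean_offspring_igc"), how="left",
                      left_on="id", right_index=True)
    prox.to_csv(out_dir / "proxies.csv", index=False)
    fates = lineage_fates(ped, statuses, focals, list(focals), config.final_year)
    fates_df = pd.DataFrame([f.__dict__ for f in fates])
    fates_df.to_csv(out_dir / "lineage_fates.csv", index=False)
    stages = extinction_stages(prox, thresholds)
    fate_summary = {
        "adulthood_threshold": dataclasses.asdict(thresholds),
        "n_focals": len(prox),
        "pct_extinct": float(100.0 * (prox["igc"] == 0).mean()) if len(prox) else None,
        "median_pct_descendants_reproduced": _nanmedian(
            fates_df, "pct_descendants_reproduced"),
        "median_pct_descendants_alive_unreproduced": _nanmedian(
            fates_df, "pct_descendants_alive_unreproduced"),
        "median_pct_failed": _nanmedian(fates_df, "pct_failed"),
        "median_pct_failed_by_emigration": _nanmedian(
            fates_df, "pct_failed_by_emigration"),
        "extinction_stages": stages,
    }
    (out_dir / "extinction_report.json").write_text(
        json.dumps(fate_summary, indent=2))
    manifest.record("proxies", cfg_hash, [out_dir / "proxies.csv"])

    # -- stage 5: models -------------------------------------------------------
    mcmc = config.mcmc_settings()
    if prox.empty:
        model_data = prox.copy()
    else:
        model_data = prox[prox["eligible_model"]].dropna(
            subset=["igc", "lifespan", "lrs", "lrs_sa", "grandoffspring"]).copy()
    fits = {}
    summaries = []
    seed_base = config.seed * 1000 + 7
    if len(model_data) < 50:
        logger.warning(
            "only %d model-eligible rows; regression stage skipped "
            "(no stabilized cohorts?)", len(model_data))
    to_fit = [m for m in config.models if m != "bias"] \
        if len(model_data) >= 50 else []
    for k, name in enumerate(to_fit):
        proxy = None if name == "null" else name
        spec = ModelSpec(response="igc", proxy=proxy, zero_inflated=True)
        if (
            config.interaction_policy == "prune"
            and proxy is not None
            and model_data["parish"].nunique() > 1
            and model_data["sex"].nunique() > 1
        ):
            spec, fit = interaction_pruning(model_data, spec, mcmc,
                                            seed=seed_base + k)
        else:
            fit = fit_model(model_data, spec, mcmc, seed=seed_base + k)
        fits[name] = fit
        s = fit.summary()
        s.insert(0, "model", name)
        summaries.append(s)
    if "bias" in config.models and len(model_data) >= 50:
        bias_data = model_data[(model_data["lrs"] > 0)
                               & model_data["mean_offspring_igc"].notna()].copy()
        bias_spec = ModelSpec(
            response="mean_offspring_igc", proxy="lrs", zero_inflated=False,
            extra_covariates=("lifespan",), response_offset=1e-10)
        if len(bias_data) >= 50:
            fit = fit_model(bias_data, bias_spec, mcmc, seed=seed_base + 99)
            fits["bias"] = fit
            s = fit.summary()
            s.insert(0, "model", "bias")
            summaries.append(s)
        else:
            logger.warning("bias model skipped: only %d reproducers", len(bias_data))
    summary_df = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    summary_df.to_csv(out_dir / "posterior_summaries.csv", index=False)
    for name, fit in fits.items():
        # one column per parameter, one row per posterior draw
        pd.DataFrame(fit.draws, columns=fit.param_names).to_csv(
            out_dir / f"draws_{name}.csv.gz", index=False, compression="gzip")
    manifest.record("models", cfg_hash, [out_dir / "posterior_summaries.csv"],
                    n=int(len(model_data)))

    # -- stage 6: report -------------------------------------------------------
    r2 = {}
    for name, fit in fits.items():
        if name == "bias":
            continue
        post = bayes_r2(fit)
        r2[name] = {"median": post.median, "mode": post.mode,
                    "ci": list(post.ci)}
    delta = {}
    fitted = [m for m in config.models if m in fits and m not in ("bias",)]
    for a in fitted:
        for b in fitted:
            if a < b:
                delta[f"{a}_vs_{b}"] = r2_difference(fits[a], fits[b])
    report = {
        "n_model": int(len(model_data)),
        "n_bias": int(fits["bias"].data_n) if "bias" in fits else 0,
        "r2": r2,
        "delta_r2": delta,
        "proxy_slopes": {},
        "cutoffs": cutoffs,
        "generation_times": gen_times,
    }
    for name, fit in fits.items():
        if name == "null":
            continue
        pname = "b_lrs" if name == "bias" else f"b_{name}"
        if pname in fit.param_names:
            d = fit.draws_of(pname)
            p, cls = prob_direction(d)
            report["proxy_slopes"][name] = {
                "median": float(np.median(d)), "pd": p, "class": cls,
            }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    manifest.record("report", cfg_hash, [out_dir / "report.json"])

    return PipelineResult(
        out_dir=out_dir, genealogy=ped.to_frame(), summary=summary.to_dict(),
        rates=rates, generation_times=gen_times, stabilization=reports,
        cutoffs=cutoffs, proxies=prox, fates=fate_summary, fits=fits, r2=r2,
        report=report,
    )


def _nanmedian(df: pd.DataFrame, col: str) -> float | None:
    if df.empty or col not in df:
        return None
    vals = df[col].dropna()
    return float(vals.median()) if len(vals) else None
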
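"""End-to-end pipeline: simulate -> fit-growth -> fit-tpc -> diversity -> stats.

A :class:`RunConfig` (typically loaded from a YAML file) names the input
and output paths and the knobs of each stage.  ``run_pipeline`` executes the
stages in order, writes every artifact as CSV/JSON, and records a manifest
(config hash, seed, package version, per-stage record counts) so a run is
reproducible from its output directory alone.  One global seed drives
deterministic per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import community_stats as cs
from . import diversity as dv
from . import growth_fitting as gf
from . import io as tio
from . import synthetic_data as sd
from . import thermal_traits as tt

logger = logging.getLogger(__name__)

_STAGE_STREAMS = {"simulate": 0, "growth": 1, "tpc": 2, "stats": 3}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) derived from the run seed."""
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(_STAGE_STREAMS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    outdir: str = "run"
    seed: int = 0
    n_starts: int = 1000           # TPC restarts
    n_starts_logistic: int = 50    # logistic restarts per well
    tref_c: float = tt.DEFAULT_TREF_C
    min_prevalence: float = 0.25
    n_perm: int = 999
    permanova_continuous: bool = False
    # input paths; filled by the simulate stage when simulation is requested
    plate_csv: str | None = None
    counts_csv: str | None = None
    biomass_csv: str | None = None
    simulate: sd.SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = sd.SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            return obj

        return plain(dataclasses.asdict(self))

    def validate(self) -> None:
        if not (0.0 <= self.min_prevalence <= 1.0):
            raise ConfigError("min_prevalence must lie in [0, 1]")
        if self.n_perm < 1 or self.n_starts < 1 or self.n_starts_logistic < 1:
            raise ConfigError("counts must be >= 1")
        if self.simulate is None:
            if self.plate_csv is None:
                raise ConfigError("plate_csv required when not simulating")
            if self.counts_csv is None:
                raise ConfigError("counts_csv required when not simulating")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _model_choice_dict(mc: cs.ModelChoice) -> dict:
    return {
        "chosen": mc.chosen, "coefficients": mc.coefficients,
        "r2": mc.r2, "f_stat": mc.f_stat, "n": mc.n,
        "lrt": [{"comparison": c, "statistic": s, "df": d, "p": p}
                for c, s, d, p in mc.lrt_stats],
    }


def run_stats(
    diversity_df: pd.DataFrame,
    abund_df: pd.DataFrame,
    traits_df: pd.DataFrame | None,
    biomass_df: pd.DataFrame | None,
    n_perm: int = 999,
    seed: int = 0,
    permanova_continuous: bool = False,
) -> dict:
    """The inferential layer on prepared diversity/abundance/trait tables."""
    report: dict = {}
    rng = np.random.default_rng(seed)

    report["richness_vs_temp"] = _model_choice_dict(cs.polynomial_lrt(
        diversity_df["temp_c"], diversity_df["richness"]))
    even = diversity_df.dropna(subset=["pielou_j"])
    report["evenness_vs_temp"] = _model_choice_dict(cs.polynomial_lrt(
        even["temp_c"], even["pielou_j"]))
    report["n_evenness_undefined"] = int(diversity_df["pielou_j"].isna().sum())

    # composition: PCA + PERMANOVA on Bray-Curtis
    wide = abund_df.pivot_table(index=["temp_c", "replicate"], columns="taxon",
                                values="rel_abund", fill_value=0.0)
    meta = wide.index.to_frame(index=False)
    mat = wide.to_numpy()
    pca = cs.pca_composition(mat)
    report["pca"] = {
        "var_explained": pca.var_explained[:4],
        "n_components": int(pca.var_explained.size),
    }
    dist = cs.bray_curtis(mat)
    groups = meta["temp_c"].to_numpy()
    perm = cs.permanova(dist, groups, n_perm=n_perm, seed=rng,
                        continuous=permanova_continuous)
    pw = cs.pairwise_permanova(dist, groups, n_perm=n_perm, seed=rng)
    report["permanova"] = {
        "pseudo_f": perm.pseudo_f, "df": perm.df, "p": perm.p_perm,
        "n_perm": perm.n_perm, "continuous": permanova_continuous,
        "pairwise": pw.to_dict(orient="records"),
    }

    # trait-abundance ANCOVAs
    if traits_df is not None and len(traits_df):
        merged = abund_df.merge(traits_df[["taxon", "topt_c"]], on="taxon",
                                how="inner")
        if merged["temp_c"].nunique() >= 2:
            res = cs.ancova_trait_abundance(
                merged["rel_abund"], merged["topt_c"], merged["temp_c"])
            report["ancova_topt"] = {
                "overall_f": res.overall_f, "r2": res.r2, "n": res.n,
                "slopes": {str(k): v for k, v in res.per_level_slopes.items()},
                "pairwise_p": {f"{a}-{b}": p for (a, b), p
                               in res.pairwise_contrasts.items()},
            }
        fits = {row["taxon"]: row for _, row in traits_df.iterrows()}
        r_at_t = abund_df.apply(
            lambda rec: float(np.exp(tt.sharpe_schoolfield_ln_rate(
                rec["temp_c"], fits[rec["taxon"]]["ea_ev"],
                fits[rec["taxon"]]["eh_ev"], fits[rec["taxon"]]["th_k"],
                fits[rec["taxon"]]["ln_r_tc"])))
            if rec["taxon"] in fits else np.nan, axis=1)
        mask = r_at_t.notna()
        if mask.sum() and abund_df.loc[mask, "temp_c"].nunique() >= 2:
            res = cs.ancova_trait_abundance(
                abund_df.loc[mask, "rel_abund"], r_at_t[mask],
                abund_df.loc[mask, "temp_c"])
            report["ancova_rate"] = {
                "overall_f": res.overall_f, "r2": res.r2, "n": res.n,
                "slopes": {str(k): v for k, v in res.per_level_slopes.items()},
                "pairwise_p": {f"{a}-{b}": p for (a, b), p
                               in res.pairwise_contrasts.items()},
            }

    # ecosystem-function regressions
    if biomass_df is not None and len(biomass_df):
        merged = diversity_df.merge(biomass_df, on=["temp_c", "replicate"],
                                    how="inner")
        fr = cs.function_regressions(
            merged["temp_c"], merged["pielou_j"], merged["biomass_od"])
        report["function"] = {k: _model_choice_dict(v) for k, v in fr.items()}
    return _jsonable(report)


def _summary_text(report: dict) -> str:
    lines = ["thermotrait stats summary", "=" * 30]
    for key in ("richness_vs_temp", "evenness_vs_temp"):
        if key in report:
            mc = report[key]
            lines.append(f"{key}: chosen={mc['chosen']} r2={mc['r2']:.3f}")
    if "permanova" in report:
        p = report["permanova"]
        lines.append(
            f"permanova: F={p['pseudo_f']:.2f} df={tuple(p['df'])} "
            f"p={p['p']:.4g} ({p['n_perm']} permutations)")
    for key in ("ancova_topt", "ancova_rate"):
        if key in report:
            f, df1, df2, p = report[key]["overall_f"]
            lines.append(f"{key}: F_{{{df1},{df2}}}={f:.2f} "
                         f"r2={report[key]['r2']:.2f} p={p:.3g}")
    if "function" in report:
        for name, mc in report["function"].items():
            lines.append(f"{name}: chosen={mc['chosen']} r2={mc['r2']:.3f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all pipeline stages; return the manifest dict.

    Stage errors propagate as exceptions carrying the stage name in their
    message (the CLI converts them to a non-zero exit status).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "config_sha256": _config_hash(config), "stages": {},
    }

    # --- simulate -----------------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate,
                                  seed=stage_seed(config.seed, "simulate"))
        params = sd.gen_taxon_params(sim)
        plate = sd.gen_growth_plate(params, sim)
        counts = sd.gen_community_counts(params, sim)
        biomass = sd.gen_community_biomass(params, sim)
        config.plate_csv = str(outdir / "plate.csv")
        config.counts_csv = str(outdir / "counts.csv")
        config.biomass_csv = str(outdir / "biomass.csv")
        tio.write_csv(plate, config.plate_csv)
        tio.write_csv(counts, config.counts_csv)
        tio.write_csv(biomass, config.biomass_csv)
        truth = pd.DataFrame([{
            "taxon": p.taxon_id, "ea_ev": p.ea_ev, "eh_ev": p.eh_ev,
            "th_k": p.th_k, "ln_r_tc": p.ln_r_tc, "topt_c": p.topt_c,
        } for p in params])
        tio.write_csv(truth, outdir / "true_params.csv")
        manifest["stages"]["simulate"] = {
            "n_taxa": len(params), "plate_records": len(plate),
            "count_records": len(counts),
        }
        logger.info("simulate: %d plate records, %d count records",
                    len(plate), len(counts))

    # --- fit-growth ---------------------------------------------------------
    plate = tio.read_plate_csv(config.plate_csv)
    corrected = gf.blank_correct(plate)
    rates = gf.growth_rate_table(corrected,
                                 n_starts=config.n_starts_logistic,
                                 seed=stage_seed(config.seed, "growth"))
    rates_path = outdir / "growth_rates.csv"
    tio.write_csv(rates, rates_path)
    manifest["stages"]["fit_growth"] = {
        "n_series": int(plate[~plate["is_blank"]]
                        .groupby(["taxon", "temp_c", "replicate"]).ngroups),
        "n_groups": len(rates),
        "n_missing": int(rates["mean_r_per_h"].isna().sum()),
    }

    # --- fit-tpc ------------------------------------------------------------
    _, traits = tt.fit_tpc_table(rates, n_starts=config.n_starts,
                                 seed=stage_seed(config.seed, "tpc"),
                                 tref_c=config.tref_c)
    traits_path = outdir / "thermal_traits.csv"
    tio.write_csv(traits, traits_path)
    manifest["stages"]["fit_tpc"] = {"n_taxa_fitted": len(traits)}

    # --- diversity ----------------------------------------------------------
    counts = tio.read_counts_csv(config.counts_csv)
    filtered = dv.filter_rare(counts, config.min_prevalence)
    diversity_df = dv.diversity_table(filtered)
    abund_df = dv.abundance_long(filtered)
    tio.write_csv(diversity_df, outdir / "diversity.csv")
    tio.write_csv(abund_df, outdir / "rel_abundance.csv")
    manifest["stages"]["diversity"] = {
        "n_communities": len(diversity_df),
        "n_taxa_records_removed": int(len(counts) - len(filtered)),
        "n_evenness_undefined": int(diversity_df["pielou_j"].isna().sum()),
    }

    # --- stats --------------------------------------------------------------
    biomass_df = (tio.read_biomass_csv(config.biomass_csv)
                  if config.biomass_csv else None)
    report = run_stats(diversity_df, abund_df, traits, biomass_df,
                       n_perm=config.n_perm,
                       seed=stage_seed(config.seed, "stats"),
                       permanova_continuous=config.permanova_continuous)
    (outdir / "stats.json").write_text(json.dumps(report, indent=2))
    (outdir / "summary.txt").write_text(_summary_text(report))
    manifest["stages"]["stats"] = {"keys": sorted(report.keys())}

    manifest["artifacts"] = sorted(p.name for p in outdir.iterdir()
                                   if p.name != "manifest.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
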
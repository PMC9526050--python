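"""End-to-end runner: simulated (or user-supplied) data to the full result set.

Stages run in dependency order: simulate -> ancestry -> assort -> lad-fit
(with assumed random mating and with the estimated spousal correlation) ->
sexbias -> roh -> ibd.  Every stochastic stage derives its seed
deterministically from the master seed plus the stage name, so a rerun with
the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admix_sim import (
    ContributionSchedule,
    SimConfig,
    autozygosity_truth,
    ibd_truth,
    simulate,
)
from .ancestry_stats import (
    global_ancestry,
    lad_windows,
    pooled_ancestry,
    population_summary,
    x_vs_auto_test,
)
from .genome_io import (
    GeneticMap,
    read_samples,
    read_segments,
    read_tracts,
    write_samples,
    write_segments,
    write_tracts,
)
from .mating import parental_ancestry, permutation_null
from .roh_ibd import (
    ancestry_switches_in_roh,
    boundary_from_generations,
    classify_roh,
    ibd_network,
    kinship_proxy,
    pairwise_ibd_totals,
    roh_summaries,
)
from .sexbias import grid_search
from .timing import fit_generations

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "derive_seed"]

CONFIG_VERSION = 1


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_TOP_KEYS = {"version", "seed", "simulate", "inputs", "stages", "params"}
_SIM_KEYS = {
    "N", "G", "rho", "sex_ratio", "n_sample", "n_founders", "population",
    "schedule", "map", "islands",
}
_SCHED_KEYS = {"kind", "h0", "m", "s1f", "s1m", "s2f", "s2m", "founding_s1f", "founding_s1m"}
_MAP_KEYS = {"autosomes_mb", "x_mb", "rate_cm_per_mb"}
_INPUT_KEYS = {"tracts", "samples", "roh", "ibd", "map"}
_STAGE_NAMES = ("ancestry", "assort", "lad_fit", "sexbias", "roh", "ibd")
_PARAM_DEFAULTS = {
    "window_mb": 10.0,
    "overlap_mb": 1.0,
    "step_mb": None,
    "g_min": 5,
    "g_max": 25,
    "rho_source": "assort",  # or a fixed float
    "m_list": [0.0, 0.01],
    "h0": 0.65,
    "sexbias_G": 20,
    "increment": 0.02,
    "keep": 0.001,
    "min_cm": 5.0,
    "edge_cm": 150.0,
    "top_quantile": None,
    "B": 1000,
    "boundary_generations": 20,
    "roh_scheme": "fixed",  # fixed | gmm3 | both
    "ibd_subsample": 80,
}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys are errors)."""

    seed: int
    simulate: dict | None = None
    inputs: dict | None = None
    stages: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, _TOP_KEYS, "top level")
        if raw.get("version", CONFIG_VERSION) != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {raw.get('version')}")
        if "seed" not in raw:
            raise ValueError("config requires a master seed")
        sim = raw.get("simulate")
        if sim is not None:
            _check_keys(sim, _SIM_KEYS, "simulate")
            _check_keys(sim.get("schedule", {}), _SCHED_KEYS, "simulate.schedule")
            _check_keys(sim.get("map", {}), _MAP_KEYS, "simulate.map")
            for isl in sim.get("islands", []) or []:
                _check_keys(isl, _SIM_KEYS - {"islands", "map", "schedule"} | {"rho"}, "island")
        inputs = raw.get("inputs")
        if inputs is not None:
            _check_keys(inputs, _INPUT_KEYS, "inputs")
            _check_keys(inputs.get("map", {}), _MAP_KEYS, "inputs.map")
        if sim is None and inputs is None:
            raise ValueError("config needs a simulate block or an inputs block")
        stages = dict.fromkeys(_STAGE_NAMES, True)
        user_stages = raw.get("stages", {})
        _check_keys(user_stages, set(_STAGE_NAMES), "stages")
        stages.update(user_stages)
        params = dict(_PARAM_DEFAULTS)
        user_params = raw.get("params", {})
        _check_keys(user_params, set(_PARAM_DEFAULTS), "params")
        params.update(user_params)
        return cls(
            seed=int(raw["seed"]), simulate=sim, inputs=inputs, stages=stages, params=params
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "version": CONFIG_VERSION,
            "seed": self.seed,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "stages": self.stages,
            "params": self.params,
        }

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _build_map(spec: dict) -> GeneticMap:
    return GeneticMap.uniform(
        spec.get("autosomes_mb", [100.0] * 10),
        rate_cm_per_mb=spec.get("rate_cm_per_mb", 1.0),
        x_mb=spec.get("x_mb"),
    )


def _build_schedule(spec: dict, G: int) -> ContributionSchedule:
    kind = spec.get("kind", "constant_migration")
    if kind == "constant_migration":
        return ContributionSchedule.constant_migration(G, spec.get("h0", 0.65), spec.get("m", 0.01))
    if kind == "constant":
        return ContributionSchedule.constant(
            G, spec.get("s1f", 0.0), spec.get("s1m", 0.0), spec.get("s2f", 0.0), spec.get("s2m", 0.0),
            founding_f=spec.get("founding_s1f"), founding_m=spec.get("founding_s1m"),
        )
    raise ValueError(f"unknown schedule kind {kind!r}")


def _simulate_stage(cfg: PipelineConfig):
    sim = cfg.simulate
    gmap = _build_map(sim.get("map", {}))
    G = sim.get("G", 20)
    schedule = _build_schedule(sim.get("schedule", {}), G)
    islands = sim.get("islands") or [{}]
    results = []
    for k, isl in enumerate(islands):
        merged = {**sim, **isl}
        sconf = SimConfig(
            gmap=gmap,
            N=merged.get("N", 500),
            schedule=schedule,
            seed=derive_seed(cfg.seed, f"simulate/{k}"),
            rho=merged.get("rho", 0.0),
            sex_ratio=merged.get("sex_ratio", 0.5),
            n_sample=merged.get("n_sample"),
            n_founders=merged.get("n_founders"),
            population=merged.get("population", f"pop{k + 1}"),
        )
        results.append(simulate(sconf))
    return gmap, results


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured stages and write one tidy table per stage.

    Returns the in-memory bundle; all tables are also written under
    ``out_dir`` together with ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    bundle: dict = {}
    seeds: dict[str, int] = {}

    sim_results = None
    roh_table = ibd_table = None
    if not any(config.stages.values()):
        manifest = {
            "package": "admixisle",
            "version": __version__,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "seeds": seeds,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        return {"manifest": manifest}
    if config.simulate is not None:
        gmap, sim_results = _simulate_stage(config)
        tracts_df = pd.concat([r.tracts.df for r in sim_results], ignore_index=True)
        samples_df = pd.concat([r.samples.df for r in sim_results], ignore_index=True)
        from .genome_io import AncestryTractSet, SampleTable

        tracts = AncestryTractSet(tracts_df, gmap)
        samples = SampleTable(samples_df)
        truth_df = pd.concat([r.truth.individuals for r in sim_results], ignore_index=True)
        write_tracts(tracts, out / "tracts.tsv")
        write_samples(samples, out / "samples.tsv")
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False, lineterminator="\n")
        bundle["simulate"] = {"truth": truth_df, "n_islands": len(sim_results)}
        seeds["simulate"] = derive_seed(config.seed, "simulate/0")
        roh_table = ibd_table = None
        if config.stages.get("roh"):
            roh_parts = [autozygosity_truth(r.truth, gmap) for r in sim_results]
            from .genome_io import SegmentTable

            roh_table = SegmentTable(
                pd.concat([t.df for t in roh_parts], ignore_index=True), gmap
            )
            write_segments(roh_table, out / "roh.tsv")
        if config.stages.get("ibd"):
            ibd_parts = []
            nsub = params["ibd_subsample"]
            for r in sim_results:
                ids = sorted(r.truth._haps)
                rng = np.random.default_rng(derive_seed(config.seed, f"ibd_subsample/{r.samples.df['population'].iat[0]}"))
                if len(ids) > nsub:
                    ids = sorted(rng.choice(ids, size=nsub, replace=False))
                ibd_parts.append(ibd_truth(r.truth, gmap, samples=ids).df)
            from .genome_io import SegmentTable

            ibd_table = SegmentTable(pd.concat(ibd_parts, ignore_index=True), gmap)
            write_segments(ibd_table, out / "ibd.tsv")
    else:
        gmap = _build_map(config.inputs.get("map", {}))
        tracts = read_tracts(config.inputs["tracts"], gmap)
        samples = read_samples(config.inputs["samples"])
        roh_table = (
            read_segments(config.inputs["roh"], gmap) if config.inputs.get("roh") else None
        )
        ibd_table = (
            read_segments(config.inputs["ibd"], gmap) if config.inputs.get("ibd") else None
        )

    anc_auto = anc_x = None
    if config.stages.get("ancestry"):
        anc_auto = global_ancestry(tracts, "autosomes")
        res = {"anc_auto": anc_auto}
        anc_tbl = pd.DataFrame({"sample": anc_auto.index, "anc_auto": anc_auto.to_numpy()})
        if gmap.x is not None:
            anc_x = global_ancestry(tracts, "X")
            anc_tbl["anc_x"] = anc_x.reindex(anc_auto.index).to_numpy()
            res["anc_x"] = anc_x
            stat, p = x_vs_auto_test(anc_auto, anc_x)
            res["x_vs_auto"] = {"W": stat, "p": p}
        res["population_summary"] = population_summary(anc_auto, samples)
        anc_tbl.to_csv(out / "ancestry.tsv", sep="\t", index=False, lineterminator="\n")
        res["population_summary"].to_csv(
            out / "ancestry_by_population.tsv", sep="\t", index=False, lineterminator="\n"
        )
        bundle["ancestry"] = res

    rho_hat = None
    if config.stages.get("assort"):
        seeds["assort"] = derive_seed(config.seed, "assort")
        pairs = parental_ancestry(tracts)
        assort = permutation_null(pairs, B=params["B"], seed=seeds["assort"])
        rho_hat = max(0.0, assort.median_r)
        assort.per_chrom.to_csv(out / "assort.tsv", sep="\t", index=False, lineterminator="\n")
        bundle["assort"] = {
            "per_chrom": assort.per_chrom,
            "median_r": assort.median_r,
            "p": assort.p,
            "B": assort.B,
        }

    if config.stages.get("lad_fit"):
        win = lad_windows(
            tracts,
            window_mb=params["window_mb"],
            overlap_mb=params["overlap_mb"],
            step_mb=params["step_mb"],
        )
        win.df.to_csv(out / "lad.tsv", sep="\t", index=False, lineterminator="\n")
        rho_src = params["rho_source"]
        if rho_src == "assort":
            if rho_hat is None:
                raise RuntimeError("rho_source 'assort' needs the assort stage enabled")
            rho_fit = rho_hat
        else:
            rho_fit = float(rho_src)
        fits = []
        for rho in sorted({0.0, rho_fit}):
            for m in params["m_list"]:
                fit = fit_generations(
                    win, rho=rho, m=m, h0=params["h0"],
                    g_min=params["g_min"], g_max=params["g_max"],
                )
                fits.append(
                    {"rho": rho, "m": m, "h0": params["h0"], "best_g": fit.best_g,
                     "sse": float(fit.sse.min()), "at_boundary": fit.at_boundary}
                )
        fits_df = pd.DataFrame(fits)
        fits_df.to_csv(out / "lad_fit.tsv", sep="\t", index=False, lineterminator="\n")
        bundle["lad_fit"] = {"windows": win.df, "mean_lad": win.mean_lad, "fits": fits_df}

    if config.stages.get("sexbias"):
        if anc_auto is None or anc_x is None:
            raise RuntimeError("sexbias stage needs the ancestry stage with an X chromosome")
        grid = grid_search(
            float(anc_auto.mean()), pooled_ancestry(tracts, "X"), pf=samples.female_fraction,
            G=params["sexbias_G"], increment=params["increment"], keep=params["keep"],
        )
        grid.retained.to_csv(out / "sexbias.tsv", sep="\t", index=False, lineterminator="\n")
        bundle["sexbias"] = {
            "retained": grid.retained,
            "median_f1": grid.median_f1,
            "median_f2": grid.median_f2,
            "obs": grid.obs,
            "pf": grid.pf,
        }

    if config.stages.get("roh") and roh_table is not None and len(roh_table) > 0:
        res = {}
        boundary = boundary_from_generations(params["boundary_generations"])
        schemes = []
        if params["roh_scheme"] in ("fixed", "both"):
            schemes.append(("fixed", dict(boundary_mb=boundary)))
        if params["roh_scheme"] in ("gmm3", "both"):
            schemes.append(("gmm3", dict(seed=derive_seed(config.seed, "roh_gmm"))))
        for name, kw in schemes:
            try:
                cls = classify_roh(roh_table, scheme=name, **kw)
            except ValueError as err:
                res[name] = {"error": str(err)}
                continue
            summary = roh_summaries(roh_table, cls, ancestry=anc_auto, samples=samples)
            switches = ancestry_switches_in_roh(roh_table, tracts, cls)
            res[name] = {
                "classification": cls,
                "per_individual": summary.per_individual,
                "correlations": summary.correlations,
                "population_tests": summary.population_tests,
                "switches_per_class": switches.per_class,
            }
            summary.per_individual.to_csv(
                out / f"roh_{name}_per_individual.tsv", sep="\t", index=False, lineterminator="\n"
            )
            switches.per_class.to_csv(
                out / f"roh_{name}_switches.tsv", sep="\t", index=False, lineterminator="\n"
            )
        bundle["roh"] = res

    if config.stages.get("ibd") and ibd_table is not None and len(ibd_table) > 0:
        totals = pairwise_ibd_totals(ibd_table, min_cm=params["min_cm"])
        edges, _graph = ibd_network(
            totals, edge_cm=None if params["top_quantile"] else params["edge_cm"],
            top_quantile=params["top_quantile"],
        )
        kin = kinship_proxy(ibd_table, gmap, min_cm=params["min_cm"])
        totals.to_csv(out / "ibd_totals.tsv", sep="\t", index=False, lineterminator="\n")
        edges.to_csv(out / "ibd_network.tsv", sep="\t", index=False, lineterminator="\n")
        bundle["ibd"] = {"totals": totals, "edges": edges, "kinship": kin}

    manifest = {
        "package": "admixisle",
        "version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seeds": seeds,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    bundle["manifest"] = manifest
    return bundle


def make_report(bundle: dict) -> str:
    """Human-readable summary of a pipeline bundle."""
    lines = ["admixisle pipeline report", "=" * 26]
    man = bundle.get("manifest", {})
    if man:
        lines.append(f"config digest: {man.get('config_digest', '')[:16]}")
    if "ancestry" in bundle:
        a = bundle["ancestry"]
        lines.append("")
        lines.append("[ancestry]")
        lines.append(f"  mean autosomal S1 ancestry: {a['anc_auto'].mean():.4f}")
        if "anc_x" in a:
            lines.append(f"  mean X S1 ancestry:         {a['anc_x'].mean():.4f}")
        if "x_vs_auto" in a:
            lines.append(
                f"  X vs autosomes Wilcoxon W={a['x_vs_auto']['W']:.1f}, p={a['x_vs_auto']['p']:.3g}"
            )
        lines.append("  per population:")
        for row in a["population_summary"].itertuples(index=False):
            lines.append(
                f"    {row.population}: n={row.n} mean={row.mean:.3f} median={row.median:.3f}"
            )
    if "assort" in bundle:
        s = bundle["assort"]
        lines.append("")
        lines.append("[assortative mating]")
        lines.append(
            f"  median spousal-ancestry R = {s['median_r']:.3f} "
            f"(permutation p = {s['p']:.4g}, B = {s['B']})"
        )
    if "lad_fit" in bundle:
        f = bundle["lad_fit"]
        lines.append("")
        lines.append("[admixture timing]")
        lines.append(f"  mean LAD over {len(f['windows'])} windows: {f['mean_lad']:.4f}")
        for row in f["fits"].itertuples(index=False):
            lines.append(
                f"  assumed rho={row.rho:.3f}, m={row.m:g}: best g = {row.best_g}"
                + (" (grid boundary)" if row.at_boundary else "")
            )
    if "sexbias" in bundle:
        s = bundle["sexbias"]
        lines.append("")
        lines.append("[sex bias]")
        lines.append(f"  observed (H_auto, H_X) = ({s['obs'][0]:.4f}, {s['obs'][1]:.4f})")
        lines.append(
            f"  retained female fractions: median f1 = {s['median_f1']:.3f}, "
            f"median f2 = {s['median_f2']:.3f}"
        )
    if "roh" in bundle:
        lines.append("")
        lines.append("[ROH]")
        for scheme, r in bundle["roh"].items():
            if "error" in r:
                lines.append(f"  {scheme}: {r['error']}")
                continue
            cls = r["classification"]
            bnd = ", ".join(f"{b:.2f} Mb" for b in cls.boundary_mb())
            lines.append(f"  {scheme}: boundaries {bnd}")
            if r["correlations"] is not None:
                for row in r["correlations"].itertuples(index=False):
                    lines.append(
                        f"    class {row[0]}: r(total, S1 ancestry) = {row.r:.3f} (p={row.p:.3g})"
                    )
            for row in r["switches_per_class"].itertuples(index=False):
                lines.append(
                    f"    class {row.cls}: {row.frac_with_switch:.1%} of segments contain "
                    f"an ancestry switch ({row.mean_per_mb:.3f}/Mb)"
                )
    if "ibd" in bundle:
        i = bundle["ibd"]
        lines.append("")
        lines.append("[IBD]")
        lines.append(f"  pairs with shared IBD: {len(i['totals'])}")
        lines.append(f"  network edges: {len(i['edges'])}")
        if len(i["kinship"]):
            lines.append(f"  max kinship proxy: {i['kinship'].max():.3f}")
    lines.append("")
    return "\n".join(lines)
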
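"""End-to-end orchestration: climate -> events -> traits -> repeatability ->
SubsetQD -> QC/kinship -> association scans -> report.

Each stage writes plain-text artifacts into the output directory; a rerun with
``resume=True`` loads finished stage outputs instead of recomputing, which is
property-tested to give byte-identical final artifacts.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc, climate, dendro, popgen, quantgen
from .io_core import (
    KinshipMatrix,
    QMatrix,
    get_logger,
    load_toml,
    read_climate_csv,
    read_genotypes,
    read_kinship_csv,
    read_long_csv,
    read_q_csv,
    read_trait_table,
    write_kinship_csv,
    write_trait_table,
)
from .synthetic_data import SimConfig, simulate_all, write_sim_data

log = get_logger("pipeline")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 42
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    # explicit input paths when simulate = False
    inputs: dict = field(default_factory=dict)
    spi_scales: tuple[int, ...] = (1, 3)
    reference_period: tuple[int, int] = (1961, 2011)
    event_threshold: float = -2.0
    growing_season: tuple[int, ...] = (4, 5, 6, 7)
    response_window: int = 2
    alpha_levels: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1)
    subset_rule: bool = True
    n_genotyped: int | None = 147
    climate_variables: tuple[str, ...] = dendro.DEFAULT_CLIMATE_VARIABLES
    flag_singles: bool = True

    def __post_init__(self) -> None:
        levels = tuple(self.alpha_levels)
        if list(levels) != sorted(levels):
            self.alpha_levels = tuple(sorted(levels))

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = load_toml(path)
        try:
            pipe = raw.get("pipeline", {})
            cfg = cls(
                out_dir=pipe["out_dir"],
                seed=int(pipe.get("seed", 42)),
                simulate=bool(raw.get("inputs", {}).get("simulate", True)),
                sim_overrides=raw.get("simulate", {}),
                inputs={k: v for k, v in raw.get("inputs", {}).items() if k != "simulate"},
            )
            spi = raw.get("spi", {})
            cfg.spi_scales = tuple(spi.get("scales", cfg.spi_scales))
            cfg.reference_period = tuple(spi.get("ref", cfg.reference_period))
            cfg.event_threshold = float(spi.get("threshold", cfg.event_threshold))
            cfg.growing_season = tuple(spi.get("growing_season", cfg.growing_season))
            resp = raw.get("response", {})
            cfg.response_window = int(resp.get("window", cfg.response_window))
            asc = raw.get("assoc", {})
            cfg.alpha_levels = tuple(sorted(asc.get("alpha_levels", cfg.alpha_levels)))
            cfg.subset_rule = bool(asc.get("subset_rule", cfg.subset_rule))
            if "n_genotyped" in asc:
                cfg.n_genotyped = int(asc["n_genotyped"]) or None
            cfg.flag_singles = bool(asc.get("flag_singles", cfg.flag_singles))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc
        return cfg


def marker_trait_pairs(n_markers: int, n_traits: int) -> int:
    """Size of the test grid: markers after QC x trait columns."""
    return n_markers * n_traits


RESPONSE_KINDS = ("Rt", "Rc", "Rs", "rRs")


class Pipeline:
    def __init__(self, cfg: PipelineConfig, resume: bool = False):
        self.cfg = cfg
        self.resume = resume
        self.out = cfg.out_dir
        os.makedirs(self.out, exist_ok=True)

    def _path(self, name: str) -> str:
        return os.path.join(self.out, name)

    def _done(self, *names: str) -> bool:
        return self.resume and all(os.path.exists(self._path(n)) for n in names)

    # -- stages ------------------------------------------------------------

    def stage_inputs(self):
        cfg = self.cfg
        if cfg.simulate:
            if self._done("rings.csv", "climate.csv", "stations.csv", "genotypes.csv", "markers.csv", "qmatrix.csv"):
                log.info("inputs: resumed from %s", self.out)
            else:
                sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim_overrides)
                data = simulate_all(sim_cfg)
                write_sim_data(data, self.out)
            self.stations = read_climate_csv(self._path("climate.csv"), self._path("stations.csv"))
            self.rings = read_long_csv(self._path("rings.csv"))
            self.G = read_genotypes(self._path("genotypes.csv"), "csv", self._path("markers.csv"))
            self.Q = read_q_csv(self._path("qmatrix.csv"))
        else:
            inp = cfg.inputs
            try:
                self.stations = read_climate_csv(inp["climate"], inp["stations"])
                self.rings = read_long_csv(inp["rings"])
                fmt = "vcf" if str(inp["genotypes"]).endswith(".vcf") else "csv"
                self.G = read_genotypes(inp["genotypes"], fmt, inp.get("markers"))
                self.Q = read_q_csv(inp["q"]) if "q" in inp else None
            except KeyError as exc:
                raise ConfigError(f"missing input path: {exc}") from exc
        site = self.cfg.sim_overrides.get("site_lat"), self.cfg.sim_overrides.get("site_lon")
        self.site = (
            float(site[0]) if site[0] is not None else 48.548,
            float(site[1]) if site[1] is not None else 16.171,
        )

    def stage_climate(self):
        cfg = self.cfg
        if self._done("spi.csv", "state.json"):
            spi_df = pd.read_csv(self._path("spi.csv"))
            state = json.load(open(self._path("state.json")))
            self.event_years = state["event_years"]
            self.site_climate = climate.idw_interpolate(self.stations, *self.site)
            return
        self.site_climate = climate.idw_interpolate(self.stations, *self.site)
        precip = self.site_climate.series("prcp_mm")
        spi_series = [
            climate.compute_spi(precip, k, cfg.reference_period) for k in cfg.spi_scales
        ]
        events = climate.detect_drought_events(
            spi_series, cfg.event_threshold, cfg.growing_season
        )
        self.event_years = climate.retained_event_years(events)
        if len(self.event_years) < 2:
            raise RuntimeError(f"only {len(self.event_years)} growing-season drought events found")
        frame = {}
        for spi in spi_series:
            frame[f"spi_k{spi.k}"] = spi.values
            frame[f"class_k{spi.k}"] = spi.classes()
        df = pd.DataFrame(frame)
        df.index.names = ["year", "month"]
        df.reset_index().to_csv(self._path("spi.csv"), index=False)
        self._save_state()

    def _save_state(self, **extra):
        state = {"event_years": getattr(self, "event_years", None)}
        state.update(extra)
        path = self._path("state.json")
        if os.path.exists(path):
            old = json.load(open(path))
            old.update({k: v for k, v in state.items() if v is not None})
            state = old
        with open(path, "w") as fh:
            json.dump(state, fh, indent=1, sort_keys=True)

    def stage_traits(self):
        self.trees = dendro.average_cores_by_tree(self.rings)
        self.provenances = pd.Series(
            {tid: s.provenance for tid, s in self.trees.items()}, name="provenance"
        )
        if self._done("traits.csv"):
            self.traits = read_trait_table(self._path("traits.csv"))
            self.responses = self.traits[
                [c for c in self.traits.columns if c[:2] in ("Rt", "Rc", "Rs") or c.startswith("rRs")]
            ]
            return
        self.traits = dendro.assemble_trait_table(
            self.trees,
            self.event_years,
            self.site_climate,
            window=self.cfg.response_window,
            climate_variables=list(self.cfg.climate_variables),
        )
        self.responses = dendro.drought_response_table(
            self.trees, self.event_years, window=self.cfg.response_window
        )
        write_trait_table(self.traits, self._path("traits.csv"))

    def stage_repeatability(self):
        if self._done("repeatability.csv", "state.json"):
            self.repeatability = pd.read_csv(self._path("repeatability.csv"))
            state = json.load(open(self._path("state.json")))
            self.subset_qd = state.get("subset_qd") or []
            return
        rows = []
        rt_estimates = {}
        suffixes = [f"{y % 100:02d}" for y in self.event_years]
        for kind in RESPONSE_KINDS:
            cols = [f"{kind}{s}" for s in suffixes]
            std = pd.DataFrame(
                {c: quantgen.standardize_response(self.traits[c], kind) for c in cols}
            )
            long = std.stack().rename("y").reset_index()
            long.columns = ["individual_id", "event", "y"]
            prov = self.provenances.reindex(long["individual_id"]).to_numpy()
            try:
                vc, est = quantgen.reml_repeatability(
                    long["y"].to_numpy(), long["individual_id"].to_numpy(), prov
                )
                rows.append(_repeat_row("overall", kind, vc, est))
            except (ValueError, RuntimeError) as exc:
                log.warning("overall REML for %s failed: %s", kind, exc)
            for label in sorted(self.provenances.unique()):
                ids = set(self.provenances.index[self.provenances == label])
                sub = long[long["individual_id"].isin(ids)]
                try:
                    vc, est = quantgen.reml_repeatability(
                        sub["y"].to_numpy(), sub["individual_id"].to_numpy()
                    )
                except (ValueError, RuntimeError) as exc:
                    log.warning("REML for %s/%s failed: %s", label, kind, exc)
                    continue
                rows.append(_repeat_row(label, kind, vc, est))
                if kind == "Rt":
                    rt_estimates[label] = est
        self.repeatability = pd.DataFrame(rows)
        self.repeatability.to_csv(self._path("repeatability.csv"), index=False)
        self.subset_qd = quantgen.select_subset_qd(rt_estimates) if self.cfg.subset_rule else []
        self._save_state(subset_qd=self.subset_qd)

    def stage_popgen(self):
        cfg = self.cfg
        # genotyped subsample: phenotype extremes on mean standardized Rt
        suffixes = [f"{y % 100:02d}" for y in self.event_years]
        rt_cols = [f"Rt{s}" for s in suffixes]
        mean_rt = self.traits[rt_cols].mean(axis=1).dropna()
        mean_rt = mean_rt[mean_rt.index.isin(self.G.individuals)]
        if cfg.n_genotyped and cfg.n_genotyped < len(mean_rt):
            half = cfg.n_genotyped // 2
            ranked = mean_rt.sort_values()
            chosen = list(ranked.index[:half]) + list(ranked.index[-(cfg.n_genotyped - half):])
            chosen = [i for i in self.G.individuals if i in set(chosen)]
        else:
            chosen = [i for i in self.G.individuals if i in set(mean_rt.index)]
        self.genotyped_ids = chosen
        G_sub = self.G.subset_individuals(chosen)
        if self._done("kinship.csv", "qc_report.tsv"):
            self.K = read_kinship_csv(self._path("kinship.csv"))
            self.G_qc, _ = popgen.snp_qc(G_sub)
            return
        self.G_qc, qc_stats = popgen.snp_qc(G_sub)
        pd.DataFrame([vars(s) for s in qc_stats]).to_csv(
            self._path("qc_report.tsv"), sep="\t", index=False
        )
        neutral = popgen.select_neutral(G_sub)
        if len(neutral) < 2:
            raise RuntimeError("fewer than 2 neutral markers for kinship")
        self.K = popgen.centered_ibs_kinship(G_sub.subset_markers(neutral))
        write_kinship_csv(self.K, self._path("kinship.csv"))

    def _run_scan(self, name: str, ids: list[str]) -> tuple[pd.DataFrame, int]:
        G_sub, _ = popgen.snp_qc(self.G.subset_individuals(ids))
        K_sub = self.K.subset(ids)
        Q_sub = self.Q.subset(ids) if self.Q is not None else None
        traits = self.traits.reindex(ids)
        path = self._path(f"gwas_{name}.tsv")
        if self._done(f"gwas_{name}.tsv"):
            return pd.read_csv(path, sep="\t"), G_sub.n_markers
        res = assoc.mlm_qk_scan(
            traits, G_sub, Q_sub, K_sub,
            alpha_levels=self.cfg.alpha_levels,
            flag_singles=self.cfg.flag_singles,
        )
        res.to_csv(path, sep="\t", index=False)
        for trait_name, grp in res.groupby("trait"):
            p = grp["p"].dropna()
            if len(p):
                assoc.qq_data(p).to_csv(
                    self._path(f"qq_{name}_{trait_name}.csv"), index=False
                )
        return res, G_sub.n_markers

    def stage_scans(self):
        self.scan_all, self.m_all = self._run_scan("all", self.genotyped_ids)
        self.scan_subset, self.m_subset = None, None
        if self.cfg.subset_rule and self.subset_qd:
            ids = [
                i for i in self.genotyped_ids if self.provenances.get(i) in set(self.subset_qd)
            ]
            if len(ids) >= 10:
                self.scan_subset, self.m_subset = self._run_scan("subset", ids)

    def stage_report(self) -> dict:
        n_traits = self.traits.shape[1]
        report = {
            "n_traits": n_traits,
            "n_trees": len(self.trees),
            "n_genotyped": len(self.genotyped_ids),
            "event_years": list(self.event_years),
            "subset_qd": list(self.subset_qd),
            "markers_after_qc_all": self.m_all,
            "marker_trait_pairs_all": marker_trait_pairs(self.m_all, n_traits),
        }
        if self.scan_subset is not None:
            report["markers_after_qc_subset"] = self.m_subset
            report["marker_trait_pairs_subset"] = marker_trait_pairs(self.m_subset, n_traits)
        for name, scan, m in (("all", self.scan_all, self.m_all), ("subset", self.scan_subset, self.m_subset)):
            if scan is None:
                continue
            for alpha in self.cfg.alpha_levels:
                thr = assoc.bonferroni_threshold(alpha, m)
                ok = scan["testable"].astype(bool) if "testable" in scan else True
                report[f"significant_{name}_alpha_{alpha}"] = int(
                    ((scan["p"] < thr) & ok).sum()
                )
        with open(self._path("report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        lines = [f"{k}\t{v}" for k, v in sorted(report.items())]
        with open(self._path("report.tsv"), "w") as fh:
            fh.write("key\tvalue\n" + "\n".join(lines) + "\n")
        return report

    STAGES = ("inputs", "climate", "traits", "repeatability", "popgen", "scans")

    def run(self) -> dict:
        for stage in self.STAGES:
            try:
                getattr(self, f"stage_{stage}")()
            except ConfigError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage wrapper contract
                raise StageError(stage, exc) from exc
        try:
            return self.stage_report()
        except Exception as exc:  # noqa: BLE001
            raise StageError("report", exc) from exc


def _repeat_row(scope, trait, vc, est) -> dict:
    return {
        "scope": scope,
        "trait": trait,
        "sigma2_prov": vc.sigma2_prov if vc.sigma2_prov is not None else "",
        "sigma2_ind": vc.sigma2_ind,
        "sigma2_res": vc.sigma2_res,
        "se_prov": vc.se_prov,
        "se_ind": vc.se_ind,
        "se_res": vc.se_res,
        "r": est.r if est.estimable else "n.e.",
        "se_r": est.se_r,
        "significant": est.significant,
    }


def run_all(config: PipelineConfig | str, resume: bool = False) -> dict:
    """Run the whole analysis graph; returns the summary report dict."""
    cfg = PipelineConfig.from_toml(config) if isinstance(config, str) else config
    return Pipeline(cfg, resume=resume).run()
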
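"""Synthetic climate, ring-series and genotype generator with ground truth.

The generator emits data with the statistical structure the analysis assumes:
a provenance trial (11 provenances, 22-55 trees each), ~30-year ring series
with embedded drought years, a provenance/individual/residual variance
decomposition of the log drought-growth multiplier (so Lloret ratios inherit
the intended repeatability), and Balding-Nichols genotypes with a 2-cluster
low-Fst structure plus a few large-effect causal markers.

Monthly precipitation is a floored gamma: x = mu_m * (floor + s * Gamma(k)).
The hard floor keeps every fitted SPI above the extreme-event threshold in
non-drought years, while drought years get growing-season precipitation cut
to a few percent of normal, far below the floor, so the SPI dives below -2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    GENE_CONTEXTS,
    MISSING,
    ClimateRecord,
    GenotypeMatrix,
    QMatrix,
    RingSeries,
    get_logger,
)

log = get_logger("simulate")

#: Tree counts per provenance mirroring the shape of a real trial (sum 323).
DEFAULT_PROVENANCE_SIZES = (27, 34, 30, 22, 32, 23, 22, 24, 55, 27, 27)

#: Seasonal mean precipitation (mm) and temperature (degC) per calendar month.
MONTH_PRCP_MM = (25, 26, 33, 42, 62, 71, 74, 68, 50, 38, 36, 30)
MONTH_TMEAN_C = (-1.5, 0.2, 4.6, 9.8, 14.6, 17.9, 19.7, 19.2, 14.8, 9.3, 3.9, -0.2)


@dataclass
class SimConfig:
    """All knobs of the generator; ``seed`` is mandatory for determinism."""

    seed: int
    n_provenances: int = 11
    trees_per_provenance: tuple[int, ...] | None = None
    year_start: int = 1961
    year_end: int = 2011
    ring_start: int = 1982
    drought_years: tuple[int, ...] = (1993, 2000, 2003)
    #: mean log growth multiplier per drought event (negative = growth loss)
    drought_log_means: tuple[float, ...] = (-0.45, -1.30, -0.40)
    #: variance fractions of the log drought multiplier
    frac_provenance: float = 0.06
    frac_individual: float = 0.30
    frac_residual: float = 0.64
    total_log_variance: float = 0.16
    #: population structure
    k_clusters: int = 2
    fst: float = 0.03
    n_markers: int = 1700
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_marker_fraction: float = 0.05
    missing_call_rate: float = 0.05
    n_missing_patterns: int = 4
    #: assign provenances to pure clusters (no admixture); useful for
    #: Fst-recovery checks where groups must coincide with clusters
    pure_clusters: bool = False
    #: causal markers: target per-marker fraction of trait variance
    causal_r2: tuple[float, ...] = (0.15, 0.25, 0.35)
    #: climate
    n_stations: int = 4
    site_lat: float = 48.548
    site_lon: float = 16.171
    drought_precip_factor: float = 0.02
    cores_per_tree: int = 2
    core_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.trees_per_provenance is None:
            sizes = list(DEFAULT_PROVENANCE_SIZES)
            if self.n_provenances != len(sizes):
                base = [24 + 3 * (i % 11) for i in range(self.n_provenances)]
                sizes = base
            self.trees_per_provenance = tuple(sizes[: self.n_provenances])
        fracs = (self.frac_provenance, self.frac_individual, self.frac_residual)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValueError("variance fractions must be >= 0 and sum to <= 1")
        for r2 in self.causal_r2:
            if not 0 < r2 < 0.6:
                raise ValueError("target causal R^2 must lie in (0, 0.6)")

    @property
    def provenances(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_provenances)]

    def tree_ids(self) -> list[tuple[str, str]]:
        out = []
        for prov, n in zip(self.provenances, self.trees_per_provenance):
            out.extend((f"{prov}_T{t + 1:02d}", prov) for t in range(n))
        return out


@dataclass
class GroundTruth:
    event_years: tuple[int, ...]
    r_individual: float  # true repeatability of the log drought multiplier
    sigma2_prov: float
    sigma2_ind: float
    sigma2_res: float
    causal_markers: dict[str, float] = field(default_factory=dict)  # id -> beta
    q: QMatrix | None = None
    provenance_of: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

_FLOOR = 0.78
_YEAR_SHAPE = 2.0
_YEAR_SCALE = 0.10  # shared wet/dry year factor; mean contribution ~0.2
_YEAR_TRUNC = 0.05  # sample the year factor above its own 5% quantile


def simulate_climate(cfg: SimConfig, rng: np.random.Generator) -> list[ClimateRecord]:
    """Simulate station records around the trial site.

    Site precipitation per month is mu_m * (floor + shared wet/dry year factor
    + small independent jitter): the shared factor keeps k-month sums as far
    from the hard floor (in sd units) as single months, so fitted SPI values
    of non-drought years stay above the extreme threshold on both timescales.
    Drought years scale May-June by ``drought_precip_factor``.  Temperatures
    are AR(1) around the seasonal mean.  Stations observe the site series with
    small multiplicative noise, so inverse-distance interpolation recovers it.
    """
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    idx = pd.MultiIndex.from_product([years, range(1, 13)], names=["year", "month"])
    n = len(idx)
    mu = np.tile(MONTH_PRCP_MM, len(years)).astype(float)
    from scipy import stats as _stats

    u = rng.uniform(_YEAR_TRUNC, 1.0, size=len(years))
    year_factor = np.repeat(_stats.gamma.ppf(u, _YEAR_SHAPE) * _YEAR_SCALE, 12)
    prcp = mu * (_FLOOR + year_factor + rng.uniform(0.01, 0.05, size=n))
    month_arr = np.tile(np.arange(1, 13), len(years))
    year_arr = np.repeat(years, 12)
    drought = np.isin(year_arr, cfg.drought_years) & np.isin(month_arr, (5, 6))
    prcp[drought] *= cfg.drought_precip_factor

    tmean = np.empty(n)
    ar = 0.0
    for i in range(n):
        ar = 0.35 * ar + rng.normal(0.0, 1.0)
        tmean[i] = MONTH_TMEAN_C[month_arr[i] - 1] + 0.8 * ar
    # growth couples negatively to summer heat; add a shared warm/cool year signal
    records = []
    for s in range(cfg.n_stations):
        factor = np.exp(rng.normal(0.0, 0.04, size=n))
        table = pd.DataFrame(
            {
                "prcp_mm": np.round(prcp * factor, 1),
                "tmean_c": np.round(tmean + rng.normal(0.0, 0.15, size=n), 2),
            },
            index=idx,
        )
        angle = 2 * np.pi * s / cfg.n_stations
        records.append(
            ClimateRecord(
                station_id=f"ST{s + 1:02d}",
                lat=cfg.site_lat + 0.15 * np.sin(angle),
                lon=cfg.site_lon + 0.2 * np.cos(angle),
                elev=250.0 + 30 * s,
                table=table,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator) -> tuple[GenotypeMatrix, QMatrix]:
    """Balding-Nichols genotypes with admixed 2-cluster (K-cluster) structure.

    Ancestral frequencies are uniform on ``maf_range``; cluster frequencies
    follow Beta(p(1-F)/F, (1-p)(1-F)/F); each individual's genotype is
    Binomial(2, q . p_clusters).  True admixture proportions are returned as
    the Q matrix.  A small fraction of markers carries missing calls, reusing
    a handful of missingness patterns.
    """
    trees = cfg.tree_ids()
    n_ind = len(trees)
    m = cfg.n_markers
    F = cfg.fst
    p_anc = rng.uniform(*cfg.maf_range, size=m)
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_pop = rng.beta(a, b, size=(cfg.k_clusters, m))
    else:
        p_pop = np.tile(p_anc, (cfg.k_clusters, 1))

    # provenance-level cluster leanings, individuals jittered around them
    if cfg.pure_clusters:
        prov_base = np.array([float(i % 2) for i in range(cfg.n_provenances)])
        jitter = 0.0
    else:
        prov_base = rng.uniform(0.15, 0.85, size=cfg.n_provenances)
        jitter = 0.08
    q1 = np.empty(n_ind)
    prov_index = {p: i for i, p in enumerate(cfg.provenances)}
    for i, (_, prov) in enumerate(trees):
        q1[i] = np.clip(prov_base[prov_index[prov]] + rng.normal(0, jitter) * (jitter > 0), 0.0, 1.0)
    if cfg.k_clusters == 2:
        q = np.column_stack([q1, 1 - q1])
    else:
        alpha = np.full(cfg.k_clusters, 0.5)
        q = rng.dirichlet(alpha, size=n_ind)
    p_ind = q @ p_pop  # (n_ind, m)
    codes = rng.binomial(2, np.clip(p_ind, 0.0, 1.0)).astype(np.int8)

    # missingness: a few shared patterns over a subset of markers
    n_missing_markers = int(round(cfg.missing_marker_fraction * m))
    patterns = [
        rng.random(n_ind) < cfg.missing_call_rate for _ in range(cfg.n_missing_patterns)
    ]
    missing_markers = rng.choice(m, size=n_missing_markers, replace=False)
    for j in missing_markers:
        pat = patterns[int(rng.integers(cfg.n_missing_patterns))]
        codes[pat, j] = MISSING

    contexts = rng.choice(
        GENE_CONTEXTS, size=m, p=(0.55, 0.15, 0.075, 0.075, 0.15)
    )
    chrom = np.sort(rng.integers(1, 13, size=m))
    pos = np.sort(rng.integers(1, 10_000_000, size=m))
    alleles = rng.choice(["A/G", "T/C", "A/C", "T/G"], size=m)
    markers = [f"SNP{j + 1:05d}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "marker_id": markers,
            "chrom": chrom.astype(str),
            "pos": pos,
            "alleles": alleles,
            "gene_context": contexts,
        }
    ).set_index("marker_id")
    G = GenotypeMatrix([t for t, _ in trees], markers, codes, meta)
    Q = QMatrix([t for t, _ in trees], q)
    return G, Q


def _pick_causal(cfg: SimConfig, G: GenotypeMatrix, rng: np.random.Generator) -> list[int]:
    """Complete, common markers make stable causal candidates."""
    codes = G.codes
    ok = []
    for j in range(G.n_markers):
        col = codes[:, j]
        if (col == MISSING).any():
            continue
        p = col.mean() / 2
        if 0.2 <= min(p, 1 - p) <= 0.5:
            ok.append(j)
    if len(ok) < len(cfg.causal_r2):
        raise ValueError("not enough complete common markers for causal effects")
    return list(rng.choice(ok, size=len(cfg.causal_r2), replace=False))


# ---------------------------------------------------------------------------
# Ring series
# ---------------------------------------------------------------------------


def _age_curve(age: np.ndarray) -> np.ndarray:
    """Smooth juvenile-rise / mature-decline ring width trend (mm)."""
    return 0.8 + 3.2 * (age / 9.0) * np.exp(1.0 - age / 9.0)


def simulate_rings(
    cfg: SimConfig,
    G: GenotypeMatrix,
    rng: np.random.Generator,
    temperature_signal: pd.Series | None = None,
) -> tuple[dict[tuple[str, str], RingSeries], GroundTruth]:
    """Simulate per-core ring series with drought-year growth multipliers.

    Baseline ring width is an age-trend curve times a lognormal tree effect
    with small year-to-year noise.  In each drought year the log multiplier is
    event mean + provenance effect + individual effect (constant across
    events) + additive causal-marker effects + residual.  Effects act on the
    log scale so the Lloret ratios inherit the variance decomposition.
    """
    trees = cfg.tree_ids()
    if [t for t, _ in trees] != list(G.individuals):
        raise ValueError("genotype individuals do not match the configured trees")
    years = np.arange(cfg.ring_start, cfg.year_end + 1)
    n_years = len(years)
    ages = np.arange(1, n_years + 1, dtype=float) + 4.0  # planted as 5-year seedlings

    tv = cfg.total_log_variance
    s2_prov = cfg.frac_provenance * tv
    s2_ind = cfg.frac_individual * tv
    s2_res = cfg.frac_residual * tv

    causal_idx = _pick_causal(cfg, G, rng) if cfg.causal_r2 else []
    betas = {}
    causal_x = []
    for j, r2 in zip(causal_idx, cfg.causal_r2):
        col = G.codes[:, j].astype(float)
        var_x = col.var()
        background = s2_prov + s2_ind + s2_res
        beta = float(np.sqrt(r2 / (1 - r2) * background / var_x))
        betas[G.markers[j]] = beta
        causal_x.append((col - col.mean()) * beta)
    genetic = np.sum(causal_x, axis=0) if causal_x else np.zeros(len(trees))
    var_genetic = float(np.var(genetic))

    prov_eff = {p: rng.normal(0.0, np.sqrt(s2_prov)) for p in cfg.provenances}
    ind_eff = rng.normal(0.0, np.sqrt(s2_ind), size=len(trees))
    event_pos = {y: i for i, y in enumerate(cfg.drought_years)}

    out: dict[tuple[str, str], RingSeries] = {}
    provenance_of = {}
    for i, (tree_id, prov) in enumerate(trees):
        provenance_of[tree_id] = prov
        tree_scale = np.exp(rng.normal(0.0, 0.15))
        log_mult = np.zeros(n_years)
        for y in cfg.drought_years:
            if y < years[0] or y > years[-1]:
                continue
            e = event_pos[y]
            log_mult[y - years[0]] = (
                cfg.drought_log_means[e]
                + prov_eff[prov]
                + ind_eff[i]
                + genetic[i]
                + rng.normal(0.0, np.sqrt(s2_res))
            )
        year_noise = rng.normal(0.0, 0.05, size=n_years)
        if temperature_signal is not None:
            year_noise = year_noise - 0.04 * temperature_signal.reindex(years).fillna(0.0).to_numpy()
        rw_true = _age_curve(ages) * tree_scale * np.exp(log_mult + year_noise)

        drought_mask = np.isin(years, cfg.drought_years)
        lwp = np.clip(
            0.25 + 0.08 * drought_mask + rng.normal(0.0, 0.03, size=n_years), 0.02, 0.9
        )
        rd = 430 + 40 * rng.normal() + 30 * drought_mask + rng.normal(0, 12, size=n_years)
        maxd = rd + 230 + 60 * drought_mask + np.abs(rng.normal(0, 20, size=n_years))
        mind = rd - 120 - np.abs(rng.normal(0, 12, size=n_years))
        ed = mind + 50 + np.abs(rng.normal(0, 8, size=n_years))
        ld = maxd - 70 - np.abs(rng.normal(0, 10, size=n_years))
        for c in range(cfg.cores_per_tree):
            noise = rng.normal(0.0, cfg.core_noise_sd, size=n_years)
            rw = np.round(np.clip(rw_true + noise, 0.01, None), 3)
            lw = np.round(rw * lwp, 3)
            ew = np.round(rw - lw, 3)
            out[(tree_id, f"c{c + 1}")] = RingSeries(
                tree_id=tree_id,
                core_id=f"c{c + 1}",
                provenance=prov,
                years=years.copy(),
                data={
                    "RW": rw,
                    "EW": ew,
                    "LW": lw,
                    "LWP": np.round(lwp * 100, 2),
                    "RD": np.round(rd, 1),
                    "ED": np.round(ed, 1),
                    "LD": np.round(ld, 1),
                    "MIND": np.round(mind, 1),
                    "MAXD": np.round(maxd, 1),
                },
            )

    s2_between = s2_ind + var_genetic
    truth = GroundTruth(
        event_years=tuple(cfg.drought_years),
        r_individual=s2_between / (s2_between + s2_res),
        sigma2_prov=s2_prov,
        sigma2_ind=s2_between,
        sigma2_res=s2_res,
        causal_markers=betas,
        provenance_of=provenance_of,
    )
    return out, truth


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class SimData:
    config: SimConfig
    stations: list[ClimateRecord]
    genotypes: GenotypeMatrix
    q: QMatrix
    rings: dict[tuple[str, str], RingSeries]
    truth: GroundTruth


def simulate_all(cfg: SimConfig) -> SimData:
    """Run all three generators off one seeded stream (deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    stations = simulate_climate(cfg, rng)
    G, Q = simulate_genotypes(cfg, rng)
    # shared warm-year signal: mean June-August temperature anomaly
    t = stations[0].table["tmean_c"]
    summer = t[t.index.get_level_values("month").isin((6, 7, 8))]
    anomaly = summer.groupby(level="year").mean()
    anomaly = anomaly - anomaly.mean()
    rings, truth = simulate_rings(cfg, G, rng, temperature_signal=anomaly)
    truth.q = Q
    return SimData(config=cfg, stations=stations, genotypes=G, q=Q, rings=rings, truth=truth)


def write_sim_data(data: SimData, out_dir) -> dict[str, str]:
    """Write the bundle as plain-text artifacts; returns path map."""
    import os

    from .io_core import (
        dump_toml,
        write_climate_csv,
        write_geno_csv,
        write_long_csv,
        write_q_csv,
        write_rwl,
        write_stations_csv,
        write_vcf,
    )

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "climate": os.path.join(out_dir, "climate.csv"),
        "stations": os.path.join(out_dir, "stations.csv"),
        "rings": os.path.join(out_dir, "rings.csv"),
        "rwl": os.path.join(out_dir, "rings.rwl"),
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "geno_csv": os.path.join(out_dir, "genotypes.csv"),
        "markers": os.path.join(out_dir, "markers.csv"),
        "q": os.path.join(out_dir, "qmatrix.csv"),
        "truth": os.path.join(out_dir, "groundtruth.toml"),
    }
    write_climate_csv(data.stations, paths["climate"])
    write_stations_csv(data.stations, paths["stations"])
    write_long_csv(data.rings, paths["rings"])
    rwl_map = {
        f"{i:08d}"[:8]: s for i, s in enumerate(data.rings.values())
    }
    write_rwl(rwl_map, paths["rwl"])
    write_vcf(data.genotypes, paths["vcf"])
    write_geno_csv(data.genotypes, paths["geno_csv"], paths["markers"])
    write_q_csv(data.q, paths["q"])
    t = data.truth
    dump_toml(
        {
            "event_years": list(t.event_years),
            "r_individual": t.r_individual,
            "sigma2_prov": t.sigma2_prov,
            "sigma2_ind": t.sigma2_ind,
            "sigma2_res": t.sigma2_res,
            "causal": {k: float(v) for k, v in t.causal_markers.items()},
        },
        paths["truth"],
    )
    return paths
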
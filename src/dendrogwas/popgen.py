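"""SNP QC, neutral-marker selection, centered-IBS kinship, HWE and global Fst."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, KinshipMatrix, get_logger

log = get_logger("popgen")


@dataclass
class SnpQCStats:
    marker_id: str
    maf: float  # minor allele frequency on non-missing calls
    call_rate: float
    monomorphic: bool
    hwe_p: float = float("nan")


def _allele_stats(codes: np.ndarray) -> tuple[float, float, int]:
    """(alt allele frequency, call rate, n called) for one marker column."""
    called = codes != MISSING
    n = int(called.sum())
    if n == 0:
        return float("nan"), 0.0, 0
    p_alt = float(codes[called].sum()) / (2 * n)
    return p_alt, n / len(codes), n


def snp_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    with_hwe: bool = False,
) -> tuple[GenotypeMatrix, list[SnpQCStats]]:
    """Filter markers by MAF >= ``maf_min`` and missingness <= ``max_missing``.

    Returns the filtered matrix plus per-marker stats for every input marker.
    """
    stats_out: list[SnpQCStats] = []
    keep: list[str] = []
    for j, mid in enumerate(G.markers):
        codes = G.codes[:, j]
        p_alt, call_rate, n = _allele_stats(codes)
        maf = min(p_alt, 1 - p_alt) if n else float("nan")
        mono = n > 0 and (p_alt == 0.0 or p_alt == 1.0)
        hwe_p = float("nan")
        if with_hwe and n:
            called = codes[codes != MISSING]
            hwe_p = hwe_exact(
                int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum())
            )
        stats_out.append(SnpQCStats(mid, maf, call_rate, mono, hwe_p))
        if n and maf >= maf_min and (1 - call_rate) <= max_missing:
            keep.append(mid)
    log.info("SNP QC: %d of %d markers pass", len(keep), G.n_markers)
    if not keep:
        raise ValueError("no markers pass QC")
    return G.subset_markers(keep), stats_out


def select_neutral(
    G: GenotypeMatrix, maf_min: float = 0.15, contexts=("intron", "intergenic", "upstream", "downstream")
) -> list[str]:
    """Neutral-marker subset: non-exonic context, 100% call rate, MAF strictly
    above ``maf_min``."""
    if not len(G.metadata) or "gene_context" not in G.metadata.columns:
        raise ValueError("gene_context metadata required for neutral-marker selection")
    missing_meta = [
        m
        for m in G.markers
        if m not in G.metadata.index or not str(G.metadata.loc[m, "gene_context"])
    ]
    if missing_meta:
        raise ValueError(f"markers lacking gene_context metadata: {missing_meta[:10]}")
    out = []
    for j, mid in enumerate(G.markers):
        if G.metadata.loc[mid, "gene_context"] not in contexts:
            continue
        p_alt, call_rate, n = _allele_stats(G.codes[:, j])
        if call_rate < 1.0 or n == 0:
            continue
        if min(p_alt, 1 - p_alt) > maf_min:
            out.append(mid)
    return out


def centered_ibs_kinship(G: GenotypeMatrix, scaling: str = "vanraden") -> KinshipMatrix:
    """Centered-IBS genomic relationship matrix.

    Missing calls are imputed to the marker mean (2 p-hat); columns are
    centered by 2 p-hat; monomorphic markers are dropped.  ``vanraden``
    divides X X' by sum_j 2 p_j (1 - p_j); ``tassel`` divides by the marker
    count (the two differ by a constant factor, which downstream mixed models
    absorb into the genetic variance).
    """
    codes = G.codes.astype(float)
    codes[codes == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic markers for kinship")
    codes = codes[:, poly]
    p = p[poly]
    X = np.where(np.isnan(codes), 0.0, codes - 2 * p)  # imputed cells center to 0
    if scaling == "vanraden":
        denom = float(np.sum(2 * p * (1 - p)))
    elif scaling == "tassel":
        denom = float(len(p))
    else:
        raise ValueError(f"unknown kinship scaling {scaling!r}")
    K = X @ X.T / denom
    return KinshipMatrix(list(G.individuals), K)


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote configurations no more probable than the observed one.
    """
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("genotype counts must be non-negative and sum to >= 1")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab  # rarer-allele bookkeeping is symmetric; use as-is
    n_a = min(n_a, 2 * n - n_a)
    hets = range(n_a % 2, n_a + 1, 2)
    logs = []
    lgamma = math.lgamma
    for h in hets:
        hom_a = (n_a - h) // 2
        hom_b = n - hom_a - h
        ll = (
            lgamma(n + 1)
            - lgamma(hom_a + 1)
            - lgamma(h + 1)
            - lgamma(hom_b + 1)
            + h * math.log(2)
            + lgamma(n_a + 1)
            + lgamma(2 * n - n_a + 1)
            - lgamma(2 * n + 1)
        )
        logs.append(ll)
    probs = np.exp(np.array(logs) - max(logs))
    probs /= probs.sum()
    obs = list(hets).index(n_ab)
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


def global_fst(
    G: GenotypeMatrix, provenances: pd.Series, estimator: str = "weir-cockerham"
) -> tuple[float, pd.Series]:
    """Global Weir-Cockerham theta over loci (ratio of sums) plus per-locus
    values.  Populations contributing no calls at a locus are skipped there.
    """
    if estimator != "weir-cockerham":
        raise ValueError("only the Weir-Cockerham 1984 estimator is implemented")
    prov = provenances.reindex(G.individuals)
    labels = prov.dropna().unique()
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    num_sum = 0.0
    den_sum = 0.0
    per_locus = {}
    groups = {lab: np.array([i for i, ind in enumerate(G.individuals) if prov.iloc[i] == lab]) for lab in labels}
    for j, mid in enumerate(G.markers):
        ns, ps, hs = [], [], []
        for lab in labels:
            codes = G.codes[groups[lab], j]
            called = codes[codes != MISSING]
            if len(called) < 2:
                continue
            ns.append(len(called))
            ps.append(called.sum() / (2 * len(called)))
            hs.append(np.mean(called == 1))
        r = len(ns)
        if r < 2:
            per_locus[mid] = float("nan")
            continue
        ns = np.array(ns, dtype=float)
        ps = np.array(ps)
        hs = np.array(hs)
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        pbar = (ns * ps).sum() / (r * nbar)
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / (r * nbar)
        if nbar <= 1 or nc <= 0:
            per_locus[mid] = float("nan")
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        denom = a + b + c
        per_locus[mid] = a / denom if denom != 0 else float("nan")
        if np.isfinite(denom):
            num_sum += a
            den_sum += denom
    theta = num_sum / den_sum if den_sum != 0 else float("nan")
    return float(theta), pd.Series(per_locus, name="theta")
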
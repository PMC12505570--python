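"""Pool-seq differentiation scan, outlier windows and candidate genes.

Two per-site Fst estimators are available for pooled read counts:

``classical``
    The PoPoolation2-style estimator (pi_total - mean pi_within) / pi_total
    with a finite-coverage correction C/(C-1) on each heterozygosity, the
    effective allele count capped at twice the pool size, and pi_total
    computed from the averaged pool frequencies with the min-coverage
    correction.  This mirrors the classical sliding-window tooling and is
    the default — but note that with only two demes its expectation is
    F/(2-F), not F, so it understates the model differentiation parameter.

``hudson``
    A Hudson-style ratio of averages on pool allele frequencies with the
    read-sampling correction f(1-f)/(C_eff - 1) subtracted from the
    numerator.  Unbiased for F under the Balding-Nichols model and used
    where the scan must estimate F itself.

Window Fst is the mean of defined site Fst values (classical, mirroring
the sliding-window tools) or the window-level ratio of summed components
(hudson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .io_formats import GeneModel, PoolSites, SubgenomeMap
from .subgenome_partition import HomeologPair

DEFAULT_FST_THRESHOLD = 0.15
DEFAULT_OUTLIER_QUANTILE = 0.01
DEFAULT_POOL_MIN_COV = 4
DEFAULT_POOL_MAX_COV = 50
DEFAULT_POOL_SIZE = 32


@dataclass
class OutlierWindow:
    chrom: str
    start: int
    end: int
    mean_fst: float
    n_sites: int
    subgenome: str = "unassigned"
    rank: int | None = None


@dataclass
class CandidateGene:
    gene_id: str
    base_symbol: str
    subgenome: str
    chrom: str
    max_snp_fst: float
    distance: int
    homeolog_status: str = "n/a"
    selection_pattern: str = "n/a"


# ---------------------------------------------------------------------------
# Site-level Fst
# ---------------------------------------------------------------------------

def _effective_alleles(coverage: np.ndarray, pool_size: int) -> np.ndarray:
    """Reads are draws from 2*pool_size chromosomes; beyond that depth adds
    no new alleles, so the correction uses min(C, 2*pool_size)."""
    return np.minimum(np.asarray(coverage, dtype=float), 2.0 * pool_size)


def pool_fst_sites(sites: PoolSites, pool_a: int = 0, pool_b: int = 1,
                   estimator: str = "classical") -> np.ndarray:
    """Per-site pool Fst between two pools; NaN where undefined."""
    c1 = sites.coverage[:, pool_a].astype(float)
    c2 = sites.coverage[:, pool_b].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = sites.alt_counts[:, pool_a] / c1
        f2 = sites.alt_counts[:, pool_b] / c2
    e1 = _effective_alleles(c1, sites.pool_size)
    e2 = _effective_alleles(c2, sites.pool_size)
    if estimator == "classical":
        with np.errstate(divide="ignore", invalid="ignore"):
            pi1 = 2.0 * f1 * (1 - f1) * e1 / (e1 - 1)
            pi2 = 2.0 * f2 * (1 - f2) * e2 / (e2 - 1)
            fbar = (f1 + f2) / 2.0
            emin = np.minimum(e1, e2)
            pit = 2.0 * fbar * (1 - fbar) * emin / (emin - 1)
            fst = (pit - (pi1 + pi2) / 2.0) / pit
        return np.where((pit > 0) & (e1 > 1) & (e2 > 1), fst, np.nan)
    if estimator == "hudson":
        num, den = pool_hudson_components(f1, e1, f2, e2)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = num / den
        return np.where(den > 0, fst, np.nan)
    raise ValueError(f"unknown estimator {estimator!r}")


def pool_hudson_components(f1, e1, f2, e2):
    """Hudson numerator/denominator on pool frequencies with read-sampling
    correction; NaN where an effective allele count is < 2."""
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (f1 - f2) ** 2 - f1 * (1 - f1) / (e1 - 1) - f2 * (1 - f2) / (e2 - 1)
        den = f1 * (1 - f2) + f2 * (1 - f1)
    ok = (e1 >= 2) & (e2 >= 2)
    return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


def pool_site_fst(ref1: int, alt1: int, ref2: int, alt2: int,
                  pool_size: int = DEFAULT_POOL_SIZE,
                  estimator: str = "classical") -> float:
    """Scalar convenience wrapper around :func:`pool_fst_sites`."""
    sites = PoolSites(np.array(["x"], dtype=object), np.array([1]),
                      np.array([[ref1, ref2]]), np.array([[alt1, alt2]]),
                      ["p1", "p2"], pool_size)
    return float(pool_fst_sites(sites, estimator=estimator)[0])


# ---------------------------------------------------------------------------
# Windowed scan and outliers
# ---------------------------------------------------------------------------

def pool_window_fst(sites: PoolSites, window_size: int = 100_000,
                    chrom_lengths: dict[str, int] | None = None,
                    min_sites: int = 1, pool_a: int = 0, pool_b: int = 1,
                    estimator: str = "classical",
                    sg: SubgenomeMap | None = None) -> list[OutlierWindow]:
    """Non-overlapping window Fst across all chromosomes.

    Windows with fewer than ``min_sites`` defined site values get NaN.
    """
    site_fst = pool_fst_sites(sites, pool_a, pool_b, estimator)
    if estimator == "hudson":
        c1 = sites.coverage[:, pool_a].astype(float)
        c2 = sites.coverage[:, pool_b].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f1 = sites.alt_counts[:, pool_a] / c1
            f2 = sites.alt_counts[:, pool_b] / c2
        num, den = pool_hudson_components(
            f1, _effective_alleles(c1, sites.pool_size),
            f2, _effective_alleles(c2, sites.pool_size))
    out: list[OutlierWindow] = []
    for chrom in dict.fromkeys(sites.chrom):
        on = np.flatnonzero(sites.chrom == chrom)
        pos0 = sites.pos[on] - 1
        length = (chrom_lengths or {}).get(chrom)
        if length is None:
            length = int(pos0.max()) + 1 if len(pos0) else window_size
        n_win = max(1, math.ceil(length / window_size))
        for k in range(n_win):
            start, end = k * window_size, min((k + 1) * window_size, length)
            lo, hi = np.searchsorted(pos0, [start, end])
            idx = on[lo:hi]
            if estimator == "hudson":
                n, d = num[idx], den[idx]
                ok = ~np.isnan(d)
                val = float(n[ok].sum() / d[ok].sum()) \
                    if ok.sum() >= min_sites and d[ok].sum() > 0 else math.nan
                n_def = int(ok.sum())
            else:
                vals = site_fst[idx]
                vals = vals[~np.isnan(vals)]
                n_def = len(vals)
                val = float(vals.mean()) if n_def >= min_sites else math.nan
            out.append(OutlierWindow(chrom, start, end, val, n_def,
                                     sg.subgenome_of(chrom) if sg else "unassigned"))
    return out


def select_outliers(windows: list[OutlierWindow],
                    quantile: float = DEFAULT_OUTLIER_QUANTILE
                    ) -> list[OutlierWindow]:
    """Top ceil(quantile * N_defined) windows by mean Fst, descending.

    Ties broken by (chrom, start); ranks assigned 1..k.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    defined = [w for w in windows if not math.isnan(w.mean_fst)]
    k = math.ceil(quantile * len(defined))
    ordered = sorted(defined, key=lambda w: (-w.mean_fst, w.chrom, w.start))
    top = ordered[:k]
    for r, w in enumerate(top, 1):
        w.rank = r
    return top


def subgenome_enrichment(outliers: list[OutlierWindow],
                         all_windows: list[OutlierWindow],
                         sg: SubgenomeMap) -> dict[str, float]:
    """Is the L sub-genome over-represented among outlier windows?

    Exact two-sided binomial test of the L count among outliers against
    the background L proportion of all defined windows.  (The underlying
    study reports the two proportions only; the test is an extension.)
    """
    if not outliers:
        return {"prop_L_outlier": math.nan, "prop_L_background": math.nan,
                "binomial_p": math.nan}
    bg = [w for w in all_windows if not math.isnan(w.mean_fst)
          and sg.subgenome_of(w.chrom) in ("L", "S")]
    ol = [w for w in outliers if sg.subgenome_of(w.chrom) in ("L", "S")]
    p_bg = sum(sg.subgenome_of(w.chrom) == "L" for w in bg) / len(bg)
    k = sum(sg.subgenome_of(w.chrom) == "L" for w in ol)
    res = binomtest(k, len(ol), p_bg, alternative="two-sided")
    return {"prop_L_outlier": k / len(ol), "prop_L_background": p_bg,
            "binomial_p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Candidate genes near high-Fst SNPs
# ---------------------------------------------------------------------------

def high_fst_sites_in_windows(sites: PoolSites, site_fst: np.ndarray,
                              windows: list[OutlierWindow],
                              fst_threshold: float = DEFAULT_FST_THRESHOLD):
    """(chrom, pos, fst) arrays for SNPs at/above threshold inside the
    given windows — the pipeline's anchor set for the gene-proximity step."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        spans.setdefault(w.chrom, []).append((w.start, w.end))
    keep = np.zeros(sites.n_sites, dtype=bool)
    for chrom, ivs in spans.items():
        on = sites.chrom == chrom
        p0 = sites.pos - 1
        for s, e in ivs:
            keep |= on & (p0 >= s) & (p0 < e)
    keep &= ~np.isnan(site_fst) & (site_fst >= fst_threshold)
    return sites.chrom[keep], sites.pos[keep], site_fst[keep]


def genes_near_outlier_snps(site_chrom: np.ndarray, site_pos: np.ndarray,
                            site_fst: np.ndarray, genes: list[GeneModel],
                            sg: SubgenomeMap | None = None,
                            fst_threshold: float = DEFAULT_FST_THRESHOLD,
                            max_dist: int = 10_000) -> list[CandidateGene]:
    """Genes whose interval lies within ``max_dist`` bp of a SNP with
    Fst >= ``fst_threshold``; distance 0 when the SNP falls inside the
    gene, strand-agnostic, compared with <=."""
    site_fst = np.asarray(site_fst, dtype=float)
    hi = ~np.isnan(site_fst) & (site_fst >= fst_threshold)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(np.asarray(site_chrom, dtype=object)[hi]):
        on = hi & (site_chrom == c)
        order = np.argsort(site_pos[on])
        by_chrom[str(c)] = (np.asarray(site_pos)[on][order],
                            site_fst[on][order])
    out: list[CandidateGene] = []
    for g in genes:
        if g.chrom not in by_chrom:
            continue
        pos, fst = by_chrom[g.chrom]
        dist = np.where(pos < g.start, g.start - pos,
                        np.where(pos > g.end, pos - g.end, 0))
        near = dist <= max_dist
        if not near.any():
            continue
        out.append(CandidateGene(
            g.gene_id, g.base_symbol,
            sg.subgenome_of(g.chrom) if sg else g.homeolog_tag,
            g.chrom, float(fst[near].max()), int(dist[near].min())))
    return out


def classify_homeolog_selection(candidates: list[CandidateGene],
                                pairs: list[HomeologPair]
                                ) -> list[CandidateGene]:
    """Annotate candidates with homeolog retention and whether the
    differentiation signal hits both retained copies or only one.

    both_copies: both homeologs independently qualify as candidates;
    one_copy: a retained pair with exactly one qualifying copy;
    single_copy: an L-only or S-only gene.
    """
    status = {p.base_symbol: p.status for p in pairs}
    cand_ids = {c.gene_id for c in candidates}
    pair_genes = {p.base_symbol: (p.gene_l, p.gene_s) for p in pairs}
    for c in candidates:
        st = status.get(c.base_symbol)
        if st is None:
            c.homeolog_status, c.selection_pattern = "n/a", "n/a"
            continue
        c.homeolog_status = st
        if st in ("L-only", "S-only"):
            c.selection_pattern = "single_copy"
            continue
        gl, gs = pair_genes[c.base_symbol]
        both = gl.gene_id in cand_ids and gs.gene_id in cand_ids
        c.selection_pattern = "both_copies" if both else "one_copy"
    return candidates


def candidates_to_dataframe(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": c.gene_id, "base_symbol": c.base_symbol,
        "subgenome": c.subgenome, "chrom": c.chrom,
        "max_snp_fst": c.max_snp_fst, "distance_bp": c.distance,
        "homeolog_status": c.homeolog_status,
        "selection_pattern": c.selection_pattern,
    } for c in candidates])


def outlier_windows_to_dataframe(windows: list[OutlierWindow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": w.chrom, "start": w.start, "end": w.end,
        "mean_fst": w.mean_fst, "n_sites": w.n_sites,
        "subgenome": w.subgenome, "rank": w.rank,
    } for w in windows])
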
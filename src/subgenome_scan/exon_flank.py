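"""Background-selection test: diversity in exon-centred windows.

Purifying selection on coding sites depresses linked neutral diversity
(background selection), so per-site nucleotide diversity averaged over a
window spanning an exon plus its flanks should sit below the genomic
average, and equally so on both sub-genomes if they experience the same
selective regime.

Windows default to the exon body plus a 10 kb flank on each side
(``anchor='exon'``); ``anchor='midpoint'`` instead takes a fixed
2*flank-wide window centred on the exon midpoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenotypeMatrix, PopulationMap, SubgenomeMap
from .popgen_core import site_pi_vector
from .subgenome_partition import ZTestResult, compare_subgenomes

logger = logging.getLogger("subgenome_scan")

DEFAULT_FLANK = 10_000

CATEGORIES = ("first", "last", "single")


@dataclass
class ExonFlankRecord:
    """One exon-centred window (0-based half-open span)."""

    gene_id: str
    exon_category: str   # 'first', 'last' or 'single'
    subgenome: str       # 'L', 'S' or 'unassigned'
    chrom: str
    start: int
    end: int
    clipped: bool = False
    n_variant_sites: int = 0
    mean_site_pi: float = math.nan


def extract_exon_windows(genes: list[GeneModel], sg: SubgenomeMap,
                         flank: int = DEFAULT_FLANK,
                         chrom_lengths: dict[str, int] | None = None,
                         anchor: str = "exon") -> list[ExonFlankRecord]:
    """One record per qualifying exon: first and last exons of multi-exon
    genes, the sole exon of single-exon genes.

    Spans are clipped at chromosome bounds (flagged).  Overlapping windows
    from adjacent genes are kept independently.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if anchor not in ("exon", "midpoint"):
        raise ValueError(f"unknown anchor {anchor!r}")
    out: list[ExonFlankRecord] = []
    for g in genes:
        if g.n_exons == 1:
            picks = [(0, "single")]
        else:
            picks = [(0, "first"), (g.n_exons - 1, "last")]
        for i, cat in picks:
            s1, e1 = g.exons[i]           # 1-based inclusive
            lo, hi = min(s1, e1) - 1, max(s1, e1)  # 0-based half-open
            if anchor == "exon":
                start, end = lo - flank, hi + flank
            else:
                mid = (lo + hi) // 2
                start, end = mid - flank, mid + flank
            clipped = False
            if start < 0:
                start, clipped = 0, True
            length = (chrom_lengths or {}).get(g.chrom)
            if length is not None and end > length:
                end, clipped = length, True
            out.append(ExonFlankRecord(g.gene_id, cat, sg.subgenome_of(g.chrom),
                                       g.chrom, int(start), int(end), clipped))
    return out


def exon_window_pi(gm: GenotypeMatrix, records: list[ExonFlankRecord],
                   pops: PopulationMap, population: str,
                   include_admixed: bool = False) -> list[ExonFlankRecord]:
    """Fill each record with the mean per-site pi over variant sites in its
    span, for one population (non-admixed members by default).

    Records whose span holds no usable variant site keep NaN.
    """
    idx = pops.sample_index(gm.sample_ids, population, include_admixed)
    if len(idx) == 0:
        raise ValueError(f"population {population!r} has no usable samples")
    alt, called = gm.allele_counts(idx)
    pi = site_pi_vector(alt, called)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in dict.fromkeys(gm.chrom):
        on = np.flatnonzero(gm.chrom == c)
        by_chrom[c] = (gm.pos[on] - 1, pi[on])  # 0-based positions
    for r in records:
        if r.end <= r.start:
            raise ValueError(f"empty span for {r.gene_id} {r.exon_category}")
        pos0, pvals = by_chrom.get(r.chrom, (np.array([]), np.array([])))
        lo, hi = np.searchsorted(pos0, [r.start, r.end])
        vals = pvals[lo:hi]
        vals = vals[~np.isnan(vals)]
        r.n_variant_sites = int(len(vals))
        r.mean_site_pi = float(vals.mean()) if len(vals) else math.nan
    return records


def genome_mean_site_pi(gm: GenotypeMatrix, pops: PopulationMap,
                        population: str, include_admixed: bool = False
                        ) -> tuple[float, np.ndarray]:
    """Genome-wide mean per-site pi and the per-site vector it averages."""
    idx = pops.sample_index(gm.sample_ids, population, include_admixed)
    alt, called = gm.allele_counts(idx)
    pi = site_pi_vector(alt, called)
    pi = pi[~np.isnan(pi)]
    return (float(pi.mean()) if len(pi) else math.nan), pi


def flank_comparison(records: list[ExonFlankRecord],
                     whole_genome_values: np.ndarray | None = None,
                     method: str = "z") -> pd.DataFrame:
    """Per-category L-vs-S (and optionally vs-whole-genome) mean tests.

    Categories: each of first/last/single plus 'all' pooled.  Empty or
    single-record groups are skipped with a log entry.
    ``whole_genome_values`` is a reference distribution of per-site (or
    per-window) pi for the L-vs-whole and S-vs-whole rows.
    """
    df = pd.DataFrame([(r.exon_category, r.subgenome, r.mean_site_pi)
                       for r in records],
                      columns=["category", "subgenome", "pi"]).dropna()
    rows = []
    for cat in ("all",) + CATEGORIES:
        sub = df if cat == "all" else df[df["category"] == cat]
        groups = {"L": sub.loc[sub["subgenome"] == "L", "pi"].to_numpy(),
                  "S": sub.loc[sub["subgenome"] == "S", "pi"].to_numpy()}
        comparisons = [("L", "S", groups["L"], groups["S"])]
        if whole_genome_values is not None:
            comparisons += [("L", "whole", groups["L"], whole_genome_values),
                            ("S", "whole", groups["S"], whole_genome_values)]
        for g1, g2, v1, v2 in comparisons:
            try:
                res: ZTestResult = compare_subgenomes(v1, v2, method=method)
            except ValueError:
                logger.info("flank_comparison: %s %s-vs-%s skipped (too few records)",
                            cat, g1, g2)
                continue
            rows.append({"category": cat, "comparison": f"{g1}_vs_{g2}",
                         "mean_1": float(np.mean(v1)), "mean_2": float(np.mean(v2)),
                         "z": res.z, "p_two_sided": res.p_two_sided,
                         "n_1": res.n1, "n_2": res.n2})
    return pd.DataFrame(rows)


def records_to_dataframe(records: list[ExonFlankRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "exon_category": r.exon_category,
        "subgenome": r.subgenome, "chrom": r.chrom, "start": r.start,
        "end": r.end, "clipped": int(r.clipped),
        "n_variant_sites": r.n_variant_sites, "mean_site_pi": r.mean_site_pi,
    } for r in records])
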
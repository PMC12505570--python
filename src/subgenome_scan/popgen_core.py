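"""Per-site and windowed population-genetic statistics.

All estimators are authored here rather than delegated: per-site nucleotide
diversity (unbiased heterozygosity), Tajima's D, Hudson's Fst as a window
ratio-of-averages, absolute divergence dxy, allele-sharing classification,
and allele-frequency spectra.

Undefined statistics are returned as NaN, never 0: a window with too few
usable sites, a site with fewer than two called alleles, or a zero Fst
denominator all yield NaN.

The pi/dxy denominator mode matters enormously and is explicit everywhere:
``per_site`` (default) averages over variant sites only, matching a
compute-per-site-then-average procedure; ``per_bp`` divides the same sums
by the window span, giving the familiar orders-of-magnitude-smaller per-bp
diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import GenotypeMatrix, PopulationMap

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_MIN_SITES = 10


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------

def site_pi(alt_count: int, called_alleles: int) -> float:
    """Unbiased per-site heterozygosity: differing pairs / total pairs.

    Equals 2*j*(n-j) / (n*(n-1)) for j alt alleles among n called.
    NaN when fewer than two alleles are called.
    """
    if called_alleles < 2:
        return math.nan
    if not 0 <= alt_count <= called_alleles:
        raise ValueError("alt_count outside [0, called_alleles]")
    n = called_alleles
    return 2.0 * alt_count * (n - alt_count) / (n * (n - 1))


def site_pi_vector(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Vectorised :func:`site_pi`; NaN where called < 2."""
    alt = np.asarray(alt, dtype=float)
    called = np.asarray(called, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * alt * (called - alt) / (called * (called - 1.0))
    return np.where(called >= 2, pi, np.nan)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1,a2,b1,b2,c1,c2,e1,e2 constants for a sample of n alleles."""
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 alleles")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n_alleles: int, n_segregating: int, sum_site_pi: float) -> float:
    """Tajima's D from allele count, segregating sites and summed site pi.

    ``sum_site_pi`` is the mean number of pairwise differences (the sum of
    per-site heterozygosity over the region).  NaN when S = 0.
    """
    if n_segregating < 0:
        raise ValueError("negative segregating-site count")
    if n_segregating == 0:
        return math.nan
    c = tajima_constants(n_alleles)
    s = n_segregating
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    if var <= 0:
        return math.nan
    return (sum_site_pi - s / c["a1"]) / math.sqrt(var)


def hudson_components(ac1, n1, ac2, n2):
    """Per-site Hudson Fst numerator and denominator.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)

    NaN where either population has fewer than 2 called alleles.
    """
    ac1 = np.asarray(ac1, dtype=float); n1 = np.asarray(n1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float); n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ac1 / n1
        p2 = ac2 / n2
        num = (p1 - p2) ** 2 \
            - p1 * (1 - p1) / (n1 - 1) \
            - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    usable = (n1 >= 2) & (n2 >= 2)
    return np.where(usable, num, np.nan), np.where(usable, den, np.nan)


def hudson_fst_window(ac1, n1, ac2, n2) -> float:
    """Hudson (1992) ratio-of-averages Fst over the sites given.

    Mean per-site numerator over mean per-site denominator; robust to
    unequal sample sizes.  NaN when no site is usable or the summed
    denominator is zero.
    """
    num, den = hudson_components(ac1, n1, ac2, n2)
    ok = ~np.isnan(den)
    if not ok.any():
        return math.nan
    d = den[ok].sum()
    if d == 0:
        return math.nan
    return float(num[ok].sum() / d)


def dxy_sites(ac1, n1, ac2, n2) -> np.ndarray:
    """Per-site absolute divergence p1(1-p2) + p2(1-p1); NaN if unusable."""
    ac1 = np.asarray(ac1, dtype=float); n1 = np.asarray(n1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float); n2 = np.asarray(n2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ac1 / n1
        p2 = ac2 / n2
        d = p1 * (1 - p2) + p2 * (1 - p1)
    return np.where((n1 >= 1) & (n2 >= 1), d, np.nan)


def dxy_window(ac1, n1, ac2, n2, span: int | None = None) -> float:
    """Window dxy: mean over usable variant sites, or summed over ``span``
    base pairs when a span is given (per-bp mode)."""
    d = dxy_sites(ac1, n1, ac2, n2)
    ok = ~np.isnan(d)
    if not ok.any():
        return math.nan
    if span is not None:
        return float(d[ok].sum() / span)
    return float(d[ok].mean())


# ---------------------------------------------------------------------------
# Allele-sharing classification
# ---------------------------------------------------------------------------

class SharingClass(Enum):
    MONOMORPHIC = "monomorphic"
    FIXED_DIFFERENCE = "fixed_difference"
    PRIVATE = "private"
    SHARED = "shared"
    UNDEFINED = "undefined"


def classify_sharing(ac_by_pop: dict[str, tuple[int, int]]
                     ) -> tuple[SharingClass, str | None]:
    """Classify one site from per-population (alt_count, called_alleles).

    Returns (class, population) where the population is set only for
    PRIVATE.  Populations with zero called alleles are ignored; with fewer
    than two informative populations the class is UNDEFINED.
    """
    informative = {p: (a, n) for p, (a, n) in ac_by_pop.items() if n > 0}
    if len(informative) < 2:
        return SharingClass.UNDEFINED, None
    segregating = [p for p, (a, n) in informative.items() if 0 < a < n]
    if len(segregating) >= 2:
        return SharingClass.SHARED, None
    if len(segregating) == 1:
        return SharingClass.PRIVATE, segregating[0]
    # every population fixed: same allele everywhere -> monomorphic
    fixed_states = {a // n for p, (a, n) in informative.items()}  # 0 or 1
    if len(fixed_states) > 1:
        return SharingClass.FIXED_DIFFERENCE, None
    return SharingClass.MONOMORPHIC, None


def sharing_percentages(gm: GenotypeMatrix, pops: PopulationMap,
                        include_admixed: bool = False) -> pd.DataFrame:
    """Per-site sharing classes tabulated as percentages of classified sites."""
    pop_idx = {p: pops.sample_index(gm.sample_ids, p, include_admixed)
               for p in pops.populations()}
    acs = {p: gm.allele_counts(ix) for p, ix in pop_idx.items()}
    rows = []
    for i in range(gm.n_sites):
        cls, who = classify_sharing({p: (int(a[i]), int(n[i]))
                                     for p, (a, n) in acs.items()})
        rows.append((cls.value, who))
    df = pd.DataFrame(rows, columns=["sharing_class", "population"])
    df = df[df["sharing_class"] != SharingClass.UNDEFINED.value]
    counts = df.groupby(["sharing_class", "population"], dropna=False).size()
    out = counts.rename("n_sites").reset_index()
    out["percent"] = 100.0 * out["n_sites"] / out["n_sites"].sum()
    return out


# ---------------------------------------------------------------------------
# Allele-frequency spectrum
# ---------------------------------------------------------------------------

def afs(freqs: np.ndarray, n_bins: int = 10, folded: bool = False) -> np.ndarray:
    """Histogram of allele frequencies over equal-width bins on (0, 1].

    Folded spectra fold around 0.5 first (bins then cover (0, 0.5]).
    The bin totals sum to the number of input sites; frequency 0 falls in
    the first bin.
    """
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        return np.zeros(n_bins, dtype=np.int64)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies outside [0, 1]")
    top = 0.5 if folded else 1.0
    if folded:
        f = np.minimum(f, 1.0 - f)
    counts, _ = np.histogram(f, bins=n_bins, range=(0.0, top))
    return counts.astype(np.int64)


# ---------------------------------------------------------------------------
# Windowed genome scan
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    """One genome-scan window (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    n_variant_sites: int
    pi: dict[str, float] = field(default_factory=dict)
    tajima_d: dict[str, float] = field(default_factory=dict)
    fst: dict[tuple[str, str], float] = field(default_factory=dict)
    dxy: dict[tuple[str, str], float] = field(default_factory=dict)
    partial: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


def window_scan(gm: GenotypeMatrix, pops: PopulationMap,
                window_size: int = DEFAULT_WINDOW_SIZE,
                chrom_lengths: dict[str, int] | None = None,
                min_sites: int = DEFAULT_MIN_SITES,
                mode: str = "per_site",
                include_admixed: bool = False) -> list[WindowStat]:
    """Non-overlapping windows tiled from position 0 on each chromosome.

    Per window and population: pi and Tajima's D; per population pair:
    Hudson Fst (ratio of averages) and dxy.  Windows with fewer than
    ``min_sites`` usable sites get NaN statistics but keep their site
    count.  A trailing partial window is emitted with its true span and
    ``partial=True``.

    ``mode`` selects the pi/dxy denominator: "per_site" averages over
    variant sites, "per_bp" divides by the window span.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if mode not in ("per_site", "per_bp"):
        raise ValueError(f"unknown mode {mode!r}")
    pop_names = pops.populations()
    pops.validate(gm.sample_ids)
    pop_idx = {p: pops.sample_index(gm.sample_ids, p, include_admixed)
               for p in pop_names}
    acs = {p: gm.allele_counts(ix) for p, ix in pop_idx.items()}
    pairs = [(a, b) for i, a in enumerate(pop_names) for b in pop_names[i + 1:]]

    out: list[WindowStat] = []
    for chrom in dict.fromkeys(gm.chrom):
        on = np.flatnonzero(gm.chrom == chrom)
        pos0 = gm.pos[on] - 1  # 0-based
        length = (chrom_lengths or {}).get(chrom)
        if length is None:
            length = int(pos0.max()) + 1 if len(pos0) else window_size
        n_full, rem = divmod(length, window_size)
        edges = [(k * window_size, (k + 1) * window_size, False)
                 for k in range(n_full)]
        if rem:
            edges.append((n_full * window_size, length, True))
        for start, end, partial in edges:
            lo, hi = np.searchsorted(pos0, [start, end])
            idx = on[lo:hi]
            w = WindowStat(chrom, int(start), int(end), int(hi - lo),
                           partial=partial)
            span = end - start
            denom_ok = w.n_variant_sites >= min_sites
            for p in pop_names:
                alt, called = acs[p][0][idx], acs[p][1][idx]
                pi = site_pi_vector(alt, called)
                usable = ~np.isnan(pi)
                if not denom_ok or not usable.any():
                    w.pi[p] = math.nan
                    w.tajima_d[p] = math.nan
                    continue
                pi_sum = float(pi[usable].sum())
                if mode == "per_bp":
                    w.pi[p] = pi_sum / span
                else:
                    w.pi[p] = pi_sum / int(usable.sum())
                seg = int(((alt > 0) & (alt < called) & usable).sum())
                n_bar = int(round(called[usable].mean()))
                w.tajima_d[p] = tajimas_d(n_bar, seg, pi_sum) if n_bar >= 4 \
                    else math.nan
            for a, b in pairs:
                if not denom_ok:
                    w.fst[(a, b)] = math.nan
                    w.dxy[(a, b)] = math.nan
                    continue
                a1, c1 = acs[a][0][idx], acs[a][1][idx]
                a2, c2 = acs[b][0][idx], acs[b][1][idx]
                w.fst[(a, b)] = hudson_fst_window(a1, c1, a2, c2)
                w.dxy[(a, b)] = dxy_window(
                    a1, c1, a2, c2, span=span if mode == "per_bp" else None)
            out.append(w)
    return out


def windows_to_dataframe(windows: list[WindowStat]) -> pd.DataFrame:
    """Tidy one-row-per-window table (popgenWindows-style columns)."""
    rows = []
    for w in windows:
        row: dict = {"chrom": w.chrom, "start": w.start, "end": w.end,
                     "n_sites": w.n_variant_sites, "partial": int(w.partial)}
        for p, v in w.pi.items():
            row[f"pi_{p}"] = v
        for p, v in w.tajima_d.items():
            row[f"taj_d_{p}"] = v
        for (a, b), v in w.fst.items():
            row[f"fst_{a}_{b}"] = v
        for (a, b), v in w.dxy.items():
            row[f"dxy_{a}_{b}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham alternative estimator (flagged option)
# ---------------------------------------------------------------------------

def weir_cockerham_fst_window(ac1, n1, ac2, n2) -> float:
    """Weir & Cockerham (1984) theta-hat over a window (two populations,
    ratio of summed variance components).  Offered as an alternative to the
    Hudson default."""
    ac1 = np.asarray(ac1, dtype=float); n1 = np.asarray(n1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float); n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        return math.nan
    ac1, n1, ac2, n2 = ac1[ok], n1[ok], ac2[ok], n2[ok]
    # haploid-equivalent sample sizes (allele counts)
    p1, p2 = ac1 / n1, ac2 / n2
    nbar = (n1 + n2) / 2.0
    r = 2.0
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (ac1 + ac2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = 0.0  # allele-count formulation: no within-individual term
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = (a + b + c).sum()
    if denom == 0:
        return math.nan
    return float(a.sum() / denom)


def two_sided_normal_p(z: float) -> float:
    """Two-sided p-value from a standard-normal statistic."""
    return float(2.0 * norm.sf(abs(z)))
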
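"""Split genome-wide results by L/S sub-genome and compare the two halves.

The allotetraploid genome carries two co-resident sub-genomes (L and S)
that do not recombine with each other; every windowed statistic can
therefore be partitioned by chromosome and the two distributions compared
with a large-sample two-sample z-test (Welch's t offered for small window
counts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .io_formats import GeneModel, SubgenomeMap
from .popgen_core import WindowStat

logger = logging.getLogger("subgenome_scan")


@dataclass
class SubgenomeSummary:
    scope: str       # 'whole', 'L' or 'S'
    statistic: str
    mean: float
    sd: float
    n_windows: int


@dataclass
class ZTestResult:
    z: float
    p_two_sided: float
    n1: int
    n2: int
    method: str = "z"


def partition_windows(windows: list[WindowStat], sg: SubgenomeMap
                      ) -> dict[str, list[WindowStat]]:
    """Disjoint partition of windows into L / S / unassigned buckets."""
    out: dict[str, list[WindowStat]] = {"L": [], "S": [], "unassigned": []}
    for w in windows:
        out[sg.subgenome_of(w.chrom)].append(w)
    return out


def compare_subgenomes(values_l, values_s, method: str = "z") -> ZTestResult:
    """Two-sample test of equal means between per-window statistic vectors.

    The default is the large-sample z-test
    z = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with a two-sided normal
    p-value; ``method='welch'`` uses the Welch t reference distribution
    instead (useful at small window counts).  NaN entries are removed
    first.  Degenerate zero-variance input yields p = 1 when the means are
    equal and p = 0 otherwise.
    """
    x = np.asarray(values_l, dtype=float)
    y = np.asarray(values_s, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 finite values per group")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if m1 == m2:
            return ZTestResult(0.0, 1.0, n1, n2, method)
        return ZTestResult(math.copysign(math.inf, m1 - m2), 0.0, n1, n2, method)
    z = (m1 - m2) / math.sqrt(se2)
    if method == "welch":
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = float(2.0 * t_dist.sf(abs(z), df))
    elif method == "z":
        p = float(2.0 * norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return ZTestResult(float(z), p, n1, n2, method)


def _column_values(windows: list[WindowStat], statistic: str, key) -> np.ndarray:
    store = getattr(windows[0], statistic) if windows else {}
    if windows and key not in store:
        raise KeyError(f"{statistic} has no entry for {key!r}")
    return np.asarray([getattr(w, statistic).get(key, math.nan) for w in windows],
                      dtype=float)


def summarise_partition(windows: list[WindowStat], sg: SubgenomeMap
                        ) -> pd.DataFrame:
    """Whole / L / S mean +- sd for every statistic column, one row per
    (statistic, population-or-pair), mirroring a summary-table layout."""
    parts = partition_windows(windows, sg)
    scopes = {"whole": windows, "L": parts["L"], "S": parts["S"]}
    keys: list[tuple[str, object]] = []
    if windows:
        w0 = windows[0]
        keys += [("pi", p) for p in w0.pi]
        keys += [("tajima_d", p) for p in w0.tajima_d]
        keys += [("fst", pr) for pr in w0.fst]
        keys += [("dxy", pr) for pr in w0.dxy]
    rows = []
    for statistic, key in keys:
        label = key if isinstance(key, str) else f"{key[0]}_vs_{key[1]}"
        row: dict = {"statistic": statistic, "group": label}
        for scope, ws in scopes.items():
            vals = _column_values(ws, statistic, key) if ws else np.array([])
            vals = vals[~np.isnan(vals)]
            row[f"{scope}_mean"] = vals.mean() if len(vals) else math.nan
            row[f"{scope}_sd"] = vals.std(ddof=1) if len(vals) > 1 else math.nan
            row[f"{scope}_n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_partition(windows: list[WindowStat], sg: SubgenomeMap,
                      method: str = "z") -> pd.DataFrame:
    """L-vs-S test for every statistic column of the window table."""
    parts = partition_windows(windows, sg)
    keys: list[tuple[str, object]] = []
    if windows:
        w0 = windows[0]
        keys += [("pi", p) for p in w0.pi]
        keys += [("tajima_d", p) for p in w0.tajima_d]
        keys += [("fst", pr) for pr in w0.fst]
        keys += [("dxy", pr) for pr in w0.dxy]
    rows = []
    for statistic, key in keys:
        label = key if isinstance(key, str) else f"{key[0]}_vs_{key[1]}"
        try:
            res = compare_subgenomes(_column_values(parts["L"], statistic, key),
                                     _column_values(parts["S"], statistic, key),
                                     method=method)
        except ValueError:
            continue
        rows.append({"statistic": statistic, "group": label, "z": res.z,
                     "p_two_sided": res.p_two_sided, "n_L": res.n1, "n_S": res.n2})
    return pd.DataFrame(rows)


def summarise_windows_df(df: pd.DataFrame, sg: SubgenomeMap) -> pd.DataFrame:
    """Whole / L / S mean +- sd per numeric statistic column of a windows
    table (file-based pipeline counterpart of :func:`summarise_partition`)."""
    sub = df["chrom"].map(sg.subgenome_of)
    stat_cols = [c for c in df.columns
                 if c not in ("chrom", "start", "end", "n_sites", "partial")]
    rows = []
    for col in stat_cols:
        row: dict = {"column": col}
        for scope, mask in (("whole", np.ones(len(df), dtype=bool)),
                            ("L", (sub == "L").to_numpy()),
                            ("S", (sub == "S").to_numpy())):
            vals = pd.to_numeric(df.loc[mask, col], errors="coerce").dropna()
            row[f"{scope}_mean"] = vals.mean() if len(vals) else math.nan
            row[f"{scope}_sd"] = vals.std(ddof=1) if len(vals) > 1 else math.nan
            row[f"{scope}_n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_windows_df(df: pd.DataFrame, sg: SubgenomeMap,
                       method: str = "z") -> pd.DataFrame:
    """L-vs-S z-test per numeric statistic column of a windows table."""
    sub = df["chrom"].map(sg.subgenome_of)
    stat_cols = [c for c in df.columns
                 if c not in ("chrom", "start", "end", "n_sites", "partial")]
    rows = []
    for col in stat_cols:
        vl = pd.to_numeric(df.loc[(sub == "L").to_numpy(), col], errors="coerce")
        vs = pd.to_numeric(df.loc[(sub == "S").to_numpy(), col], errors="coerce")
        try:
            res = compare_subgenomes(vl, vs, method=method)
        except ValueError:
            continue
        rows.append({"column": col, "z": res.z, "p_two_sided": res.p_two_sided,
                     "n_L": res.n1, "n_S": res.n2})
    return pd.DataFrame(rows)


@dataclass
class HomeologPair:
    base_symbol: str
    gene_l: GeneModel | None
    gene_s: GeneModel | None

    @property
    def status(self) -> str:
        if self.gene_l is not None and self.gene_s is not None:
            return "both"
        return "L-only" if self.gene_l is not None else "S-only"


def pair_homeologs(genes: list[GeneModel]) -> list[HomeologPair]:
    """Group genes by base symbol into retained-pair / single-copy classes.

    Pairing is by the terminal '.L'/'.S' gene-symbol suffix.  Groups with
    two same-tag genes are ambiguous and excluded with a log entry; genes
    without a homeolog tag are skipped.
    """
    by_base: dict[str, dict[str, list[GeneModel]]] = {}
    for g in genes:
        if g.homeolog_tag == "none":
            continue
        by_base.setdefault(g.base_symbol, {}).setdefault(g.homeolog_tag, []).append(g)
    out: list[HomeologPair] = []
    for base in sorted(by_base):
        tags = by_base[base]
        if any(len(v) > 1 for v in tags.values()):
            logger.warning("ambiguous homeolog group %r (duplicate tag); excluded", base)
            continue
        out.append(HomeologPair(base,
                                tags.get("L", [None])[0],
                                tags.get("S", [None])[0]))
    return out
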
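"""Readers/writers for the external formats the pipeline touches, plus the
hard site filters applied to the SNP call set.

Conventions
-----------
Internal window arithmetic is 0-based half-open; VCF and GFF3 are 1-based
inclusive and are converted at this boundary.  ``GenotypeMatrix.pos`` keeps
the VCF 1-based convention since it is carried straight from the file.

Genotypes are stored as alt-allele dosage (0, 1, 2) with ``MISSING`` (-1)
for uncalled genotypes.  Only biallelic SNPs survive ``read_vcf``;
multi-allelic and indel records are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
import gffutils

logger = logging.getLogger("subgenome_scan")

MISSING = -1

_SNP_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites x samples with diploid alt-dosage codes.

    Attributes
    ----------
    chrom : np.ndarray of str, one entry per site
    pos : np.ndarray of int, 1-based positions (VCF convention),
        strictly increasing within each chromosome
    ref, alt : np.ndarray of single-character strings
    gt : int8 array of shape (n_sites, n_samples); -1 encodes missing
    sample_ids : ordered sample labels
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.pos), len(self.sample_ids)):
            raise ValueError(
                f"gt shape {self.gt.shape} does not match "
                f"{len(self.pos)} sites x {len(self.sample_ids)} samples"
            )
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[index], self.pos[index], self.ref[index],
            self.alt[index], self.gt[index], list(self.sample_ids),
        )

    def allele_counts(self, sample_index: np.ndarray | None = None):
        """Per-site (alt_count, called_alleles) over the given samples."""
        g = self.gt if sample_index is None else self.gt[:, sample_index]
        called = 2 * (g != MISSING).sum(axis=1)
        alt = np.where(g == MISSING, 0, g).sum(axis=1)
        return alt.astype(np.int64), called.astype(np.int64)


@dataclass
class PopulationMap:
    """sample_id -> population label, with per-sample admixed flags."""

    population: dict[str, str]
    admixed: dict[str, bool]

    def populations(self) -> list[str]:
        return sorted(set(self.population.values()))

    def sample_index(self, sample_ids: list[str], pop: str,
                     include_admixed: bool = False) -> np.ndarray:
        """Column indices of the (by default non-admixed) members of *pop*."""
        idx = []
        for i, s in enumerate(sample_ids):
            if s not in self.population:
                raise KeyError(f"sample {s!r} missing from population map")
            if self.population[s] != pop:
                continue
            if not include_admixed and self.admixed.get(s, False):
                continue
            idx.append(i)
        return np.asarray(idx, dtype=np.int64)

    def validate(self, sample_ids: list[str]) -> None:
        missing = [s for s in sample_ids if s not in self.population]
        if missing:
            raise KeyError(f"samples missing from population map: {missing}")


@dataclass
class SubgenomeMap:
    """chrom -> {'L','S'} assignment plus explicit homeolog chromosome pairs."""

    assignment: dict[str, str]
    homeolog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in self.assignment.values():
            if v not in ("L", "S"):
                raise ValueError(f"sub-genome label must be L or S, got {v!r}")
        for cl, cs in self.homeolog_pairs:
            if self.assignment.get(cl) != "L" or self.assignment.get(cs) != "S":
                raise ValueError(f"homeolog pair ({cl},{cs}) inconsistent with assignment")

    def subgenome_of(self, chrom: str) -> str:
        """'L', 'S' or 'unassigned'."""
        return self.assignment.get(chrom, "unassigned")


@dataclass
class GeneModel:
    """One protein-coding gene (longest-CDS transcript).

    ``exons`` and ``cds_segments`` are 1-based inclusive intervals sorted in
    transcription order (5'->3'), i.e. descending coordinates on the minus
    strand.  ``cds_segments`` entries are (start, end, phase).
    """

    gene_id: str
    base_symbol: str
    homeolog_tag: str  # 'L', 'S' or 'none'
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int, int]]
    codable: bool = True

    @property
    def start(self) -> int:
        return min(s for s, e in self.exons)

    @property
    def end(self) -> int:
        return max(e for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_category(self, i: int) -> str:
        if self.n_exons == 1:
            return "single"
        if i == 0:
            return "first"
        if i == self.n_exons - 1:
            return "last"
        return "internal"


@dataclass
class FilterConfig:
    """Hard site/genotype filters mirroring a VCFtools-style pass.

    Per-genotype: DP < min_dp or GQ < min_gq sets the genotype to missing.
    Per-site: mean DP across samples > max_mean_dp, missing fraction >
    max_missing_frac, or minor allele frequency < min_maf drops the site.
    ``min_maf=0`` disables the frequency filter; ``min_dp=0``/``min_gq=0``
    skip the genotype masking (so files without DP/GQ pass through).
    """

    min_dp: int = 5
    max_mean_dp: float = 20.0
    max_missing_frac: float = 0.20
    min_gq: int = 30
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0.0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")

    @classmethod
    def disabled(cls) -> "FilterConfig":
        """No-op filter: every polymorphic biallelic SNP is retained."""
        return cls(min_dp=0, max_mean_dp=float("inf"),
                   max_missing_frac=1.0, min_gq=0, min_maf=0.0)


@dataclass
class FilterLog:
    """Per-reason tally of dropped records."""

    n_input: int = 0
    n_retained: int = 0
    non_snp: int = 0
    multiallelic: int = 0
    mean_dp: int = 0
    missingness: int = 0
    maf: int = 0
    monomorphic: int = 0


@dataclass
class PoolSites:
    """Pooled allele-count table: sites x pools ref/alt read counts."""

    chrom: np.ndarray
    pos: np.ndarray
    ref_counts: np.ndarray  # (n_sites, n_pools)
    alt_counts: np.ndarray
    pool_names: list[str]
    pool_size: int = 32

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if np.any(self.ref_counts < 0) or np.any(self.alt_counts < 0):
            raise ValueError("negative read counts")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def coverage(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    def take(self, index: np.ndarray) -> "PoolSites":
        return PoolSites(self.chrom[index], self.pos[index],
                         self.ref_counts[index], self.alt_counts[index],
                         list(self.pool_names), self.pool_size)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, filt: FilterConfig | None = None,
             log: FilterLog | None = None) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, applying hard filters.

    Only biallelic SNP records passing every enabled filter are returned.
    A :class:`FilterLog` (optional ``log`` argument, also logged at INFO)
    records the per-reason drop tally.
    """
    filt = filt or FilterConfig.disabled()
    log = log if log is not None else FilterLog()

    vcf = VCF(path)
    samples = list(vcf.samples)
    n = len(samples)
    if n == 0:
        raise ValueError(f"{path}: VCF has no samples")

    chroms, poss, refs, alts, gts = [], [], [], [], []
    for v in vcf:
        log.n_input += 1
        if len(v.ALT) != 1:
            log.multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or \
                v.REF not in _SNP_BASES or v.ALT[0] not in _SNP_BASES:
            log.non_snp += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        g = v.gt_types.astype(np.int8)
        if len(g) != n:
            raise ValueError(f"{path}: genotype count differs from header sample count at "
                             f"{v.CHROM}:{v.POS}")
        dosage = np.select([g == 0, g == 1, g == 3], [0, 1, 2], default=MISSING).astype(np.int8)

        dp = v.format("DP") if (filt.min_dp > 0 or np.isfinite(filt.max_mean_dp)) else None
        if dp is not None:
            dp = dp.reshape(-1).astype(float)
            dp[dp < 0] = np.nan  # cyvcf2 encodes missing as negative sentinel
        if filt.min_dp > 0 and dp is not None:
            dosage[~(dp >= filt.min_dp)] = MISSING
        if filt.min_gq > 0:
            gq = v.format("GQ")
            if gq is not None:
                gq = gq.reshape(-1).astype(float)
                gq[gq < 0] = np.nan
                dosage[~(gq >= filt.min_gq)] = MISSING

        if np.isfinite(filt.max_mean_dp) and dp is not None and np.any(~np.isnan(dp)):
            if np.nanmean(dp) > filt.max_mean_dp:
                log.mean_dp += 1
                continue

        called = dosage != MISSING
        if (~called).mean() > filt.max_missing_frac:
            log.missingness += 1
            continue
        n_alleles = 2 * called.sum()
        if n_alleles == 0:
            log.missingness += 1
            continue
        ac = int(dosage[called].sum())
        if ac == 0 or ac == n_alleles:
            log.monomorphic += 1
            continue
        if filt.min_maf > 0:
            maf = min(ac, n_alleles - ac) / n_alleles
            if maf < filt.min_maf:
                log.maf += 1
                continue

        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gts.append(dosage)
        log.n_retained += 1

    logger.info(
        "read_vcf %s: %d records in, %d retained (non-SNP %d, multiallelic %d, "
        "mean-DP %d, missingness %d, MAF %d, monomorphic %d)",
        path, log.n_input, log.n_retained, log.non_snp, log.multiallelic,
        log.mean_dp, log.missingness, log.maf, log.monomorphic,
    )
    gt = np.vstack(gts) if gts else np.empty((0, n), dtype=np.int8)
    return GenotypeMatrix(np.asarray(chroms, dtype=object), np.asarray(poss),
                          np.asarray(refs, dtype=object), np.asarray(alts, dtype=object),
                          gt, samples)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str,
              dp: np.ndarray | None = None, gq: np.ndarray | None = None,
              contig_lengths: dict[str, int] | None = None,
              extra_header: list[str] | None = None) -> None:
    """Write a GenotypeMatrix as VCF 4.2 text.

    ``dp``/``gq`` are optional per-genotype int arrays of the same shape as
    ``gm.gt``; when given, the FORMAT becomes GT:DP:GQ.
    """
    fmt_keys = ["GT"]
    if dp is not None:
        fmt_keys.append("DP")
    if gq is not None:
        fmt_keys.append("GQ")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for line in extra_header or []:
            fh.write(line.rstrip("\n") + "\n")
        for c in dict.fromkeys(gm.chrom):  # preserves order
            ln = (contig_lengths or {}).get(c)
            fh.write(f"##contig=<ID={c}" + (f",length={ln}" if ln else "") + ">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        fmt = ":".join(fmt_keys)
        for i in range(gm.n_sites):
            fields = [gm.chrom[i], str(gm.pos[i]), ".", gm.ref[i], gm.alt[i],
                      ".", "PASS", ".", fmt]
            for j in range(gm.n_samples):
                cell = _GT_STR[int(gm.gt[i, j])]
                if dp is not None:
                    cell += f":{int(dp[i, j])}"
                if gq is not None:
                    cell += f":{int(gq[i, j])}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def split_homeolog_suffix(gene_id: str) -> tuple[str, str]:
    """Strip a terminal '.L'/'.S' homeolog suffix (case-sensitive).

    Returns (base_symbol, homeolog_tag) with tag in {'L', 'S', 'none'}.
    """
    for tag in ("L", "S"):
        if gene_id.endswith("." + tag):
            return gene_id[: -(len(tag) + 1)], tag
    return gene_id, "none"


def read_gff(path: str) -> list[GeneModel]:
    """Parse a GFF3 into one GeneModel per protein-coding gene.

    When a gene has several mRNAs the transcript with the longest total CDS
    represents the gene.  Exons and CDS segments are sorted in transcription
    order (reversed on the minus strand).  Genes whose CDS length is not a
    multiple of 3 after phase adjustment are kept but flagged non-codable.
    CDS/exon features with an unresolvable parent are skipped with a warning.
    """
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, list, list] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
                   for f in db.children(mrna, featuretype="CDS")]
            if not exons or not cds:
                continue
            cds_len = sum(e - s + 1 for s, e, _ in cds)
            if best is None or cds_len > best[0]:
                best = (cds_len, exons, cds)
        if best is None:
            logger.warning("gene %s has no mRNA with exons and CDS; skipped", gene.id)
            continue
        cds_len, exons, cds = best
        reverse = gene.strand == "-"
        exons = sorted(exons, key=lambda t: t[0], reverse=reverse)
        cds = sorted(cds, key=lambda t: t[0], reverse=reverse)
        phase0 = cds[0][2]
        codable = (cds_len - phase0) % 3 == 0
        base, tag = split_homeolog_suffix(gene.id)
        genes.append(GeneModel(gene.id, base, tag, gene.seqid, gene.strand,
                               exons, cds, codable))
    return genes


def write_gff(genes: list[GeneModel], path: str,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Emit GeneModels as a minimal gene/mRNA/exon/CDS GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c, ln in (contig_lengths or {}).items():
            fh.write(f"##sequence-region {c} 1 {ln}\n")
        for g in genes:
            gs, ge = g.start, g.end
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(f"{g.chrom}\t.\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t.\tmRNA\t{gs}\t{ge}\t.\t{g.strand}\t.\t"
                     f"ID={mid};Parent={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\t.\texon\t{min(s, e)}\t{max(s, e)}\t.\t{g.strand}\t.\t"
                         f"ID={mid}.exon{k};Parent={mid}\n")
            for k, (s, e, ph) in enumerate(g.cds_segments, 1):
                fh.write(f"{g.chrom}\t.\tCDS\t{min(s, e)}\t{max(s, e)}\t.\t{g.strand}\t{ph}\t"
                         f"ID={mid}.cds{k};Parent={mid}\n")


# ---------------------------------------------------------------------------
# TSV maps and pool counts
# ---------------------------------------------------------------------------

def read_population_map(path: str) -> PopulationMap:
    """TSV with columns: sample, population, admixed (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample": str, "population": str})
    pop = dict(zip(df["sample"], df["population"]))
    adm = dict(zip(df["sample"], df["admixed"].astype(int).astype(bool))) \
        if "admixed" in df.columns else {s: False for s in pop}
    return PopulationMap(pop, adm)


def write_population_map(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tadmixed\n")
        for s in pm.population:
            fh.write(f"{s}\t{pm.population[s]}\t{int(pm.admixed.get(s, False))}\n")


def read_subgenome_map(path: str) -> SubgenomeMap:
    """TSV with columns: chrom, subgenome; pairing by shared numeric prefix."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    assignment = dict(zip(df["chrom"], df["subgenome"]))
    return SubgenomeMap(assignment, infer_homeolog_chrom_pairs(assignment))


def infer_homeolog_chrom_pairs(assignment: dict[str, str]) -> list[tuple[str, str]]:
    """Pair chrNL with chrNS when both sub-genome labels are terminal."""
    by_stem: dict[str, dict[str, str]] = {}
    for c, sg in assignment.items():
        stem = c[:-1] if c.endswith(("L", "S")) else c
        by_stem.setdefault(stem, {})[sg] = c
    return [(d["L"], d["S"]) for d in by_stem.values() if set(d) == {"L", "S"}]


def write_subgenome_map(sg: SubgenomeMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tsubgenome\n")
        for c, v in sg.assignment.items():
            fh.write(f"{c}\t{v}\n")


def read_pool_counts(path: str, min_cov: int = 4, max_cov: int = 50,
                     pool_size: int = 32,
                     mask: list[tuple[str, int, int]] | None = None) -> PoolSites:
    """Read a pooled allele-count TSV and apply coverage bounds.

    Expected columns: chrom, pos, ref, alt, then <pool>_ref/<pool>_alt pairs.
    Sites with coverage outside [min_cov, max_cov] in *any* pool are removed,
    as are sites inside the optional BED-style mask (0-based half-open).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    count_cols = [c for c in df.columns if c.endswith(("_ref", "_alt"))]
    pool_names = list(dict.fromkeys(c.rsplit("_", 1)[0] for c in count_cols))
    ref_counts = df[[p + "_ref" for p in pool_names]].to_numpy(dtype=np.int64)
    alt_counts = df[[p + "_alt" for p in pool_names]].to_numpy(dtype=np.int64)
    sites = PoolSites(df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(),
                      ref_counts, alt_counts, pool_names, pool_size)
    cov = sites.coverage
    keep = np.all((cov >= min_cov) & (cov <= max_cov), axis=1)
    if mask:
        for mc, ms, me in mask:  # 0-based half-open mask vs 1-based pos
            keep &= ~((sites.chrom == mc) & (sites.pos > ms) & (sites.pos <= me))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("read_pool_counts %s: dropped %d/%d sites (coverage/mask)",
                    path, n_drop, sites.n_sites)
    return sites.take(keep)


def write_pool_counts(sites: PoolSites, path: str,
                      ref: np.ndarray | None = None,
                      alt: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        header = ["chrom", "pos", "ref", "alt"]
        for p in sites.pool_names:
            header += [f"{p}_ref", f"{p}_alt"]
        fh.write("\t".join(header) + "\n")
        for i in range(sites.n_sites):
            row = [sites.chrom[i], str(sites.pos[i]),
                   (ref[i] if ref is not None else "N"),
                   (alt[i] if alt is not None else "N")]
            for j in range(len(sites.pool_names)):
                row += [str(sites.ref_counts[i, j]), str(sites.alt_counts[i, j])]
            fh.write("\t".join(row) + "\n")


def read_bed_mask(path: str) -> list[tuple[str, int, int]]:
    """BED3 (0-based half-open) mask intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e = line.split()[:3]
            out.append((c, int(s), int(e)))
    return out


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
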
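"""Functional classification of coding SNPs and impact-stratified spectra.

Coding SNPs are classified from first principles (codon located via CDS
segments, phase and strand; translated with the standard code) into a
function class (silent / missense / nonsense) and an impact tier
(Low / Moderate / High), following the usual variant-annotation
convention: synonymous -> Low, missense -> Moderate, stop gain -> High.
Stop-loss and start-loss changes are High-impact (function class
missense, the one deliberate exception to the missense -> Moderate rule).
Sites outside any CDS are noncoding / Modifier.

An ANN-field parser accepts VCFs annotated by external tools in the same
vocabulary, so the pipeline runs identically on pre-annotated data.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import norm

from .io_formats import GeneModel, GenotypeMatrix, PopulationMap, SubgenomeMap
from .subgenome_partition import compare_subgenomes

logger = logging.getLogger("subgenome_scan")

IMPACTS = ("High", "Moderate", "Low", "Modifier")
FUNC_CLASSES = ("nonsense", "missense", "silent", "noncoding")

_SEVERITY = {"High": 3, "Moderate": 2, "Low": 1, "Modifier": 0}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class EffectRecord:
    chrom: str
    pos: int
    impact: str
    func_class: str
    derived_freq: float
    subgenome: str


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_codon_change(ref_codon: str, alt_codon: str,
                          is_start: bool = False) -> tuple[str, str]:
    """(func_class, impact) for a single-base codon substitution."""
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    if aa_ref == aa_alt:
        return "silent", "Low"
    if aa_alt == "*":
        return "nonsense", "High"
    if aa_ref == "*":          # stop loss
        return "missense", "High"
    if is_start and aa_ref == "M":   # start loss
        return "missense", "High"
    return "missense", "Moderate"


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic positions (1-based) of CDS bases in transcription order."""
    out: list[int] = []
    for s, e, _ in gene.cds_segments:
        lo, hi = min(s, e), max(s, e)
        rng = range(lo, hi + 1) if gene.strand == "+" else range(hi, lo - 1, -1)
        out.extend(rng)
    return out


def classify_coding_snp(gene: GeneModel, ref_seq: str, pos: int,
                        ref: str, alt: str) -> tuple[str, str]:
    """Classify one SNP against a gene model.

    ``ref_seq`` is the plus-strand chromosome sequence; ``pos`` is 1-based;
    ``ref``/``alt`` are plus-strand alleles.  Positions outside the CDS
    (or in the out-of-frame leading phase bases) are noncoding/Modifier.
    """
    if ref_seq[pos - 1] != ref:
        raise ValueError(f"reference mismatch at {gene.chrom}:{pos}: "
                         f"sequence has {ref_seq[pos - 1]}, record says {ref}")
    cds_pos = _cds_positions(gene)
    try:
        i = cds_pos.index(pos)
    except ValueError:
        return "noncoding", "Modifier"
    phase0 = gene.cds_segments[0][2]
    if i < phase0 or not gene.codable:
        return "noncoding", "Modifier"
    codon_idx, offset = divmod(i - phase0, 3)
    codon_genomic = cds_pos[phase0 + 3 * codon_idx: phase0 + 3 * codon_idx + 3]
    if len(codon_genomic) < 3:
        return "noncoding", "Modifier"   # trailing incomplete codon
    bases = [ref_seq[p - 1] for p in codon_genomic]
    alt_base = alt
    if gene.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_base = alt.translate(_COMPLEMENT)
    ref_codon = "".join(bases)
    alt_codon_l = list(bases)
    alt_codon_l[offset] = alt_base
    return classify_codon_change(ref_codon, "".join(alt_codon_l),
                                 is_start=(codon_idx == 0))


class _CdsIndex:
    """Sorted-interval lookup from position to covering genes, per chrom."""

    def __init__(self, genes: list[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[tuple[int, GeneModel]]]] = {}
        tmp: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for g in genes:
            for s, e, _ in g.cds_segments:
                tmp.setdefault(g.chrom, []).append((min(s, e), max(s, e), g))
        for c, ivs in tmp.items():
            ivs.sort(key=lambda t: t[0])
            starts = [s for s, _, _ in ivs]
            self._by_chrom[c] = (starts, [(e, g) for _, e, g in ivs])

    def covering(self, chrom: str, pos: int) -> list[GeneModel]:
        if chrom not in self._by_chrom:
            return []
        starts, rest = self._by_chrom[chrom]
        out = []
        # scan left from the insertion point; CDS segments are short so the
        # overlap horizon is narrow
        i = bisect_right(starts, pos) - 1
        while i >= 0:
            end, g = rest[i]
            if end >= pos:
                out.append(g)
            elif pos - starts[i] > 1_000_000:
                break
            i -= 1
        return out


def annotate_sites(gm: GenotypeMatrix, genes: list[GeneModel],
                   ref_seqs: dict[str, str], sg: SubgenomeMap,
                   pops: PopulationMap, population: str,
                   include_admixed: bool = False) -> list[EffectRecord]:
    """Classify every site of the matrix and attach its derived (non-ref)
    allele frequency in the given population.

    With several covering gene models the most severe consequence wins.
    Sites with no called alleles in the population are skipped.
    """
    index = _CdsIndex(genes)
    sidx = pops.sample_index(gm.sample_ids, population, include_admixed)
    alt_c, called = gm.allele_counts(sidx)
    out: list[EffectRecord] = []
    for i in range(gm.n_sites):
        if called[i] == 0:
            continue
        chrom, pos = gm.chrom[i], int(gm.pos[i])
        best = ("noncoding", "Modifier")
        for g in index.covering(chrom, pos):
            fc, imp = classify_coding_snp(g, ref_seqs[chrom], pos,
                                          gm.ref[i], gm.alt[i])
            if _SEVERITY[imp] > _SEVERITY[best[1]]:
                best = (fc, imp)
        out.append(EffectRecord(chrom, pos, best[1], best[0],
                                float(alt_c[i] / called[i]),
                                sg.subgenome_of(chrom)))
    return out


def parse_snpeff_ann(ann_value: str) -> tuple[str, str]:
    """Map the first (most severe) ANN entry to (func_class, impact)."""
    first = ann_value.split(",")[0]
    fields = first.split("|")
    if len(fields) < 3:
        raise ValueError(f"malformed ANN entry: {ann_value!r}")
    terms = fields[1].split("&")
    impact = fields[2].capitalize()
    if impact not in IMPACTS:
        raise ValueError(f"unknown impact {fields[2]!r}")
    func = "noncoding"
    for term in terms:
        if term == "stop_gained":
            func = "nonsense"; break
        if term == "missense_variant" or term in ("start_lost", "stop_lost"):
            func = "missense"; break
        if term in ("synonymous_variant", "stop_retained_variant"):
            func = "silent"; break
    return func, impact


def read_annotated_vcf(path: str, sg: SubgenomeMap, pops: PopulationMap,
                       population: str) -> list[EffectRecord]:
    """EffectRecords from a VCF carrying ANN INFO fields (external
    annotator dialect).  Records without ANN are skipped with a count."""
    from cyvcf2 import VCF
    vcf = VCF(path)
    samples = list(vcf.samples)
    pidx = pops.sample_index(samples, population)
    skipped = 0
    out: list[EffectRecord] = []
    for v in vcf:
        ann = v.INFO.get("ANN")
        if ann is None:
            skipped += 1
            continue
        func, impact = parse_snpeff_ann(str(ann))
        g = v.gt_types[pidx]
        called = 2 * (g != 2).sum()
        if called == 0:
            continue
        ac = int((g == 1).sum() + 2 * (g == 3).sum())
        out.append(EffectRecord(v.CHROM, v.POS, impact, func, ac / called,
                                sg.subgenome_of(v.CHROM)))
    if skipped:
        logger.info("read_annotated_vcf %s: %d records without ANN skipped",
                    path, skipped)
    return out


def effect_summary(records: list[EffectRecord]) -> pd.DataFrame:
    """Per-sub-genome counts/proportions by impact and function class, with
    the missense/silent ratio.  Impact proportions are over the coding
    tiers (High/Moderate/Low); function-class proportions over
    nonsense/missense/silent — denominators are reported explicitly."""
    if not records:
        raise ValueError("no records to summarise")
    df = pd.DataFrame([(r.subgenome, r.impact, r.func_class) for r in records],
                      columns=["subgenome", "impact", "func_class"])
    rows = []
    for sgn, sub in df.groupby("subgenome"):
        coding = sub[sub["impact"] != "Modifier"]
        n_imp = len(coding)
        row: dict = {"subgenome": sgn, "n_sites": len(sub),
                     "n_coding": n_imp}
        for imp in ("High", "Moderate", "Low"):
            k = int((coding["impact"] == imp).sum())
            row[f"impact_{imp}_n"] = k
            row[f"impact_{imp}_prop"] = k / n_imp if n_imp else math.nan
        cls = sub[sub["func_class"] != "noncoding"]
        n_cls = len(cls)
        for fc in ("nonsense", "missense", "silent"):
            k = int((cls["func_class"] == fc).sum())
            row[f"class_{fc}_n"] = k
            row[f"class_{fc}_prop"] = k / n_cls if n_cls else math.nan
        n_sil = row["class_silent_n"]
        row["missense_silent_ratio"] = \
            row["class_missense_n"] / n_sil if n_sil else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p)."""
    if min(n1, n2) == 0:
        raise ValueError("empty group")
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    se2 = p * (1 - p) * (1 / n1 + 1 / n2)
    if se2 == 0:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(se2)
    return float(z), float(2.0 * norm.sf(abs(z)))


def impact_afs(records: list[EffectRecord], n_bins: int = 10) -> pd.DataFrame:
    """Normalised derived-allele-frequency spectra per impact tier and
    sub-genome, plus the mean frequency quantifying any left shift."""
    df = pd.DataFrame([(r.impact, r.subgenome, r.derived_freq) for r in records],
                      columns=["impact", "subgenome", "freq"])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for (imp, sgn), sub in df.groupby(["impact", "subgenome"]):
        counts, _ = np.histogram(sub["freq"], bins=edges)
        total = counts.sum()
        for b in range(n_bins):
            rows.append({"impact": imp, "subgenome": sgn,
                         "bin_start": edges[b], "bin_end": edges[b + 1],
                         "count": int(counts[b]),
                         "proportion": counts[b] / total if total else math.nan,
                         "mean_freq": float(sub["freq"].mean()),
                         "n_sites": int(total)})
    return pd.DataFrame(rows)


def compare_afs(records: list[EffectRecord], impact: str,
                method: str = "z"):
    """L-vs-S test of mean derived frequency within one impact tier."""
    fl = [r.derived_freq for r in records
          if r.impact == impact and r.subgenome == "L"]
    fs = [r.derived_freq for r in records
          if r.impact == impact and r.subgenome == "S"]
    return compare_subgenomes(fl, fs, method=method)
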
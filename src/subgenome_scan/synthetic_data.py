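"""Synthetic allotetraploid cohorts with known ground truth.

The generator emulates the data structures the sub-genome comparison
assumes, at desk scale:

* paired homeologous L/S chromosomes (chr1L/chr1S, ...), with per-gene
  retention probabilities so some genes survive on both sub-genomes and
  some on only one;
* multi-population divergence under the Balding-Nichols model: per site an
  ancestral frequency p ~ Beta(a, b), deme frequencies
  q ~ Beta(p(1-F)/F, (1-p)(1-F)/F) and diploid genotypes ~ Binomial(2, q)
  — chosen over a coalescent simulator because E[Hudson Fst] = F in closed
  form, giving analytic recovery checks;
* background-selection troughs near exons: the multiplier
  m(d) = 1 - trough_depth * exp(-d / trough_decay), with d the distance to
  the nearest exon, both thins variant density (Poisson thinning) and
  deflates the minor-allele frequency, so per-site diversity genuinely dips
  near exons as it does in real data (density thinning alone would leave
  the per-variant-site diversity estimator unchanged);
* effect-class-dependent frequencies: CDS variants are assigned a target
  function class (silent/missense/nonsense), the alt base is chosen so the
  codon change actually realises that class, and the ancestral frequency
  is multiplied by a per-impact deflation factor (purifying selection);
* pooled sequencing: two pools with read counts ~ Binomial(depth, q) at
  a separate (lower) background divergence, optionally with planted
  high-divergence outlier windows.

All randomness flows through one seeded generator; the same seed gives
byte-identical output files.  The seed is recorded in every emitted
text header.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import (
    GeneModel, GenotypeMatrix, PoolSites, PopulationMap, SubgenomeMap,
    infer_homeolog_chrom_pairs, write_fasta, write_gff,
    write_pool_counts, write_population_map, write_subgenome_map, write_vcf,
)
from .effect_annotation import classify_coding_snp

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS and a + b + c != "ATG"]


@dataclass
class SimParams:
    """Full parameterisation of a synthetic allotetraploid cohort.

    Defaults describe the study conditions being emulated: two diverged
    populations at F = 0.30 (the empirical between-population window Fst
    sits around 0.27-0.35), hard-filtered diploid genotypes at mean depth
    11x, a 50% diversity trough decaying over ~5 kb around exons, a
    function-class mix of roughly 53% silent / 46% missense / 1% nonsense,
    and 32-individual pools sequenced at 32x with background divergence
    F = 0.05.  theta is the expected variant-site density per bp; the
    desk-scale default (5e-3) trades genome length for site count.
    """

    seed: int = 0
    n_chrom_pairs: int = 2
    chrom_length: int = 500_000
    pop_names: tuple[str, ...] = ("pop1", "pop2")
    pop_sizes: tuple[int, ...] = (10, 10)
    n_admixed: int = 0
    ancestral_beta: tuple[float, float] = (0.5, 0.5)
    divergence_F: float = 0.30
    theta: float = 5e-3
    n_genes_per_chrom: int = 10
    exon_count_mean: float = 3.0
    exon_length_range: tuple[int, int] = (90, 240)
    intron_length_range: tuple[int, int] = (500, 3000)
    gene_gap_range: tuple[int, int] = (8_000, 25_000)
    retention_prob: tuple[float, float] = (0.92, 0.69)  # P(kept on L), P(kept on S)
    trough_depth: float = 0.5
    trough_decay: float = 5_000.0
    impact_mix: tuple[float, float, float] = (0.53, 0.46, 0.01)  # silent, missense, nonsense
    impact_freq_deflation: dict = field(default_factory=lambda: {
        "Low": 1.0, "Moderate": 0.7, "High": 0.3, "Modifier": 1.0})
    dp_mean: float = 11.0
    gq_low_rate: float = 0.03
    missing_rate: float = 0.02
    pool_F: float = 0.05
    pool_depth: float = 32.0
    pool_size: int = 32
    n_outlier_windows: int = 0
    outlier_F: float = 0.6
    outlier_window_size: int = 100_000
    asymmetry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.impact_mix), 1.0, abs_tol=1e-9):
            raise ValueError("impact_mix proportions must sum to 1")
        if not 0.0 <= self.trough_depth <= 1.0:
            raise ValueError("trough_depth must be in [0, 1]")
        for f in (self.divergence_F, self.pool_F, self.outlier_F):
            if not 0.0 < f < 1.0:
                raise ValueError("divergence F parameters must be in (0, 1)")
        if len(self.pop_names) != len(self.pop_sizes):
            raise ValueError("pop_names and pop_sizes length mismatch")

    def value_for(self, name: str, subgenome: str):
        """Parameter value with any per-sub-genome asymmetry override."""
        override = self.asymmetry.get(name)
        if override and subgenome in override:
            return override[subgenome]
        return getattr(self, name)


@dataclass
class GroundTruth:
    """True per-site state the generator committed to."""

    chrom: np.ndarray
    pos: np.ndarray
    ancestral_freq: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    func_class: np.ndarray
    impact: np.ndarray
    pool_freqs: np.ndarray          # (n_sites, 2)
    planted_windows: list[tuple[str, int, int]]
    homeolog_bases: list[str]

    def to_jsonable(self) -> dict:
        return {
            "chrom": self.chrom.tolist(),
            "pos": self.pos.tolist(),
            "ancestral_freq": np.round(self.ancestral_freq, 6).tolist(),
            "pop_freqs": {p: np.round(v, 6).tolist()
                          for p, v in self.pop_freqs.items()},
            "func_class": self.func_class.tolist(),
            "impact": self.impact.tolist(),
            "pool_freqs": np.round(self.pool_freqs, 6).tolist(),
            "planted_windows": [list(w) for w in self.planted_windows],
            "homeolog_bases": self.homeolog_bases,
        }


@dataclass
class SimulatedCohort:
    params: SimParams
    reference: dict[str, str]
    genes: list[GeneModel]
    gm: GenotypeMatrix
    dp: np.ndarray
    gq: np.ndarray
    pop_map: PopulationMap
    subgenome_map: SubgenomeMap
    pool_sites: PoolSites
    ground_truth: GroundTruth

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}


# ---------------------------------------------------------------------------
# Gene/reference construction
# ---------------------------------------------------------------------------

def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop; avoids internal stops."""
    body = rng.choice(len(_SENSE_CODONS), size=max(0, n_codons - 2))
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _build_chromosome(rng: np.random.Generator, params: SimParams, chrom: str,
                      subgenome: str, base_symbols: list[str],
                      keep: np.ndarray) -> tuple[str, list[GeneModel]]:
    """Random reference with the retained genes' CDS written in."""
    length = int(params.value_for("chrom_length", subgenome))
    seq = rng.choice(4, size=length)
    ref = "".join(_BASES[seq])
    genes: list[GeneModel] = []
    cursor = int(rng.integers(*params.gene_gap_range))
    for k, base in enumerate(base_symbols):
        n_exons = 1 + int(rng.poisson(max(params.exon_count_mean - 1, 0.0)))
        exon_lens = [int(rng.integers(*params.exon_length_range))
                     for _ in range(n_exons)]
        # total CDS length must be a codon multiple
        total = sum(exon_lens)
        exon_lens[-1] += (3 - total % 3) % 3
        intron_lens = [int(rng.integers(*params.intron_length_range))
                       for _ in range(n_exons - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_span = sum(exon_lens) + sum(intron_lens)
        if not keep[k]:
            # burn the same number of draws regardless of retention so L/S
            # layouts stay comparable, then skip placement
            continue
        start = cursor + 1  # 1-based
        if start + gene_span + max(params.gene_gap_range) >= length:
            raise ValueError(
                f"gene layout exceeds chromosome {chrom}: need more than "
                f"{length} bp for {len(base_symbols)} genes")
        exons: list[tuple[int, int]] = []
        p = start
        for i, el in enumerate(exon_lens):
            exons.append((p, p + el - 1))
            p += el + (intron_lens[i] if i < n_exons - 1 else 0)
        # genomic-order exons; transcription order depends on strand
        tx_exons = exons if strand == "+" else exons[::-1]
        cds_lens_tx = exon_lens if strand == "+" else exon_lens[::-1]
        # GFF phase: bases to skip to reach the next codon start
        phases, cum = [], 0
        for el in cds_lens_tx:
            phases.append((3 - cum % 3) % 3)
            cum += el
        coding = _random_coding_sequence(rng, cum // 3)
        # write coding sequence into the reference along transcription order
        ref_l = list(ref)
        ci = 0
        for (s, e) in tx_exons:
            el = e - s + 1
            chunk = coding[ci:ci + el]
            ci += el
            if strand == "+":
                ref_l[s - 1:e] = list(chunk)
            else:
                ref_l[s - 1:e] = list(chunk.translate(_REVCOMP)[::-1])
        ref = "".join(ref_l)
        cds_segments = [(s, e, phases[i]) for i, (s, e) in enumerate(tx_exons)]
        genes.append(GeneModel(f"{base}.{subgenome}", base, subgenome, chrom,
                               strand, tx_exons, cds_segments, True))
        cursor = max(e for s, e in exons) + int(rng.integers(*params.gene_gap_range))
    return ref, genes


def distance_to_nearest_interval(pos: np.ndarray,
                                 intervals: list[tuple[int, int]]) -> np.ndarray:
    """Distance in bp from each 0-based position to the nearest interval
    (0-based half-open); 0 inside an interval."""
    pos = np.asarray(pos, dtype=np.int64)
    if not intervals:
        return np.full(len(pos), np.iinfo(np.int64).max // 2, dtype=np.int64)
    ivs = sorted(intervals)
    starts = np.array([s for s, _ in ivs], dtype=np.int64)
    ends = np.array([e for _, e in ivs], dtype=np.int64)
    i = np.searchsorted(starts, pos, side="right") - 1
    dist = np.full(len(pos), np.iinfo(np.int64).max // 2, dtype=np.int64)
    has_left = i >= 0
    inside = has_left & (pos < ends[np.clip(i, 0, None)])
    dist[inside] = 0
    left_gap = np.where(has_left & ~inside, pos - ends[np.clip(i, 0, None)] + 1, dist)
    nxt = i + 1
    has_right = nxt < len(starts)
    right_gap = np.where(has_right, starts[np.clip(nxt, None, len(starts) - 1)] - pos,
                         np.iinfo(np.int64).max // 2)
    out = np.minimum(np.where(inside, 0, left_gap), np.where(inside, 0, right_gap))
    return np.maximum(out, 0)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float
                     ) -> np.ndarray:
    ratio = (1.0 - F) / F
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return rng.beta(p * ratio, (1.0 - p) * ratio)


def simulate(params: SimParams) -> SimulatedCohort:
    """Generate a complete cohort (reference, genes, genotypes, maps, pools,
    ground truth), mutually consistent and reproducible from the seed."""
    rng = np.random.default_rng(params.seed)

    # sample sheet
    sample_ids, pop_of, admixed = [], {}, {}
    for pname, psize in zip(params.pop_names, params.pop_sizes):
        for i in range(psize):
            s = f"{pname}_s{i:02d}"
            sample_ids.append(s)
            pop_of[s] = pname
            admixed[s] = i < params.n_admixed
    pop_map = PopulationMap(pop_of, admixed)

    assignment: dict[str, str] = {}
    for i in range(1, params.n_chrom_pairs + 1):
        assignment[f"chr{i}L"] = "L"
        assignment[f"chr{i}S"] = "S"
    sg = SubgenomeMap(assignment, infer_homeolog_chrom_pairs(assignment))

    reference: dict[str, str] = {}
    genes: list[GeneModel] = []
    homeolog_bases: list[str] = []
    chrom_site_data = []

    for pair in range(1, params.n_chrom_pairs + 1):
        n_genes = int(params.n_genes_per_chrom)
        bases = [f"g{pair}_{k:02d}" for k in range(n_genes)]
        homeolog_bases.extend(bases)
        keep_l = rng.random(n_genes) < params.retention_prob[0]
        keep_s = rng.random(n_genes) < params.retention_prob[1]
        for sub, keep in (("L", keep_l), ("S", keep_s)):
            chrom = f"chr{pair}{sub}"
            ref, g = _build_chromosome(rng, params, chrom, sub, bases, keep)
            reference[chrom] = ref
            genes.extend(g)

    # planted pool-scan outlier windows, drawn over the whole genome
    all_windows: list[tuple[str, int, int]] = []
    for chrom, ref in reference.items():
        for s in range(0, len(ref), params.outlier_window_size):
            all_windows.append((chrom, s, min(s + params.outlier_window_size, len(ref))))
    planted: list[tuple[str, int, int]] = []
    if params.n_outlier_windows > 0:
        pick = rng.choice(len(all_windows), size=params.n_outlier_windows,
                          replace=False)
        planted = [all_windows[i] for i in sorted(pick)]

    # per-chromosome variant sites
    from .effect_annotation import _CdsIndex
    cds_index = _CdsIndex(genes)
    chroms_l, pos_l, ref_a, alt_a = [], [], [], []
    anc_l, fclass_l, impact_l = [], [], []
    for chrom, ref in reference.items():
        sub = sg.subgenome_of(chrom)
        theta = float(params.value_for("theta", sub))
        depth = float(params.value_for("trough_depth", sub))
        decay = float(params.value_for("trough_decay", sub))
        L = len(ref)
        n_cand = rng.poisson(theta * L)
        cand = np.unique(rng.integers(0, L, size=n_cand))  # 0-based
        exon_ivs = [(min(s, e) - 1, max(s, e)) for g in genes if g.chrom == chrom
                    for (s, e) in g.exons]
        d = distance_to_nearest_interval(cand, exon_ivs)
        m = 1.0 - depth * np.exp(-d / decay)
        kept = cand[rng.random(len(cand)) < m]
        m_kept = 1.0 - depth * np.exp(
            -distance_to_nearest_interval(kept, exon_ivs) / decay)
        a, b = params.ancestral_beta
        p_anc = rng.beta(a, b, size=len(kept))
        # trough deflates the minor-allele frequency (folding keeps the
        # deflation a strict reduction of heterozygosity on both arms)
        minor = np.minimum(p_anc, 1.0 - p_anc) * m_kept
        p_anc = np.where(p_anc <= 0.5, minor, 1.0 - minor)
        deflation = params.value_for("impact_freq_deflation", sub)
        for j, pos0 in enumerate(kept):
            pos = int(pos0) + 1
            ref_base = ref[pos0]
            covering = cds_index.covering(chrom, pos)
            fc, imp, alt_base = "noncoding", "Modifier", None
            if covering:
                gene = covering[0]
                options: dict[str, tuple[str, str]] = {}
                for cand_alt in "ACGT":
                    if cand_alt == ref_base:
                        continue
                    c_fc, c_imp = classify_coding_snp(gene, ref, pos,
                                                      ref_base, cand_alt)
                    options.setdefault(c_fc, (cand_alt, c_imp))
                # draw the target class from impact_mix renormalised over
                # the classes actually reachable at this codon position
                classes = ("silent", "missense", "nonsense")
                w = np.array([params.impact_mix[i] if c in options else 0.0
                              for i, c in enumerate(classes)])
                if w.sum() > 0:
                    fc = classes[rng.choice(3, p=w / w.sum())]
                    alt_base, imp = options[fc]
                elif "noncoding" in options:
                    fc = "noncoding"
                    alt_base, imp = options[fc]
            if alt_base is None:
                others = [x for x in "ACGT" if x != ref_base]
                alt_base = others[rng.integers(0, 3)]
            chroms_l.append(chrom)
            pos_l.append(pos)
            ref_a.append(ref_base)
            alt_a.append(alt_base)
            anc_l.append(p_anc[j] * deflation.get(imp, 1.0))
            fclass_l.append(fc)
            impact_l.append(imp)

    chrom_arr = np.asarray(chroms_l, dtype=object)
    pos_arr = np.asarray(pos_l, dtype=np.int64)
    anc = np.clip(np.asarray(anc_l, dtype=float), 1e-6, 1 - 1e-6)
    n_sites = len(pos_arr)

    # population frequencies and genotypes
    pop_freqs: dict[str, np.ndarray] = {}
    gts = np.empty((n_sites, len(sample_ids)), dtype=np.int8)
    col = 0
    Fd = params.divergence_F
    for pname, psize in zip(params.pop_names, params.pop_sizes):
        q = _balding_nichols(rng, anc, Fd)
        pop_freqs[pname] = q
        g = rng.binomial(2, q[:, None], size=(n_sites, psize)).astype(np.int8)
        gts[:, col:col + psize] = g
        col += psize
    if params.missing_rate > 0:
        miss = rng.random(gts.shape) < params.missing_rate
        gts[miss] = -1

    # pooled read counts (two pools, separate divergence, planted outliers)
    pool_F_site = np.full(n_sites, params.pool_F)
    for (c, s, e) in planted:
        inwin = (chrom_arr == c) & (pos_arr - 1 >= s) & (pos_arr - 1 < e)
        pool_F_site[inwin] = params.outlier_F
    q1 = np.empty(n_sites); q2 = np.empty(n_sites)
    for Fv in np.unique(pool_F_site):
        sel = pool_F_site == Fv
        q1[sel] = _balding_nichols(rng, anc[sel], float(Fv))
        q2[sel] = _balding_nichols(rng, anc[sel], float(Fv))
    cov = rng.poisson(params.pool_depth, size=(n_sites, 2)).clip(min=1)
    alt_reads = np.column_stack([rng.binomial(cov[:, 0], q1),
                                 rng.binomial(cov[:, 1], q2)])
    pool_sites_all = PoolSites(chrom_arr, pos_arr, cov - alt_reads, alt_reads,
                               ["low", "high"], params.pool_size)

    # drop sites monomorphic across all called genotypes (not SNPs in-sample)
    called = gts != -1
    n_called = 2 * called.sum(axis=1)
    ac = np.where(called, gts, 0).sum(axis=1)
    poly = (n_called > 0) & (ac > 0) & (ac < n_called)

    gm = GenotypeMatrix(chrom_arr[poly], pos_arr[poly],
                        np.asarray(ref_a, dtype=object)[poly],
                        np.asarray(alt_a, dtype=object)[poly],
                        gts[poly], sample_ids)
    dp = rng.poisson(params.dp_mean, size=gm.gt.shape).clip(min=1)
    gq = np.where(rng.random(gm.gt.shape) < params.gq_low_rate,
                  rng.integers(5, 30, size=gm.gt.shape), 99)

    truth = GroundTruth(
        chrom=chrom_arr[poly], pos=pos_arr[poly],
        ancestral_freq=anc[poly],
        pop_freqs={p: v[poly] for p, v in pop_freqs.items()},
        func_class=np.asarray(fclass_l, dtype=object)[poly],
        impact=np.asarray(impact_l, dtype=object)[poly],
        pool_freqs=np.column_stack([q1, q2])[poly],
        planted_windows=planted,
        homeolog_bases=homeolog_bases,
    )
    return SimulatedCohort(params, reference, genes, gm, dp, gq, pop_map, sg,
                           pool_sites_all.take(poly), truth)


def make_null_pair(params: SimParams) -> SimulatedCohort:
    """Cohort whose L and S sub-genomes are generated from identical
    parameters with independent randomness — the null for every L-vs-S
    comparison.  Any asymmetry overrides are rejected."""
    if params.asymmetry:
        raise ValueError("make_null_pair requires empty asymmetry overrides")
    return simulate(params)


def split_by_subgenome(cohort: SimulatedCohort
                       ) -> dict[str, GenotypeMatrix]:
    """The cohort's genotype matrix restricted to each sub-genome."""
    out = {}
    for sub in ("L", "S"):
        on_sub = np.array([cohort.subgenome_map.subgenome_of(c) == sub
                           for c in cohort.gm.chrom])
        out[sub] = cohort.gm.take_sites(np.flatnonzero(on_sub))
    return out


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir: str) -> dict[str, str]:
    """Write FASTA, GFF3, VCF, map TSVs, pool TSV, params JSON and ground
    truth JSON; returns the path of each artifact."""
    os.makedirs(outdir, exist_ok=True)
    seed = cohort.params.seed
    paths = {
        "reference": os.path.join(outdir, "reference.fa"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "pop_map": os.path.join(outdir, "populations.tsv"),
        "subgenome_map": os.path.join(outdir, "subgenomes.tsv"),
        "pool_counts": os.path.join(outdir, "pool_counts.tsv"),
        "params": os.path.join(outdir, "sim_params.json"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
    }
    write_fasta(cohort.reference, paths["reference"])
    write_gff(cohort.genes, paths["gff"])
    write_vcf(cohort.gm, paths["vcf"], dp=cohort.dp, gq=cohort.gq,
              contig_lengths=cohort.chrom_lengths,
              extra_header=[f"##simulation_seed={seed}"])
    write_population_map(cohort.pop_map, paths["pop_map"])
    write_subgenome_map(cohort.subgenome_map, paths["subgenome_map"])
    write_pool_counts(cohort.pool_sites, paths["pool_counts"])
    with open(paths["params"], "w") as fh:
        json.dump({"seed": seed, **asdict(cohort.params)}, fh, indent=1,
                  default=str)
    with open(paths["ground_truth"], "w") as fh:
        json.dump({"seed": seed, **cohort.ground_truth.to_jsonable()}, fh)
    return paths
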
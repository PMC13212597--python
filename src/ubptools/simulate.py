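"""Seeded generators for every input the pipeline consumes, with planted truth.

Each generator derives its own child random stream from (seed, stream-name),
so adding a generator never perturbs the draws of another. All outputs are
bit-reproducible given the same configuration and seed.
"""

from __future__ import annotations

import zlib
from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Blacklist, GenomeSpec, Interval, IntervalIndex, Peak, PeakSet, TEAnnotation
from .meth_summary import find_context_sites

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible stream keyed by (seed, stream name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


def _lognormal_mean1(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size)


# ----------------------------------------------------------------- genome


@dataclass
class GenomeParams:
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    gc: float = 0.42
    with_sequence: bool = True


@dataclass
class SyntheticGenome:
    spec: GenomeSpec
    sequences: dict[str, str] | None = None


def gen_genome(params: GenomeParams, seed: int) -> SyntheticGenome:
    """Genome of equal-length chromosomes with random sequence content."""
    if params.n_chrom < 1:
        raise ValueError("need at least one chromosome")
    names = [f"chr{i + 1}" for i in range(params.n_chrom)]
    spec = GenomeSpec(names, [params.chrom_length] * params.n_chrom)
    sequences = None
    if params.with_sequence:
        rng = child_rng(seed, "genome")
        p_gc = params.gc / 2
        p = np.array([0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc])
        sequences = {
            name: BASES[rng.choice(4, size=params.chrom_length, p=p)].tobytes().decode()
            for name in names
        }
    return SyntheticGenome(spec, sequences)


# ------------------------------------------------------------ TE annotation


@dataclass
class TESubfamilySpec:
    subclass: str
    count: int
    mean_length: float = 800.0
    sigma_log: float = 0.3
    min_length: int = 100


def _place_nonoverlapping(
    rng: np.random.Generator,
    lengths: list[int],
    genome: GenomeSpec,
    occupied: dict[str, list[tuple[int, int]]],
    max_retries: int = 1000,
) -> list[Interval]:
    """Place intervals of given lengths without overlapping ``occupied``."""
    chrom_lens = genome.chrom_lengths
    out = []
    for L in lengths:
        placed = None
        for _ in range(max_retries):
            feas = np.clip(chrom_lens - L + 1, 0, None).astype(float)
            if feas.sum() == 0:
                break
            ci = rng.choice(len(chrom_lens), p=feas / feas.sum())
            start = int(rng.integers(0, int(feas[ci])))
            chrom = genome.chrom_names[ci]
            slots = occupied.setdefault(chrom, [])
            j = bisect_left(slots, (start, start + L))
            prev_ok = j == 0 or slots[j - 1][1] <= start
            next_ok = j == len(slots) or start + L <= slots[j][0]
            if prev_ok and next_ok:
                insort(slots, (start, start + L))
                placed = Interval(chrom, start, start + L)
                break
        if placed is None:
            raise RuntimeError(
                f"infeasible packing: could not place interval of length {L}"
            )
        out.append(placed)
    return out


def gen_te_annotation(
    genome: GenomeSpec,
    te_spec: dict[str, TESubfamilySpec],
    seed: int,
) -> TEAnnotation:
    """Non-overlapping TE insertions with exact per-subfamily counts."""
    rng = child_rng(seed, "te_annotation")
    total_requested = sum(s.count * s.mean_length for s in te_spec.values())
    if total_requested >= 0.8 * genome.total_length:
        raise ValueError("requested TE bases exceed feasible genome occupancy")
    occupied: dict[str, list[tuple[int, int]]] = {}
    records = []
    for subfamily in sorted(te_spec):
        spec = te_spec[subfamily]
        lengths = [
            max(spec.min_length, int(round(l)))
            for l in rng.lognormal(
                np.log(spec.mean_length), spec.sigma_log, spec.count
            )
        ]
        for iv in _place_nonoverlapping(rng, lengths, genome, occupied):
            records.append((iv, spec.subclass, subfamily))
    return TEAnnotation(records)


# ----------------------------------------------------------------- peaks


@dataclass
class PeakParams:
    count: int = 200
    mean_length: float = 600.0
    sigma_log: float = 0.5
    min_length: int = 100
    max_length: int = 10_000
    enrichment_fraction: float = 0.0
    target_subfamily: str | None = None
    base_rpkm: float = 200.0
    rpkm_sigma_log: float = 0.5
    noise_cv: float = 0.1
    samples: tuple[str, ...] = ("rep1", "rep2")


def gen_peaks(
    genome: GenomeSpec,
    params: PeakParams,
    te: TEAnnotation | None = None,
    seed: int = 0,
    blacklist: Blacklist | None = None,
) -> tuple[PeakSet, pd.DataFrame]:
    """Peaks with a controllable fraction placed inside a target TE subfamily.

    A fraction ``enrichment_fraction`` of peaks is placed fully inside
    insertions of ``target_subfamily``; the rest are uniform genome-wide,
    avoiding the blacklist. Per-sample RPKMs are drawn around a per-peak truth
    value with multiplicative noise of the given CV.
    """
    if not 0 <= params.enrichment_fraction <= 1:
        raise ValueError("enrichment_fraction must be in [0, 1]")
    rng = child_rng(seed, "peaks")
    n_in = int(round(params.enrichment_fraction * params.count))
    if n_in > 0:
        if te is None or params.target_subfamily is None:
            raise ValueError("enrichment requires a TE annotation and target subfamily")
        insertions = te.intervals_of(subfamily=params.target_subfamily)
        insertions = [iv for iv in insertions if iv.length >= params.min_length]
        if not insertions:
            raise ValueError(
                f"no {params.target_subfamily} insertion can hold a peak of "
                f"length >= {params.min_length}"
            )
    lengths = np.clip(
        np.round(rng.lognormal(np.log(params.mean_length), params.sigma_log, params.count)),
        params.min_length,
        params.max_length,
    ).astype(int)

    ex_index = None
    if blacklist is not None and len(blacklist):
        ex_index = IntervalIndex(list(blacklist), genome)

    intervals: list[Interval] = []
    planted = np.zeros(params.count, dtype=bool)
    ins_lens = np.array([iv.length for iv in insertions], dtype=float) if n_in else None
    for i in range(params.count):
        L = int(lengths[i])
        if i < n_in:
            j = int(rng.choice(len(insertions), p=ins_lens / ins_lens.sum()))
            ins = insertions[j]
            L = min(L, ins.length)
            lengths[i] = L
            start = int(rng.integers(ins.start, ins.end - L + 1))
            intervals.append(Interval(ins.chrom, start, start + L))
            planted[i] = True
        else:
            for attempt in range(1000):
                feas = np.clip(genome.chrom_lengths - L + 1, 0, None).astype(float)
                ci = int(rng.choice(len(feas), p=feas / feas.sum()))
                start = int(rng.integers(0, int(feas[ci])))
                iv = Interval(genome.chrom_names[ci], start, start + L)
                if ex_index is None:
                    break
                s, e = genome.to_absolute([iv])
                if int(ex_index.coverage(s, e)[0]) == 0:
                    break
            else:
                raise RuntimeError("could not place peak outside the blacklist")
            intervals.append(iv)

    true_rpkm = rng.lognormal(np.log(params.base_rpkm), params.rpkm_sigma_log, params.count)
    peaks = []
    for i, iv in enumerate(intervals):
        noise = _lognormal_mean1(rng, params.noise_cv, len(params.samples))
        rpkms = {s: float(true_rpkm[i] * noise[j]) for j, s in enumerate(params.samples)}
        peaks.append(Peak(iv, f"peak_{i:05d}", rpkms))
    truth = pd.DataFrame(
        {
            "peak_id": [p.id for p in peaks],
            "chrom": [p.interval.chrom for p in peaks],
            "start": [p.interval.start for p in peaks],
            "end": [p.interval.end for p in peaks],
            "planted_in_target": planted,
            "true_rpkm": true_rpkm,
        }
    )
    return PeakSet(peaks, genome), truth


def gen_wt_ko_peaks(
    genome: GenomeSpec,
    count: int = 300,
    enhanced_fraction: float = 0.3,
    ko_factor: float = 2.0,
    noise_cv: float = 0.1,
    n_reps: int = 2,
    mean_length: float = 600.0,
    base_rpkm: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Non-overlapping UBP-style intervals with planted KO-enhanced peaks.

    Returns a table with per-condition replicate-mean RPKMs and the planted
    class truth. Planted enhanced peaks have true KO RPKM = ko_factor x WT.
    """
    rng = child_rng(seed, "wt_ko_peaks")
    lengths = np.clip(
        np.round(rng.lognormal(np.log(mean_length), 0.4, count)), 100, 10_000
    ).astype(int)
    occupied: dict[str, list[tuple[int, int]]] = {}
    intervals = _place_nonoverlapping(rng, [int(l) for l in lengths], genome, occupied)
    n_enh = int(round(enhanced_fraction * count))
    enhanced = np.zeros(count, dtype=bool)
    enhanced[:n_enh] = True
    wt_true = rng.lognormal(np.log(base_rpkm), 0.4, count)
    ko_true = wt_true * np.where(enhanced, ko_factor, 1.0)
    wt_obs = (wt_true[:, None] * _lognormal_mean1(rng, noise_cv, (count, n_reps))).mean(axis=1)
    ko_obs = (ko_true[:, None] * _lognormal_mean1(rng, noise_cv, (count, n_reps))).mean(axis=1)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "wt_rpkm": wt_obs,
            "ko_rpkm": ko_obs,
            "true_enhanced": enhanced,
            "wt_true": wt_true,
            "ko_true": ko_true,
        }
    )


# ----------------------------------------------------------------- genes


def gen_genes(
    genome: GenomeSpec,
    count: int = 40,
    mean_length: float = 20_000.0,
    seed: int = 0,
):
    """Non-overlapping gene models with random strands; TSS is strand-resolved."""
    from .genome import GeneModel

    rng = child_rng(seed, "genes")
    lengths = np.clip(
        np.round(rng.lognormal(np.log(mean_length), 0.4, count)), 1000, None
    ).astype(int)
    occupied: dict[str, list[tuple[int, int]]] = {}
    intervals = _place_nonoverlapping(rng, [int(l) for l in lengths], genome, occupied)
    genes = []
    for i, iv in enumerate(intervals):
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (iv.start, iv.end) if strand == "+" else (iv.end, iv.start)
        genes.append(GeneModel(f"gene_{i:04d}", iv.chrom, tss, tes, strand))
    return genes


# ----------------------------------------------------------------- reads/SNPs


@dataclass
class ReadParams:
    count: int = 1000
    length: int = 5000
    n_deletion_rate: float = 0.0
    error_rate: float = 0.0


def gen_snp_table(
    genome: SyntheticGenome,
    snp_density: float,
    seed: int,
) -> pd.DataFrame:
    """Biallelic SNPs at the given density (SNPs per kb), unique positions.

    The maternal base follows the reference sequence when available; the
    paternal base is a different random base.
    """
    rng = child_rng(seed, "snps")
    rows = []
    for chrom in genome.spec.chrom_names:
        length = genome.spec.length_of(chrom)
        n = int(round(snp_density * length / 1000))
        n = min(n, length)
        positions = np.sort(rng.choice(length, size=n, replace=False))
        for pos in positions:
            if genome.sequences is not None:
                mat = genome.sequences[chrom][pos]
                if mat == "N":
                    mat = "A"
            else:
                mat = "ACGT"[rng.integers(4)]
            others = [b for b in "ACGT" if b != mat]
            pat = others[rng.integers(3)]
            rows.append({"chrom": chrom, "pos": int(pos), "maternal": mat, "paternal": pat})
    return pd.DataFrame(rows, columns=["chrom", "pos", "maternal", "paternal"])


def gen_reads_with_snps(
    genome: SyntheticGenome,
    snps: pd.DataFrame,
    params: ReadParams,
    maternal_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reads of known parental origin with per-SNP observations.

    Returns (observations, truth). Observations have one row per covered
    known SNP site: read_id, chrom, pos, base (base call or DEL). With zero
    error and N-deletion rates, every observation matches the read's true
    parental allele.
    """
    if not 0 <= maternal_fraction <= 1:
        raise ValueError("maternal_fraction must be in [0, 1]")
    rng = child_rng(seed, "reads")
    spec = genome.spec
    snp_pos = {
        chrom: grp.sort_values("pos").reset_index(drop=True)
        for chrom, grp in snps.groupby("chrom")
    }
    obs_rows, truth_rows = [], []
    feas = np.clip(spec.chrom_lengths - params.length + 1, 0, None).astype(float)
    if feas.sum() == 0:
        raise ValueError("read length exceeds every chromosome")
    for i in range(params.count):
        read_id = f"read_{i:06d}"
        origin = "maternal" if rng.random() < maternal_fraction else "paternal"
        ci = int(rng.choice(len(feas), p=feas / feas.sum()))
        chrom = spec.chrom_names[ci]
        start = int(rng.integers(0, int(feas[ci])))
        end = start + params.length
        covered = 0
        if chrom in snp_pos:
            tab = snp_pos[chrom]
            lo = int(np.searchsorted(tab["pos"].to_numpy(), start, side="left"))
            hi = int(np.searchsorted(tab["pos"].to_numpy(), end, side="left"))
            for j in range(lo, hi):
                covered += 1
                pos = int(tab.at[j, "pos"])
                true_base = tab.at[j, "maternal" if origin == "maternal" else "paternal"]
                u = rng.random()
                if u < params.n_deletion_rate:
                    base = "DEL"
                elif u < params.n_deletion_rate + params.error_rate:
                    base = "ACGT"[rng.integers(4)]
                else:
                    base = true_base
                obs_rows.append({"read_id": read_id, "chrom": chrom, "pos": pos, "base": base})
        truth_rows.append(
            {"read_id": read_id, "origin": origin, "chrom": chrom,
             "start": start, "end": end, "n_snps_covered": covered}
        )
    observations = pd.DataFrame(obs_rows, columns=["read_id", "chrom", "pos", "base"])
    truth = pd.DataFrame(truth_rows)
    return observations, truth


# ----------------------------------------------------------------- expression


@dataclass
class ExprParams:
    n_minor: int = 50
    n_major: int = 30
    n_null: int = 120
    n_down: int = 40
    fold_down: float = 4.0
    n_reps: int = 4
    noise_cv: float = 0.05


def gen_expression(params: ExprParams, seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stage-profile and WT/KO replicate FPKM tables with planted truth.

    Returns (stage_table, wt_matrix, ko_matrix, truth). Planted minor genes
    satisfy the minor rule with margin (oocyte FPKM < 2, embryonic stages in
    [8, 50]); planted major genes have oocyte FPKM in [6, 15] and a late
    2-cell rise of 6-10x; null genes are flat. The first ``n_down`` genes are
    downregulated ``fold_down``-fold in the KO matrix.
    """
    rng = child_rng(seed, "expression")
    n_genes = params.n_minor + params.n_major + params.n_null
    if params.n_down > n_genes:
        raise ValueError("n_down exceeds the number of genes")
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    classes = (
        ["minor"] * params.n_minor + ["major"] * params.n_major + ["none"] * params.n_null
    )
    rows = []
    for cls in classes:
        if cls == "minor":
            fgo, mii = rng.uniform(0, 2, 2)
            c1, e2c = rng.uniform(8, 50, 2)
            l2c = rng.uniform(8, 50)
        elif cls == "major":
            fgo, mii = rng.uniform(6, 15, 2)
            c1, e2c = rng.uniform(6, 30, 2)
            l2c = ((fgo + mii) / 2) * rng.uniform(6, 10)
        else:
            level = rng.uniform(0.5, 20)
            fgo, mii, c1, e2c, l2c = level * rng.uniform(0.98, 1.02, 5)
        rows.append({"FGO": fgo, "MII": mii, "c1": c1, "e2c": e2c, "l2c": l2c})
    stage = pd.DataFrame(rows, index=gene_ids)
    stage.insert(0, "gene_id", gene_ids)

    wt_true = rng.lognormal(np.log(20), 0.8, n_genes)
    down = np.zeros(n_genes, dtype=bool)
    down[: params.n_down] = True
    ko_true = wt_true / np.where(down, params.fold_down, 1.0)
    rep_cols = [f"rep{r + 1}" for r in range(params.n_reps)]
    wt = pd.DataFrame(
        wt_true[:, None] * _lognormal_mean1(rng, params.noise_cv, (n_genes, params.n_reps)),
        index=gene_ids, columns=rep_cols,
    )
    ko = pd.DataFrame(
        ko_true[:, None] * _lognormal_mean1(rng, params.noise_cv, (n_genes, params.n_reps)),
        index=gene_ids, columns=rep_cols,
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "zga_class": classes,
            "true_down": down,
            "wt_true": wt_true,
            "ko_true": ko_true,
        }
    )
    return stage, wt, ko, truth


# ----------------------------------------------------------------- methylation


@dataclass
class MethRegionSpec:
    region: Interval
    context: str  # WCG or GCH
    level: float
    n_calls: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.level <= 1:
            raise ValueError("true methylation level must be in [0, 1]")


def gen_methylation(
    genome: SyntheticGenome,
    specs: list[MethRegionSpec],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site methylation calls with region-level true rates.

    Sites of the requested context are located in the genome sequence (both
    strands); each call picks a site uniformly and a methylated flag from a
    Bernoulli draw at the region's true level.
    """
    if genome.sequences is None:
        raise ValueError("methylation simulation needs genome sequences")
    rng = child_rng(seed, "methylation")
    call_rows, truth_rows = [], []
    for spec in specs:
        region, context = spec.region, spec.context
        seq = genome.sequences[region.chrom]
        lo = max(0, region.start - 1)
        hi = min(len(seq), region.end + 1)
        sites = find_context_sites(seq[lo:hi], context=context)
        sites = sites[(sites["pos"] + lo >= region.start) & (sites["pos"] + lo < region.end)]
        if sites.empty:
            raise ValueError(
                f"no {context} site inside {region.chrom}:{region.start}-{region.end}"
            )
        idx = rng.integers(0, len(sites), size=spec.n_calls)
        meth = rng.random(spec.n_calls) < spec.level
        for j, m in zip(idx, meth):
            row = sites.iloc[int(j)]
            call_rows.append(
                {
                    "chrom": region.chrom,
                    "pos": int(row["pos"]) + lo,
                    "strand": row["strand"],
                    "context": context,
                    "methylated": int(m),
                }
            )
        truth_rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "context": context,
                "true_level": spec.level,
                "n_calls": spec.n_calls,
            }
        )
    calls = pd.DataFrame(call_rows, columns=["chrom", "pos", "strand", "context", "methylated"])
    truth = pd.DataFrame(truth_rows)
    return calls, truth
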
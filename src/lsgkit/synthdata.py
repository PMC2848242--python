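"""Seeded synthetic data with known planted truth for every pipeline stage.

The generator emulates the shape of the study system without any download:

* a tissue expression panel (18 tissues by default) and a peripartal liver
  time series (7 time points from -65 to +49 days around parturition, two
  diets, replicate animals), with planted co-expression clusters driven by
  a shared latent factor (x_g = sqrt(rho) z + sqrt(1-rho) eps, giving
  expected pairwise Pearson r = rho), tissue-preferential genes (>= 2-fold
  over every other tissue) and diet effects of a configurable fold
  (~1.8-fold in the emulated study) at chosen time points;
* 1100-nt promoters (a [-1000, +100] TSS window) with exact-consensus
  motif instances and ordered composites planted at controlled rates and
  gap distances over a background promoter population, soft-masked
  "repeat" blocks emitted as lowercase;
* a synthetic PWM library in TRANSFAC flat format; and
* a toy genome FASTA plus BED6 TSS annotation for coordinate round-trips.

Everything derives from one integer seed: identical configuration means
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exprdata import ExpressionMatrix, RatioMatrix
from .motifscan import PWM, write_transfac

BASES = "ACGT"
DEFAULT_TIMEPOINTS = (-65, -30, -14, 1, 14, 28, 49)
DEFAULT_DIETS = ("adlib", "restricted")


class ConfigurationError(ValueError):
    pass


class PlantingError(RuntimeError):
    pass


@dataclass
class ClusterSpec:
    size: int
    latent_r: float = 0.95
    preferred_tissue: str | None = None
    fold: float = 2.0


@dataclass
class DietEffectSpec:
    n_genes: int
    times: tuple = (1, 14)
    fold: float = 1.8
    direction: int = -1  # -1: under-expressed on the restricted diet


@dataclass
class PromoterSpec:
    n_fg: int = 100
    n_bg: int = 1000
    length: int = 1100
    gc: float = 0.5
    masked_fraction: float = 0.1


@dataclass
class PlantSpec:
    pwm_ids: tuple[str, ...]
    rate: float = 1.0  # foreground planting rate
    bg_rate: float = 0.0
    gap_range: tuple[int, int] = (20, 250)
    ordered: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1 or not 0 <= self.bg_rate <= 1:
            raise ConfigurationError("planting rates must lie in [0, 1]")
        lo, hi = self.gap_range
        if not (0 <= lo <= hi <= 250):
            raise ConfigurationError("gap ranges must lie within [0, 250]")


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 1000
    n_tissues: int = 18
    timepoints: tuple = DEFAULT_TIMEPOINTS
    diets: tuple = DEFAULT_DIETS
    replicates: int = 5
    cluster_specs: list[ClusterSpec] = field(default_factory=list)
    diet_effect_specs: list[DietEffectSpec] = field(default_factory=list)
    noise_sd: float = 0.3  # replicate-level noise, log2 units
    amplitude: float = 2.0  # latent profile amplitude, log2 units
    base_log2: float = 9.0  # median log2 intensity (~512 units)
    base_sd: float = 1.5
    intensity_floor: float = 1.0
    neg_control_median: float = 50.0

    def __post_init__(self) -> None:
        for cs in self.cluster_specs:
            if cs.size > self.n_genes:
                raise ConfigurationError("cluster size exceeds n_genes")
        if sum(cs.size for cs in self.cluster_specs) > self.n_genes:
            raise ConfigurationError("cluster sizes exceed n_genes")


@dataclass
class PlantedTruth:
    clusters: dict[str, list[str]] = field(default_factory=dict)
    tissue_preferential: dict[str, list[str]] = field(default_factory=dict)
    diet_effects: list[dict] = field(default_factory=list)
    promoter_records: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# PWM library
# ---------------------------------------------------------------------------

def gen_pwm_library(
    n: int,
    width_range: tuple[int, int] = (6, 12),
    seed: int = 0,
    depth: int = 20,
    out_path=None,
) -> list[PWM]:
    """Random informative PWMs with constant per-position count depth.

    Each position gives its consensus base 85-100% of the depth.  The
    sharpness emulates a minimized-false-positive matrix profile: at the
    usual similarity thresholds (core 0.9, matrix 0.85) chance matches in
    random sequence are rare, so planted instances dominate scan output.
    """
    lo, hi = width_range
    if lo > hi or lo < 4:
        raise ConfigurationError(f"invalid width range {width_range}")
    rng = np.random.default_rng(seed)
    pwms: list[PWM] = []
    for i in range(n):
        width = int(rng.integers(lo, hi + 1))
        counts = np.zeros((width, 4))
        for pos in range(width):
            cons = int(rng.integers(4))
            major = int(rng.integers(int(0.9 * depth), depth + 1))
            counts[pos, cons] = major
            rest = depth - major
            others = [b for b in range(4) if b != cons]
            split = rng.multinomial(rest, [1 / 3] * 3)
            for b, c in zip(others, split):
                counts[pos, b] += c
        pwms.append(PWM(f"M{i + 1:03d}", counts, name=f"SYN{i + 1}"))
    if out_path is not None:
        write_transfac(pwms, out_path)
    return pwms


# ---------------------------------------------------------------------------
# Promoters with planted motifs / composites
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def _soft_mask(rng: np.random.Generator, seq: str, fraction: float) -> str:
    """Lowercase contiguous blocks until roughly ``fraction`` is masked."""
    if fraction <= 0:
        return seq
    chars = list(seq)
    target = int(round(fraction * len(seq)))
    masked = 0
    guard = 0
    while masked < target and guard < 1000:
        guard += 1
        block = int(rng.integers(20, 120))
        start = int(rng.integers(0, max(1, len(seq) - block)))
        for i in range(start, min(start + block, len(seq))):
            if chars[i].isupper():
                chars[i] = chars[i].lower()
                masked += 1
            if masked >= target:
                break
    return "".join(chars)


def _plant_in_promoter(
    rng: np.random.Generator,
    seq: str,
    words: list[str],
    gap_range: tuple[int, int],
    occupied: list[tuple[int, int]],
    promoter_id: str,
    max_retries: int = 50,
) -> tuple[str, list[int], list[int]]:
    """Insert consensus words left-to-right with sampled gaps; no overlap.

    Returns (sequence, 0-based start positions, gaps used).  Collisions
    with previously planted spans are retried a bounded number of times.
    """
    L = len(seq)
    for _attempt in range(max_retries):
        gaps = [int(rng.integers(gap_range[0], gap_range[1] + 1)) for _ in words[1:]]
        span = sum(len(w) for w in words) + sum(gaps)
        if span > L:
            raise PlantingError(
                f"{promoter_id}: planted span {span} exceeds promoter length {L}"
            )
        start0 = int(rng.integers(0, L - span + 1))
        positions = []
        pos = start0
        for j, w in enumerate(words):
            if j > 0:
                pos += gaps[j - 1]
            positions.append(pos)
            pos += len(w)
        spans = [(p, p + len(w) - 1) for p, w in zip(positions, words)]
        if any(s <= e2 and e >= s2 for s, e in spans for s2, e2 in occupied):
            continue
        chars = list(seq)
        for p, w in zip(positions, words):
            chars[p : p + len(w)] = list(w)  # uppercase: planted sites unmasked
        occupied.extend(spans)
        return "".join(chars), positions, gaps
    raise PlantingError(f"{promoter_id}: could not place motifs without collision")


def gen_promoters(
    pspec: PromoterSpec,
    plant_specs: list[PlantSpec],
    pwms: dict[str, PWM] | list[PWM],
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], PlantedTruth]:
    """Foreground and background promoter sets with planted-truth records.

    Planted instances are the exact consensus words of the named PWMs,
    inserted on the forward strand at recorded 0-based positions with
    consecutive gaps drawn uniformly from the spec's gap range.
    """
    if isinstance(pwms, list):
        pwms = {p.matrix_id: p for p in pwms}
    for ps in plant_specs:
        span = sum(pwms[m].width for m in ps.pwm_ids) + ps.gap_range[1] * (
            len(ps.pwm_ids) - 1
        )
        if pspec.length < span:
            raise ConfigurationError(
                f"promoter length {pspec.length} < max planted span {span}"
            )
    rng = np.random.default_rng(seed)
    truth = PlantedTruth()
    out: list[dict[str, str]] = []
    for setname, n_prom, rate_attr in (
        ("fg", pspec.n_fg, "rate"),
        ("bg", pspec.n_bg, "bg_rate"),
    ):
        seqs: dict[str, str] = {}
        for i in range(n_prom):
            pid = f"{setname}{i + 1:04d}"
            seq = _random_seq(rng, pspec.length, pspec.gc)
            seq = _soft_mask(rng, seq, pspec.masked_fraction)
            occupied: list[tuple[int, int]] = []
            for ps in plant_specs:
                if rng.random() >= getattr(ps, rate_attr):
                    continue
                words = [pwms[m].consensus for m in ps.pwm_ids]
                seq, positions, gaps = _plant_in_promoter(
                    rng, seq, words, ps.gap_range, occupied, pid
                )
                truth.promoter_records.append(
                    {
                        "promoter": pid,
                        "set": setname,
                        "pwm_ids": list(ps.pwm_ids),
                        "positions": positions,
                        "gaps": gaps,
                        "ordered": ps.ordered,
                    }
                )
            seqs[pid] = seq
        out.append(seqs)
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:04d}" for i in range(n)]


def _assign_clusters(sim: SimConfig) -> tuple[list[str], dict[str, list[str]]]:
    genes = _gene_ids(sim.n_genes)
    clusters: dict[str, list[str]] = {}
    cursor = 0
    for ci, cs in enumerate(sim.cluster_specs, start=1):
        clusters[f"cluster{ci}"] = genes[cursor : cursor + cs.size]
        cursor += cs.size
    return genes, clusters


def gen_expression_panel(sim: SimConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Tissue-panel intensities with planted clusters and preferences.

    Latent-factor model on the log2 scale: within a planted cluster
    x_g = base_g + amplitude * (sqrt(r) z_tissue + sqrt(1-r) eps), so the
    expected pairwise correlation equals the spec's latent_r.  Preferred-
    tissue genes afterwards get their target tissue set to exactly
    fold x the maximum over other tissues (the inclusive >= fold rule
    passes by construction).  Intensities are 2**x with a configurable
    floor; present flags and negative-control medians are emitted so the
    detection filters have nontrivial effect.
    """
    rng = np.random.default_rng(sim.seed)
    genes, clusters = _assign_clusters(sim)
    tissues = [f"tissue{j + 1:02d}" for j in range(sim.n_tissues)]
    base = rng.normal(sim.base_log2, sim.base_sd, size=sim.n_genes)
    x = base[:, None] + sim.amplitude * rng.standard_normal((sim.n_genes, sim.n_tissues))
    truth = PlantedTruth(clusters=clusters)
    gidx = {g: i for i, g in enumerate(genes)}
    for cs, (cname, members) in zip(sim.cluster_specs, clusters.items()):
        z = rng.standard_normal(sim.n_tissues)
        for g in members:
            i = gidx[g]
            eps = rng.standard_normal(sim.n_tissues)
            x[i] = base[i] + sim.amplitude * (
                np.sqrt(cs.latent_r) * z + np.sqrt(1 - cs.latent_r) * eps
            )
    intensity = np.maximum(2.0 ** x, sim.intensity_floor)
    for cs, (cname, members) in zip(sim.cluster_specs, clusters.items()):
        if cs.preferred_tissue is None:
            continue
        tj = tissues.index(cs.preferred_tissue)
        for g in members:
            i = gidx[g]
            others = np.delete(intensity[i], tj)
            intensity[i, tj] = cs.fold * others.max()
        truth.tissue_preferential[cs.preferred_tissue] = list(members)
    df = pd.DataFrame(intensity, index=genes, columns=tissues)
    present = pd.DataFrame(
        intensity > 2.0 * sim.neg_control_median, index=genes, columns=tissues
    )
    meta = pd.DataFrame(
        {
            "tissue": tissues,
            "neg_control_median": sim.neg_control_median,
        },
        index=pd.Index(tissues, name="sample"),
    )
    return ExpressionMatrix(intensity=df, meta=meta, present=present), truth


def gen_expression_timeseries(
    sim: SimConfig,
) -> tuple[ExpressionMatrix, RatioMatrix, PlantedTruth]:
    """Liver-style time series: log2 ratios plus raw-intensity companions.

    Samples are time x diet x replicate.  Cluster genes share a latent
    per-condition profile (expected pairwise r = latent_r on condition
    means); diet-affected genes carry a true log2 effect of
    direction * log2(fold) on the second (restricted) diet at the named
    time points.  Per-spot p-values versus the reference pool are emitted
    from the replicate-noise model so the significance filter is
    exercised.
    """
    rng = np.random.default_rng(sim.seed + 1)
    genes, clusters = _assign_clusters(sim)
    conditions = [(t, d) for t in sim.timepoints for d in sim.diets]
    samples = [
        f"t{t}_{d}_r{r + 1}"
        for (t, d) in conditions
        for r in range(sim.replicates)
    ]
    meta = pd.DataFrame(
        {
            "time": [t for (t, d) in conditions for _ in range(sim.replicates)],
            "diet": [d for (t, d) in conditions for _ in range(sim.replicates)],
            "replicate": [
                r + 1 for _ in conditions for r in range(sim.replicates)
            ],
            "neg_control_median": sim.neg_control_median,
        },
        index=pd.Index(samples, name="sample"),
    )
    n_cond = len(conditions)
    n_time = len(sim.timepoints)
    n_tr = n_time * sim.replicates
    # Non-cluster genes follow a diet-independent temporal profile; cluster
    # genes share a latent factor drawn per (time, replicate-animal) and
    # identical for both diets.  Planted effects are therefore the only
    # systematic diet signal, and because latent draws are shared between
    # diets they cancel exactly from every diet-within-time estimate.
    base_tr = np.zeros((sim.n_genes, n_tr))
    time_profile = sim.amplitude * rng.standard_normal((sim.n_genes, n_time)) * 0.3
    gidx = {g: i for i, g in enumerate(genes)}
    truth = PlantedTruth(clusters=clusters)
    in_cluster = np.zeros(sim.n_genes, dtype=bool)
    for cs, (cname, members) in zip(sim.cluster_specs, clusters.items()):
        z = rng.standard_normal(n_tr)
        for g in members:
            i = gidx[g]
            in_cluster[i] = True
            eps = rng.standard_normal(n_tr)
            base_tr[i] = sim.amplitude * (
                np.sqrt(cs.latent_r) * z + np.sqrt(1 - cs.latent_r) * eps
            )
    base_tr[~in_cluster] = np.repeat(
        time_profile[~in_cluster], sim.replicates, axis=1
    )
    tindex = {t: j for j, t in enumerate(sim.timepoints)}
    cond_mean = np.zeros((sim.n_genes, n_cond))
    # planted diet effects (applied to the second diet at the named times)
    cursor = 0
    for spec in sim.diet_effect_specs:
        members = genes[cursor : cursor + spec.n_genes]
        cursor += spec.n_genes
        effect = spec.direction * np.log2(spec.fold)
        for g in members:
            i = gidx[g]
            for ci, (t, d) in enumerate(conditions):
                if t in set(spec.times) and d == sim.diets[1]:
                    cond_mean[i, ci] += effect
        truth.diet_effects.append(
            {
                "genes": list(members),
                "times": list(spec.times),
                "log2_effect": float(effect),
                "fold": spec.fold,
            }
        )
    ratios = np.repeat(cond_mean, sim.replicates, axis=1)
    # add the (time, replicate) baseline, identical for both diets
    col = 0
    for (t, _d) in conditions:
        j = tindex[t]
        for r in range(sim.replicates):
            ratios[:, col] += base_tr[:, j * sim.replicates + r]
            col += 1
    ratios = ratios + sim.noise_sd * rng.standard_normal(ratios.shape)
    rdf = pd.DataFrame(ratios, index=genes, columns=samples)
    # companion raw intensities and per-spot significance vs the reference
    base = rng.normal(sim.base_log2, sim.base_sd, size=sim.n_genes)
    intensity = np.maximum(
        2.0 ** (base[:, None] + 0.5 * rng.standard_normal(ratios.shape)),
        sim.intensity_floor,
    )
    from scipy import stats as _st

    pvals = 2.0 * _st.norm.sf(np.abs(ratios) / sim.noise_sd)
    idf = pd.DataFrame(intensity, index=genes, columns=samples)
    pdf = pd.DataFrame(pvals, index=genes, columns=samples)
    present = pd.DataFrame(
        intensity > 2.0 * sim.neg_control_median, index=genes, columns=samples
    )
    em = ExpressionMatrix(intensity=idf, meta=meta, present=present, pvals=pdf)
    return em, RatioMatrix(ratios=rdf, meta=meta), truth


# ---------------------------------------------------------------------------
# Genome + TSS annotation
# ---------------------------------------------------------------------------

def gen_annotation(
    n_genes: int,
    genome_len: int,
    seed: int = 0,
    gc: float = 0.5,
    masked_fraction: float = 0.0,
    plant: dict[int, tuple[str, int]] | None = None,
    window: tuple[int, int] = (-1000, 100),
):
    """Toy genome (one contig) and BED6 TSS annotation, both strands.

    TSSs are spaced so every promoter window fits inside the contig.
    ``plant`` optionally writes a word into gene i's promoter at a 0-based
    promoter offset (strand-aware), for coordinate round-trip checks.
    Returns (genome dict, TSS records, bed lines).
    """
    from .promoters import TSSRecord, reverse_complement

    up, down = window
    wlen = -up + down
    if genome_len <= n_genes * (wlen + 200):
        raise ConfigurationError(
            f"genome length {genome_len} too short for {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, genome_len, gc)
    seq = _soft_mask(rng, seq, masked_fraction)
    slot = genome_len // n_genes
    records = []
    chars = list(seq)
    for i in range(n_genes):
        strand = "+" if (n_genes == 1 or rng.random() < 0.5) else "-"
        jitter = int(rng.integers(-slot // 8, slot // 8 + 1))
        pos = i * slot + slot // 2 + jitter
        # clamp so the strand-aware window sits fully inside the contig
        if strand == "+":
            pos = min(max(pos, -up + 1), genome_len - down)
        else:
            pos = min(max(pos, down), genome_len + up)
        rec = TSSRecord("chr1", pos, strand, f"g{i + 1:04d}")
        records.append(rec)
        if plant and i in plant:
            word, off = plant[i]
            if strand == "+":
                gstart = pos + up + off  # 1-based genomic start of the word
                chars[gstart - 1 : gstart - 1 + len(word)] = list(word)
            else:
                gend = pos - up - off  # word's first base maps here (1-based)
                rc = reverse_complement(word)
                chars[gend - len(word) : gend] = list(rc)
    genome = {"chr1": "".join(chars)}
    bed_lines = [
        "\t".join(
            [
                r.chrom,
                str(r.position - 1 if r.strand == "+" else r.position - 1),
                str(r.position if r.strand == "+" else r.position),
                r.gene_id,
                "0",
                r.strand,
            ]
        )
        for r in records
    ]
    return genome, records, bed_lines


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(lines: list[str], path) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
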
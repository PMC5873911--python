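"""Synthetic cohorts of serially allografted tumors.

Generates toy genomes (binned GC and mappability tracks, under-replicated /
repeat / gene / exome intervals), tumor lineages propagated through rounds of
allograft with per-passage lesion birth and retention, and binned read
coverage with GC bias, mappability dropout and polytene under-replication of
the larval control.  Every draw is reproducible from ``SimConfig.seed``.

The coverage mean model per 1 kb bin is

    mu = depth * (copy / 2) * exp(b(gc)) * mappability * u

where ``b`` is a quadratic in GC on the log scale, ``copy`` is the true copy
number of the bin given sex and somatic CNVs, and ``u = ur_factor`` inside
under-replicated intervals of a control (polytene) sample, 1 otherwise.
The emitted value is the mean per-base depth over the bin, built from a
negative-binomial draw of the number of reads hitting the bin
(mean ``mu * binlen / read_length``, variance ``overdispersion`` times the
mean) — the noise a 1 kb-binned whole-genome run actually shows, where the
sampling unit is the read, not the bin.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "SimConfig",
    "LineageTruth",
    "SampleInfo",
    "simulate_genome",
    "simulate_lineage",
    "simulate_coverage",
    "simulate_cohort",
]

#: default toy arm lengths (bp); six arms totalling 20 Mb so that the full
#: pipeline runs in seconds, plus a short repeat-free Y proxy region used
#: only for sex inference (a kl-2-like interval, not real heterochromatin).
DEFAULT_CHROM_LENGTHS = {
    "X": 4_000_000,
    "2L": 3_500_000,
    "2R": 3_500_000,
    "3L": 3_500_000,
    "3R": 4_000_000,
    "4": 1_500_000,
}
DEFAULT_Y_LENGTH = 300_000

DEFAULT_SPECTRUM = {
    # pyrimidine-reference six-class substitution probabilities; C>A-heavy,
    # as in tumors under oxidative stress (8-oxo-dG damage)
    "C>A": 0.40,
    "C>G": 0.08,
    "C>T": 0.22,
    "T>A": 0.08,
    "T>C": 0.15,
    "T>G": 0.07,
}

_CLASS_TO_PAIRS = {
    "C>A": (("C", "A"), ("G", "T")),
    "C>G": (("C", "G"), ("G", "C")),
    "C>T": (("C", "T"), ("G", "A")),
    "T>A": (("T", "A"), ("A", "T")),
    "T>C": (("T", "C"), ("A", "G")),
    "T>G": (("T", "G"), ("A", "C")),
}


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of a synthetic allograft study.

    Rates are per passage, where a passage is one step of the sampled
    schedule (e.g. T0 -> T5 is one step).  ``retention_prob`` is the
    probability that an existing lesion survives one such step.
    """

    seed: int = 0
    # genome geometry
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    bin_size: int = 1000
    y_length: int = DEFAULT_Y_LENGTH
    gc_autocorr: float = 0.98  # AR(1) coefficient of the smooth GC track
    gc_mean: float = 0.42
    gc_sd: float = 0.06
    zero_mappability_fraction: float = 0.02
    ur_fraction: float = 0.05
    ur_size_range: tuple = (100_000, 400_000)
    repeat_fraction: float = 0.03
    repeat_size_range: tuple = (5_000, 50_000)
    gene_size_range: tuple = (2_000, 20_000)
    gene_gap_mean: float = 5_000.0
    exome_fraction_of_gene: float = 0.6
    # coverage model
    depth: float = 50.0  # mean per-base sequencing depth
    read_length: int = 100
    gc_bias_coeffs: tuple = (0.0, 0.6, -8.0)  # log-scale: c0 + c1*dg + c2*dg^2
    gc_center: float = 0.45
    overdispersion: float = 1.2  # Fano factor of the read count per bin (1 = Poisson)
    ur_factor: float = 0.3  # control under-replication multiplier in (0, 1]
    sex: str = "male"
    # lineage dynamics
    line_name: str = "L1"
    timepoints: tuple = (0, 5, 10)
    split_at: float | None = None  # passage at which the line splits (last step)
    cnv_rate_per_passage: float = 4.0
    snp_rate_per_passage: float = 40.0
    cnv_size_law: tuple = (50_000, 500_000)  # log-uniform range, bp
    cnv_min_gap: int = 50_000  # lesions closer than this are not separable events
    cnv_state_probs: dict = field(
        default_factory=lambda: {1: 0.45, -1: 0.45, 2: 0.05, -2: 0.05}
    )
    cnv_avoid_masked: bool = True  # place CNVs clear of UR/repeat intervals
    retention_prob: float = 0.5
    spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    snp_exonic_nonsyn_prob: float = 0.7

    def __post_init__(self):
        if self.bin_size <= 0:
            raise InvalidConfigError("bin_size must be positive")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise InvalidConfigError(f"chromosome {name} has non-positive length")
        if not (0 < self.ur_factor <= 1):
            raise InvalidConfigError("ur_factor must be in (0, 1]")
        for r in (self.cnv_rate_per_passage, self.snp_rate_per_passage):
            if r < 0:
                raise InvalidConfigError("lesion rates must be >= 0")
        if not (0 <= self.retention_prob <= 1):
            raise InvalidConfigError("retention_prob must be in [0, 1]")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-6:
            raise InvalidConfigError(f"spectrum must sum to 1 (got {total})")
        if self.sex not in ("male", "female"):
            raise InvalidConfigError("sex must be 'male' or 'female'")
        tps = self.timepoints
        if len(tps) == 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise InvalidConfigError("timepoints must be non-empty and increasing")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GenomeModel:
    """Toy genome geometry on a fixed bin grid shared by all samples."""

    chrom_names: list
    chrom_lengths: dict
    bin_size: int
    gc: np.ndarray  # flat per-bin GC fraction over all arms
    mappability: np.ndarray  # flat per-bin mappability in [0, 1]
    ur_intervals: pd.DataFrame  # columns: chrom, start, end, id (0-based half-open)
    repeat_intervals: pd.DataFrame
    gene_intervals: pd.DataFrame
    exome_intervals: pd.DataFrame
    y_region: tuple | None = None  # (chrom, start, end) repeat-free Y proxy

    def __post_init__(self):
        offsets = {}
        pos = 0
        for name in self.chrom_names:
            n = self.n_bins(name)
            offsets[name] = (pos, pos + n)
            pos += n
        self._offsets = offsets
        self.n_bins_total = pos
        if len(self.gc) != pos or len(self.mappability) != pos:
            raise InvalidConfigError("track length does not match bin grid")
        # flat per-bin chrom / start arrays for table output
        chroms, starts = [], []
        for name in self.chrom_names:
            n = self.n_bins(name)
            chroms.append(np.repeat(name, n))
            starts.append(np.arange(n, dtype=np.int64) * self.bin_size)
        self.bin_chrom = np.concatenate(chroms)
        self.bin_start = np.concatenate(starts)
        self.bin_end = np.minimum(
            self.bin_start + self.bin_size,
            np.array([self.chrom_lengths[c] for c in self.bin_chrom]),
        )

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_lengths[chrom] / self.bin_size)

    def arm_slice(self, chrom: str) -> slice:
        lo, hi = self._offsets[chrom]
        return slice(lo, hi)

    @property
    def autosomes(self) -> list:
        return [c for c in self.chrom_names if c not in ("X", "Y")]

    def bins_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Flat indices of bins overlapping [start, end) on chrom by >= 1 bp."""
        lo, hi = self._offsets[chrom]
        first = lo + start // self.bin_size
        last = lo + (max(end - 1, start)) // self.bin_size
        return np.arange(first, min(last + 1, hi))

    def interval_mask(self, intervals: pd.DataFrame) -> np.ndarray:
        """Boolean flat mask of bins overlapping any interval by >= 1 bp."""
        mask = np.zeros(self.n_bins_total, dtype=bool)
        for row in intervals.itertuples(index=False):
            if row.chrom in self._offsets:
                mask[self.bins_in(row.chrom, int(row.start), int(row.end))] = True
        return mask


@dataclass
class SampleInfo:
    sample_id: str
    line: str
    timepoint: int
    role: str  # tumor | control
    donor_id: str
    split: str | None = None  # sub-line label (A/B) after a lineage split


@dataclass
class LineageTruth:
    """Ground truth for one simulated lineage (plus its donor control)."""

    samples: list  # SampleInfo, control first then tumors in passage order
    true_cnvs: pd.DataFrame  # sample_id, chrom, start, end, state, birth
    true_snps: pd.DataFrame  # sample_id, chrom, pos, ref, alt, aaf, f1r2, f2r1, region_class, birth

    def cnvs_for(self, sample_id: str) -> pd.DataFrame:
        return self.true_cnvs[self.true_cnvs.sample_id == sample_id].reset_index(drop=True)

    def snps_for(self, sample_id: str) -> pd.DataFrame:
        return self.true_snps[self.true_snps.sample_id == sample_id].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genome


def _smooth_track(rng, n, phi, mean, sd, squash=2.2):
    """Stationary AR(1) track squashed smoothly into mean ± squash*sd.

    The tanh squash gives the track compact support without the density gap
    or boundary point mass a hard clip would create; it is near-identity for
    excursions below ~1.5 sd.
    """
    if phi <= 0:
        z = rng.standard_normal(n)
    else:
        eps = rng.standard_normal(n) * math.sqrt(1 - phi**2)
        z = np.empty(n)
        z[0] = rng.standard_normal()
        for i in range(1, n):
            z[i] = phi * z[i - 1] + eps[i]
    return np.clip(mean + sd * squash * np.tanh(z / squash), 0.02, 0.98)


def _place_intervals(rng, length, target_bp, size_range, bin_size, prefix):
    """Non-overlapping bin-aligned intervals covering ~target_bp of an arm."""
    placed = []
    covered = 0
    attempts = 0
    while covered < target_bp and attempts < 1000:
        attempts += 1
        size = int(
            np.exp(rng.uniform(np.log(size_range[0]), np.log(size_range[1])))
        )
        size = max(bin_size, (size // bin_size) * bin_size)
        if size >= length:
            continue
        start = int(rng.integers(0, (length - size) // bin_size + 1)) * bin_size
        end = start + size
        if any(s < end and start < e for s, e in placed):
            continue
        placed.append((start, end))
        covered += size
    placed.sort()
    return placed


def simulate_genome(config: SimConfig) -> GenomeModel:
    """Draw a toy genome: smooth GC, mappability dropout, annotation intervals.

    Deterministic given ``config.seed``; two calls with the same config return
    identical models.
    """
    rng = np.random.default_rng([config.seed, 11])
    chrom_lengths = dict(config.chrom_lengths)
    chrom_names = list(chrom_lengths)
    if config.y_length > 0:
        chrom_names.append("Y")
        chrom_lengths["Y"] = config.y_length

    gc_parts, map_parts = [], []
    ur, rep, genes, exome = [], [], [], []
    total_bp = sum(config.chrom_lengths.values())
    for name in chrom_names:
        length = chrom_lengths[name]
        n = math.ceil(length / config.bin_size)
        gc_parts.append(
            _smooth_track(rng, n, config.gc_autocorr, config.gc_mean, config.gc_sd)
        )
        m = np.ones(n)
        if name != "Y" and config.zero_mappability_fraction > 0:
            k = int(round(config.zero_mappability_fraction * n))
            if k:
                m[rng.choice(n, size=k, replace=False)] = 0.0
        map_parts.append(m)
        if name == "Y":
            continue  # the Y proxy region is repeat-free and lesion-free
        for store, frac, size_range in (
            (ur, config.ur_fraction, config.ur_size_range),
            (rep, config.repeat_fraction, config.repeat_size_range),
        ):
            if frac <= 0:
                continue
            for s, e in _place_intervals(
                rng, length, frac * length, size_range, config.bin_size, name
            ):
                store.append((name, s, e))
        # genes tile the arm left to right with exponential gaps
        pos = int(rng.exponential(config.gene_gap_mean))
        while pos < length - config.gene_size_range[0]:
            size = int(
                np.exp(
                    rng.uniform(
                        np.log(config.gene_size_range[0]),
                        np.log(config.gene_size_range[1]),
                    )
                )
            )
            end = min(pos + size, length)
            genes.append((name, pos, end))
            pad = int((end - pos) * (1 - config.exome_fraction_of_gene) / 2)
            exome.append((name, pos + pad, end - pad))
            pos = end + int(rng.exponential(config.gene_gap_mean)) + 1

    def _df(rows, prefix):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["id"] = [f"{prefix}{i}" for i in range(len(df))]
        return df

    return GenomeModel(
        chrom_names=chrom_names,
        chrom_lengths=chrom_lengths,
        bin_size=config.bin_size,
        gc=np.concatenate(gc_parts),
        mappability=np.concatenate(map_parts),
        ur_intervals=_df(ur, "ur"),
        repeat_intervals=_df(rep, "rep"),
        gene_intervals=_df(genes, "gene"),
        exome_intervals=_df(exome, "ex"),
        y_region=("Y", 0, chrom_lengths["Y"]) if config.y_length > 0 else None,
    )


# ---------------------------------------------------------------------------
# lineage


class _Lesion:
    __slots__ = ("kind", "chrom", "start", "end", "state", "pos", "ref", "alt",
                 "aaf", "f1r2", "f2r1", "region_class", "birth")

    def __init__(self, **kw):
        for k in self.__slots__:
            setattr(self, k, kw.get(k))


def _draw_cnv(rng, model, config, active, blocked_mask):
    arms = [c for c in model.chrom_names if c not in ("Y",)]
    lengths = np.array([model.chrom_lengths[c] for c in arms], dtype=float)
    probs = lengths / lengths.sum()
    states = list(config.cnv_state_probs)
    sp = np.array([config.cnv_state_probs[s] for s in states], dtype=float)
    sp /= sp.sum()
    bs = config.bin_size
    for _ in range(100):
        chrom = arms[rng.choice(len(arms), p=probs)]
        size = int(np.exp(rng.uniform(np.log(config.cnv_size_law[0]),
                                      np.log(config.cnv_size_law[1]))))
        size = max(bs, (size // bs) * bs)
        if size >= model.chrom_lengths[chrom]:
            continue
        start = int(rng.integers(0, (model.chrom_lengths[chrom] - size) // bs + 1)) * bs
        end = start + size
        gap = config.cnv_min_gap
        if any(l.chrom == chrom and l.start < end + gap and start < l.end + gap
               for l in active if l.kind == "cnv"):
            continue
        if config.cnv_avoid_masked and blocked_mask is not None:
            if blocked_mask[model.bins_in(chrom, start, end)].any():
                continue
        state = int(states[rng.choice(len(states), p=sp)])
        return _Lesion(kind="cnv", chrom=chrom, start=start, end=end, state=state)
    raise RuntimeError("could not place a non-overlapping CNV after 100 attempts")


def _draw_snp(rng, model, config, depth):
    arms = [c for c in model.chrom_names if c != "Y"]
    lengths = np.array([model.chrom_lengths[c] for c in arms], dtype=float)
    chrom = arms[rng.choice(len(arms), p=lengths / lengths.sum())]
    pos = int(rng.integers(1, model.chrom_lengths[chrom] + 1))  # 1-based
    classes = list(config.spectrum)
    cls = classes[rng.choice(len(classes), p=np.array([config.spectrum[c] for c in classes]))]
    ref, alt = _CLASS_TO_PAIRS[cls][int(rng.integers(2))]
    aaf = float(np.clip(rng.beta(2.0, 4.0), 0.05, 0.95))
    alt_reads = max(1, int(round(aaf * depth)))
    f1r2 = int(rng.binomial(alt_reads, 0.5))
    region_class = _annotate_position(model, chrom, pos)
    if region_class == "exonic":
        region_class = ("exonic-nonsyn"
                        if rng.random() < config.snp_exonic_nonsyn_prob
                        else "exonic-syn")
    return _Lesion(kind="snp", chrom=chrom, pos=pos, ref=ref, alt=alt, aaf=aaf,
                   f1r2=f1r2, f2r1=alt_reads - f1r2, region_class=region_class)


def _annotate_position(model, chrom, pos):
    p0 = pos - 1  # intervals are 0-based half-open
    def _hit(df):
        sub = df[df.chrom == chrom]
        return ((sub.start <= p0) & (p0 < sub.end)).any()

    if _hit(model.repeat_intervals):
        return "masked"
    if _hit(model.exome_intervals):
        return "exonic"  # refined to syn/nonsyn by the caller
    if _hit(model.gene_intervals):
        return "intron"
    return "intergenic"


def simulate_lineage(model: GenomeModel, config: SimConfig) -> LineageTruth:
    """Evolve one tumor line over the allograft schedule.

    Each schedule step brings Poisson-distributed new CNVs and SNPs (birth
    recorded as the step's timepoint) and retains each existing lesion
    independently with ``retention_prob``.  If ``split_at`` lies inside the
    last step, the line is split: sublines share every lesion born before the
    split point and diverge afterwards.
    """
    rng = np.random.default_rng([config.seed, 23])
    blocked = None
    if config.cnv_avoid_masked:
        blocked = model.interval_mask(model.ur_intervals) | model.interval_mask(
            model.repeat_intervals
        )
        blocked |= model.mappability == 0

    tps = list(config.timepoints)
    line = config.line_name
    donor = f"{line}-donor"
    samples = [SampleInfo(f"{line}-control", line, tps[0], "control", donor)]
    rows_cnv, rows_snp = [], []

    def _step(active, frac, tp):
        # survival then births for a (possibly fractional) passage step
        surv_p = config.retention_prob ** frac if frac < 1 else config.retention_prob
        kept = [l for l in active if rng.random() < surv_p]
        for _ in range(rng.poisson(config.cnv_rate_per_passage * frac)):
            new = _draw_cnv(rng, model, config, kept, blocked)
            new.birth = tp
            kept.append(new)
        for _ in range(rng.poisson(config.snp_rate_per_passage * frac)):
            new = _draw_snp(rng, model, config, config.depth)
            new.birth = tp
            kept.append(new)
        return kept

    def _record(active, sample_id):
        for l in active:
            if l.kind == "cnv":
                rows_cnv.append((sample_id, l.chrom, l.start, l.end, l.state, l.birth))
            else:
                rows_snp.append((sample_id, l.chrom, l.pos, l.ref, l.alt, l.aaf,
                                 l.f1r2, l.f2r1, l.region_class, l.birth))

    active = []
    split_frac = None
    if config.split_at is not None and len(tps) >= 2:
        lo, hi = tps[-2], tps[-1]
        if not (lo < config.split_at < hi):
            raise InvalidConfigError("split_at must fall inside the last schedule step")
        split_frac = (config.split_at - lo) / (hi - lo)

    for idx, tp in enumerate(tps):
        last = idx == len(tps) - 1
        if last and split_frac is not None:
            common = _step(active, split_frac, tp)
            for label in ("A", "B"):
                sub = _step(list(common), 1.0 - split_frac, tp)
                sid = f"{line}-T{tp}{label}"
                samples.append(SampleInfo(sid, line, tp, "tumor", donor, split=label))
                _record(sub, sid)
            break
        active = _step(active, 1.0, tp)
        sid = f"{line}-T{tp}"
        samples.append(SampleInfo(sid, line, tp, "tumor", donor))
        _record(active, sid)

    true_cnvs = pd.DataFrame(
        rows_cnv, columns=["sample_id", "chrom", "start", "end", "state", "birth"]
    )
    true_snps = pd.DataFrame(
        rows_snp,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "aaf", "f1r2", "f2r1",
                 "region_class", "birth"],
    )
    return LineageTruth(samples=samples, true_cnvs=true_cnvs, true_snps=true_snps)


# ---------------------------------------------------------------------------
# coverage


def gc_bias_log(gc: np.ndarray, config: SimConfig) -> np.ndarray:
    """Smooth log-scale GC bias: quadratic in (gc - gc_center)."""
    c0, c1, c2 = config.gc_bias_coeffs
    d = gc - config.gc_center
    return c0 + c1 * d + c2 * d * d


def copy_number_track(model: GenomeModel, cnvs: pd.DataFrame | None,
                      config: SimConfig) -> np.ndarray:
    """True per-bin copy number given sex and a sample's somatic CNVs."""
    copy = np.full(model.n_bins_total, 2.0)
    for chrom in model.chrom_names:
        if chrom == "X" and config.sex == "male":
            copy[model.arm_slice(chrom)] = 1.0
        elif chrom == "Y":
            copy[model.arm_slice(chrom)] = 1.0 if config.sex == "male" else 0.0
    if cnvs is not None:
        for row in cnvs.itertuples(index=False):
            idx = model.bins_in(row.chrom, int(row.start), int(row.end))
            copy[idx] = np.maximum(copy[idx] + row.state, 0.0)
    return copy


def simulate_coverage(model: GenomeModel, cnvs: pd.DataFrame | None,
                      config: SimConfig, is_control: bool = False,
                      stream: int = 0) -> np.ndarray:
    """Draw one sample's per-bin coverage under the negative-binomial model.

    ``cnvs`` must be None (or empty) for controls: the donor larva carries no
    somatic lesions, but its polytene gDNA under-replicates UR intervals by
    ``ur_factor``.  ``stream`` separates the random stream per sample.
    """
    if is_control and cnvs is not None and len(cnvs):
        raise InvalidConfigError("control samples carry no somatic lesions")
    rng = np.random.default_rng([config.seed, 37, stream])
    copy = copy_number_track(model, None if is_control else cnvs, config)
    mu = (
        config.depth
        * (copy / 2.0)
        * np.exp(gc_bias_log(model.gc, config))
        * model.mappability
    )
    if is_control and config.ur_factor < 1 and len(model.ur_intervals):
        mu[model.interval_mask(model.ur_intervals)] *= config.ur_factor
    # reads hitting the bin; per-bin mean depth = reads * read_length / binlen
    binlen = (model.bin_end - model.bin_start).astype(float)
    mu_reads = mu * binlen / config.read_length
    phi = config.overdispersion
    if phi <= 1.0:
        counts = rng.poisson(np.maximum(mu_reads, 0.0)).astype(float)
    else:
        size = np.maximum(mu_reads, 1e-12) / (phi - 1.0)
        p = size / (size + np.maximum(mu_reads, 1e-12))
        counts = rng.negative_binomial(size, p).astype(float)
    counts[mu_reads <= 0] = 0.0
    return counts * config.read_length / binlen


def simulate_cohort(config: SimConfig):
    """Convenience: genome + lineage + coverage for every sample.

    Returns ``(model, truth, coverages)`` where ``coverages`` maps sample_id
    to its flat per-bin coverage vector (control included).
    """
    model = simulate_genome(config)
    truth = simulate_lineage(model, config)
    coverages = {}
    for i, s in enumerate(truth.samples):
        cnvs = None if s.role == "control" else truth.cnvs_for(s.sample_id)[
            ["chrom", "start", "end", "state"]
        ]
        coverages[s.sample_id] = simulate_coverage(
            model, cnvs, config, is_control=s.role == "control", stream=i
        )
    return model, truth, coverages
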
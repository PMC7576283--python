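"""Synthetic cohort and molecular-data generator with known ground truth.

Emulates a cross-sectional cohort of healthy men aged 18-84 in six age
bins, together with every molecular layer the downstream analyses consume:

* clinical parameters with linear age trends and Gaussian noise,
* DNA fragmentation index (DFI) increasing with age,
* relative telomere length with opposite-sign blood and sperm slopes,
* per-donor sperm/blood methylomes with implanted age-linear DMRs on a
  bimodal, predominantly methylated background,
* targeted deep-bisulphite (DBS) measurements for a region panel,
* early-embryo methylation trajectories containing known reprogramming
  escapees and non-escapees.

Every generator is a pure function of (config, seed): the same inputs give
byte-identical outputs. Ground truth (implanted DMR locations and slopes,
escapee flags) is returned alongside the data so recovery can be scored.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    DonorRecord,
    GenomicInterval,
    MethylomeTrack,
    SiteArray,
)

__all__ = [
    "SimConfig",
    "DmrTruth",
    "DbsMeasurement",
    "EmbryoTrajectory",
    "GenomeLandscape",
    "generate_cohort",
    "make_landscape",
    "generate_methylomes",
    "pool_methylomes",
    "select_pool_donors",
    "select_dbs_cohorts",
    "default_dbs_panel",
    "generate_dbs_measurements",
    "generate_embryo_trajectories",
]

# Stream tags keep the per-purpose RNGs independent of one another.
_S_COHORT, _S_LANDSCAPE, _S_METH, _S_DBS, _S_EMBRYO = range(5)

# Age sampling ranges per group (years); the last group is truncated at the
# oldest study age, 84.
_GROUP_AGE_RANGES = ((18, 26), (26, 36), (36, 46), (46, 56), (56, 66), (66, 84))

# Clinical parameter trends: name -> (intercept at age 0, slope per year,
# noise SD). Intercepts/slopes chosen so group means run from young values of
# roughly 42 cm3 testicular volume, 4.2 ml ejaculate, 3 U/l FSH, 38 nmol/l
# SHBG, 494 pmol/l free testosterone down/up to their old-age counterparts.
_DEFAULT_CLINICAL_TRENDS: dict[str, tuple[float, float, float]] = {
    "testicular_volume_cm3": (42.8, -0.03, 13.0),
    "ejaculate_volume_ml": (5.15, -0.044, 1.6),
    "sperm_concentration_mio_per_ml": (29.8, 0.45, 20.0),
    "progressive_motility_percent": (63.6, -0.39, 16.0),
    "vitality_percent": (76.6, -0.25, 13.0),
    "fsh_u_per_l": (1.7, 0.06, 2.5),
    "shbg_nmol_per_l": (29.4, 0.41, 14.0),
    "free_testosterone_pmol_per_l": (556.0, -2.9, 110.0),
}

DEFAULT_EMBRYO_STAGES = (
    "sperm",
    "zygote_early_PN",
    "zygote_mid_PN",
    "zygote_late_PN",
)


@dataclass(frozen=True)
class DmrTruth:
    """Ground-truth age trend of one implanted DMR.

    Methylation at age a is clamp(baseline + slope * (a - 18), 0, 1); the
    baseline is the level at the youngest study age.
    """

    interval: GenomicInterval
    slope: float  # delta beta per year
    baseline: float  # beta at age 18
    region_id: str = ""

    @property
    def direction(self) -> str:
        return "hyper" if self.slope > 0 else "hypo"

    def beta_at(self, age) -> np.ndarray:
        return np.clip(self.baseline + self.slope * (np.asarray(age) - 18.0), 0.0, 1.0)


@dataclass(frozen=True)
class DbsMeasurement:
    """Donor-wise mean methylation of one panel region from deep sequencing."""

    region_id: str
    donor_id: str
    mean_meth: float
    reads: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_meth <= 1.0:
            raise ValueError(f"mean_meth {self.mean_meth} outside [0, 1]")
        if self.reads < 1:
            raise ValueError("reads must be >= 1")


@dataclass(frozen=True)
class EmbryoTrajectory:
    """Stage-ordered methylation of one region through early development."""

    region_id: str
    stages: tuple[str, ...]
    meth: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.stages) != len(self.meth):
            raise ValueError("stages and meth must have equal length")
        # NaN marks a missing stage value; classification rejects it later
        if any(not np.isnan(b) and not 0.0 <= b <= 1.0 for b in self.meth):
            raise ValueError("methylation values outside [0, 1]")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study-design defaults.

    Group sizes default to 34/36/28/39/36/24 (197 donors). Telomere slopes
    default to -0.0055 (blood) and +0.0077 (sperm) relative-length units per
    year. DMR truths default to 20 regions per tissue with slopes of
    +/-0.008 per year, i.e. ~0.4 methylation difference between the pooled
    young and old groups.
    """

    seed: int = 0
    group_sizes: tuple[int, ...] = (34, 36, 28, 39, 36, 24)

    # genome / WGBS layer
    n_chromosomes: int = 2
    cpgs_per_chromosome: int = 50_000
    mean_cpg_spacing: int = 100  # bp; sets chromosome length
    mean_coverage: float = 30.0
    background_mixture: tuple[tuple[float, tuple[float, float]], ...] = (
        (0.80, (9.0, 1.0)),  # high-methylation bulk of the sperm genome
        (0.15, (1.0, 19.0)),  # unmethylated islands
        (0.05, (2.0, 2.0)),  # intermediate
    )
    n_dmrs_sperm: int = 20
    n_dmrs_blood: int = 20
    dmr_n_cpgs: int = 8
    dmr_slope: float = 0.008  # per year; sign alternates hyper/hypo
    dmr_baseline_hyper: float = 0.15
    dmr_baseline_hypo: float = 0.85
    dmr_cpg_spacing: tuple[int, int] = (20, 80)  # truth regions are CpG-dense
    dmr_truth: Optional[Mapping[str, Sequence[DmrTruth]]] = None  # override

    # clinical layer
    clinical_trends: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CLINICAL_TRENDS)
    )
    clinical_noise_scale: float = 1.0  # multiplies every per-parameter SD

    # DFI layer (percent units)
    dfi_intercept: float = 3.2
    dfi_slope: float = 0.38
    dfi_noise_sd: float = 10.0

    # telomere layer (relative T/S ratio units)
    telomere_slope_blood: float = -0.0055
    telomere_slope_sperm: float = 0.0077
    telomere_intercept_blood: float = 1.275
    telomere_intercept_sperm: float = 0.615
    telomere_noise_sd: float = 0.08
    rtl_missing_blood: int = 3  # yields n = 194 of 197
    rtl_missing_sperm: int = 18  # yields n = 179 of 197

    # DBS layer
    dbs_depth: int = 1000
    dbs_beta_noise_sd: float = 0.03  # donor-level biological scatter on beta

    # embryo layer
    embryo_stages: tuple[str, ...] = DEFAULT_EMBRYO_STAGES
    boundary_fraction: float = 0.1  # trajectories placed exactly on thresholds

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        if any(n <= 0 for n in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if len(self.group_sizes) > len(_GROUP_AGE_RANGES):
            raise ValueError("at most six age groups are supported")

    @property
    def chrom_length(self) -> int:
        return self.cpgs_per_chromosome * self.mean_cpg_spacing


def _rng(config_seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, *tags]))


def _donor_tag(donor_id: str) -> int:
    return zlib.crc32(donor_id.encode())


def generate_cohort(config: SimConfig) -> list[DonorRecord]:
    """Draw the synthetic cohort: ages, clinical values, DFI and rTL.

    Ages are uniform within each group's bin. Every continuous readout is
    intercept + slope * age + Gaussian noise; clinical values are clipped at
    zero, DFI at [0, 100]. A few donors lack telomere measurements, mirroring
    incomplete sampling.
    """
    rng = _rng(config.seed, _S_COHORT)
    ages = []
    for size, (lo, hi) in zip(config.group_sizes, _GROUP_AGE_RANGES):
        ages.append(rng.uniform(lo, hi, size=size))
    ages = np.concatenate(ages)
    n = ages.size

    clinical = {}
    for name, (b0, b1, sd) in config.clinical_trends.items():
        noise = rng.normal(0.0, sd * config.clinical_noise_scale, size=n)
        clinical[name] = np.maximum(b0 + b1 * ages + noise, 0.0)

    dfi = config.dfi_intercept + config.dfi_slope * ages
    if config.dfi_noise_sd > 0:
        dfi = dfi + rng.normal(0.0, config.dfi_noise_sd, size=n)
    dfi = np.clip(dfi, 0.0, 100.0)

    rtl_b = config.telomere_intercept_blood + config.telomere_slope_blood * ages
    rtl_s = config.telomere_intercept_sperm + config.telomere_slope_sperm * ages
    if config.telomere_noise_sd > 0:
        rtl_b = rtl_b + rng.normal(0.0, config.telomere_noise_sd, size=n)
        rtl_s = rtl_s + rng.normal(0.0, config.telomere_noise_sd, size=n)
    miss_b = set(rng.choice(n, size=min(config.rtl_missing_blood, n), replace=False))
    miss_s = set(rng.choice(n, size=min(config.rtl_missing_sperm, n), replace=False))

    donors = []
    for i in range(n):
        donors.append(
            DonorRecord(
                donor_id=f"D{i + 1:03d}",
                age=float(ages[i]),
                clinical={k: float(v[i]) for k, v in clinical.items()},
                dfi_percent=float(dfi[i]),
                rtl_blood=None if i in miss_b else float(rtl_b[i]),
                rtl_sperm=None if i in miss_s else float(rtl_s[i]),
            )
        )
    return donors


@dataclass
class GenomeLandscape:
    """Fixed per-genome state shared by all donors of a simulation.

    CpG positions and background methylation are properties of the genome,
    not of a donor; implanted DMR truths are tissue-specific and the sperm
    and blood truth sets are disjoint by construction.
    """

    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray]
    background_beta: dict[str, np.ndarray]
    truths: dict[str, list[DmrTruth]]


def make_landscape(config: SimConfig) -> GenomeLandscape:
    """Build the CpG landscape and implant the tissue-specific DMR truths.

    Truth regions sit on locally dense CpG clusters (20-80 bp spacing),
    emulating the CpG-rich regulatory elements real DMRs fall in; the
    background has ~``mean_cpg_spacing`` bp between CpGs. Sperm and blood
    anchors interleave along each chromosome so the two truth sets can never
    overlap, and within each tissue the direction alternates hyper/hypo.
    """
    rng = _rng(config.seed, _S_LANDSCAPE)
    L = config.chrom_length
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    if config.dmr_truth is not None:
        truths = {t: list(v) for t, v in config.dmr_truth.items()}
        _check_disjoint_truths(truths)
    else:
        truths = {"sperm": [], "blood": []}

    positions: dict[str, np.ndarray] = {}
    background: dict[str, np.ndarray] = {}
    counters = {"sperm": 0, "blood": 0}
    for ci, chrom in enumerate(chrom_names):
        truth_pos: list[np.ndarray] = []
        if config.dmr_truth is None:
            per = {
                "sperm": _split_count(config.n_dmrs_sperm, config.n_chromosomes, ci),
                "blood": _split_count(config.n_dmrs_blood, config.n_chromosomes, ci),
            }
            slots = ["sperm"] * per["sperm"] + ["blood"] * per["blood"]
            # interleave tissues so sperm and blood regions alternate
            slots = [t for pair in zip(*_balanced_halves(slots)) for t in pair if t]
            n_slots = len(slots)
            lo_s, hi_s = config.dmr_cpg_spacing
            for j, tissue in enumerate(slots):
                anchor = int(L * (j + 0.5) / n_slots)
                gaps = rng.integers(lo_s, hi_s + 1, size=config.dmr_n_cpgs - 1)
                pos = anchor + np.concatenate([[0], np.cumsum(gaps)])
                k = counters[tissue]
                hyper = k % 2 == 0  # alternate direction within each tissue
                truths[tissue].append(
                    DmrTruth(
                        interval=GenomicInterval(chrom, int(pos[0]), int(pos[-1]) + 1),
                        slope=config.dmr_slope if hyper else -config.dmr_slope,
                        baseline=(
                            config.dmr_baseline_hyper
                            if hyper
                            else config.dmr_baseline_hypo
                        ),
                        region_id=f"{tissue}_truth_{k + 1:02d}",
                    )
                )
                counters[tissue] += 1
                truth_pos.append(pos)
        else:
            for tissue in truths:
                for t in truths[tissue]:
                    if t.interval.chrom == chrom:
                        lo_s, hi_s = config.dmr_cpg_spacing
                        width = len(t.interval)
                        k = max(config.dmr_n_cpgs, 2)
                        pos = t.interval.start + np.unique(
                            np.linspace(0, width - 1, k).astype(np.int64)
                        )
                        truth_pos.append(pos)
        tp = (
            np.unique(np.concatenate(truth_pos))
            if truth_pos
            else np.empty(0, dtype=np.int64)
        )
        n_bg = max(config.cpgs_per_chromosome - tp.size, 0)
        bg = rng.choice(L, size=n_bg, replace=False).astype(np.int64)
        pos = np.unique(np.concatenate([tp, bg]))
        positions[chrom] = pos
        background[chrom] = _draw_background_beta(rng, pos.size, config)

    _check_disjoint_truths(truths)
    return GenomeLandscape(
        chrom_lengths={c: L for c in chrom_names},
        positions=positions,
        background_beta=background,
        truths=truths,
    )


def _split_count(total: int, parts: int, index: int) -> int:
    base, rem = divmod(total, parts)
    return base + (1 if index < rem else 0)


def _balanced_halves(slots: list[str]) -> tuple[list[str], list[str]]:
    a = [s for s in slots if s == "sperm"]
    b = [s for s in slots if s == "blood"]
    width = max(len(a), len(b))
    a += [""] * (width - len(a))
    b += [""] * (width - len(b))
    return a, b


def _draw_background_beta(
    rng: np.random.Generator, n: int, config: SimConfig
) -> np.ndarray:
    weights = np.array([w for w, _ in config.background_mixture])
    weights = weights / weights.sum()
    comp = rng.choice(len(weights), size=n, p=weights)
    beta = np.empty(n)
    for k, (_, (a, b)) in enumerate(config.background_mixture):
        mask = comp == k
        beta[mask] = rng.beta(a, b, size=int(mask.sum()))
    return beta


def _check_disjoint_truths(truths: Mapping[str, Sequence[DmrTruth]]) -> None:
    ivs = [t.interval for ts in truths.values() for t in ts]
    ivs.sort()
    for a, b in zip(ivs, ivs[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping truth intervals: {a} and {b}")


def generate_methylomes(
    donors: Sequence[DonorRecord],
    config: SimConfig,
    tissue: str = "sperm",
    landscape: Optional[GenomeLandscape] = None,
) -> list[MethylomeTrack]:
    """Simulate per-donor WGBS tracks for one tissue.

    Expected methylation is the landscape background everywhere except
    inside the tissue's truth regions, where it is the truth's age line.
    Per-site coverage is Poisson(mean_coverage) with zeros raised to 1, and
    methylated counts are Binomial(coverage, beta). Each donor's track
    depends only on (config, tissue, donor_id), so subsetting the cohort
    does not change anyone's methylome.
    """
    if landscape is None:
        landscape = make_landscape(config)
    truths = landscape.truths.get(tissue, [])
    _check_disjoint_truths({tissue: truths})
    tissue_tag = 0 if tissue == "sperm" else 1
    tracks = []
    for donor in donors:
        rng = _rng(config.seed, _S_METH, tissue_tag, _donor_tag(donor.donor_id))
        chroms = {}
        for chrom, pos in landscape.positions.items():
            beta = landscape.background_beta[chrom].copy()
            for t in truths:
                if t.interval.chrom != chrom:
                    continue
                lo = np.searchsorted(pos, t.interval.start, side="left")
                hi = np.searchsorted(pos, t.interval.end, side="left")
                beta[lo:hi] = t.beta_at(donor.age)
            total = rng.poisson(config.mean_coverage, size=pos.size)
            total[total < 1] = 1
            meth = rng.binomial(total, beta)
            chroms[chrom] = SiteArray(pos, meth, total, validate=False)
        tracks.append(
            MethylomeTrack(
                sample_id=donor.donor_id,
                tissue=tissue,
                group_label=f"group{donor.age_group}",
                chroms=chroms,
            )
        )
    return tracks


def pool_methylomes(
    tracks: Sequence[MethylomeTrack],
    sample_id: str = "pool",
    group_label: str = "",
) -> MethylomeTrack:
    """Pool tracks by summing read counts per site.

    The pooled beta is therefore the coverage-weighted mean of the input
    betas. All tracks must share tissue and CpG position sets.
    """
    if not tracks:
        raise ValueError("cannot pool zero tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if t.tissue != first.tissue:
            raise ValueError("cannot pool tracks of different tissues")
        if not first.same_positions(t):
            raise ValueError("cannot pool tracks with mismatched CpG positions")
    chroms = {}
    for chrom in first.chrom_names():
        pos = first.chroms[chrom].pos
        meth = sum(t.chroms[chrom].meth for t in tracks)
        total = sum(t.chroms[chrom].total for t in tracks)
        chroms[chrom] = SiteArray(pos, meth, total, validate=False)
    return MethylomeTrack(sample_id, first.tissue, group_label, chroms)


def select_pool_donors(
    donors: Sequence[DonorRecord], n_per_pool: int = 6
) -> tuple[list[DonorRecord], list[DonorRecord]]:
    """The WGBS pool design: the n youngest and the n oldest donors."""
    by_age = sorted(donors, key=lambda d: (d.age, d.donor_id))
    if len(by_age) < 2 * n_per_pool:
        raise ValueError("cohort smaller than the two requested pools")
    return by_age[:n_per_pool], by_age[-n_per_pool:]


def select_dbs_cohorts(
    donors: Sequence[DonorRecord],
    seed: Optional[int] = None,
    config: Optional[SimConfig] = None,
    n_pool: int = 6,
    n_extra: int = 30,
    n_validation: int = 33,
) -> tuple[list[DonorRecord], list[DonorRecord]]:
    """Pick the DBS training and validation cohorts from the full study.

    Training mirrors the study design: the 2 * ``n_pool`` donors that formed
    the WGBS pools plus ``n_extra`` donors drawn at random from the rest, so
    the cohort spans all age groups. The validation cohort is a further
    ``n_validation`` random donors disjoint from training.
    """
    cfg = config or SimConfig()
    seed = cfg.seed if seed is None else seed
    young, old = select_pool_donors(donors, n_pool)
    pool_ids = {d.donor_id for d in young + old}
    rest = [d for d in donors if d.donor_id not in pool_ids]
    if len(rest) < n_extra + n_validation:
        raise ValueError("cohort too small for the requested DBS design")
    rng = _rng(seed, _S_DBS, 1)
    picks = rng.choice(len(rest), size=n_extra + n_validation, replace=False)
    train = young + old + [rest[i] for i in picks[:n_extra]]
    validation = [rest[i] for i in picks[n_extra:]]
    return train, validation


def default_dbs_panel(config: SimConfig) -> dict[str, DmrTruth]:
    """The 11-region DBS validation panel with its generating trends.

    Six regions carry a strong age trend (+/-0.006 per year, alternating
    direction) and five carry an essentially flat trend (+/-0.0002 per
    year), so that with realistic donor-level noise only the six strong
    regions reach p < 0.001 against age in a 42-donor cohort.
    """
    panel: dict[str, DmrTruth] = {}
    for k in range(11):
        region_id = f"DMR{k + 1:02d}"
        strong = k < 6
        hyper = k % 2 == 0
        slope = (0.006 if strong else 0.0002) * (1 if hyper else -1)
        baseline = (0.15 if hyper else 0.85) if strong else 0.5
        panel[region_id] = DmrTruth(
            interval=GenomicInterval("panel", 10_000 * k, 10_000 * k + 500),
            slope=slope,
            baseline=baseline,
            region_id=region_id,
        )
    return panel


def generate_dbs_measurements(
    donors: Sequence[DonorRecord],
    panel: Mapping[str, DmrTruth],
    depth: Optional[int] = None,
    seed: Optional[int] = None,
    beta_noise_sd: Optional[float] = None,
    config: Optional[SimConfig] = None,
    region_ids: Optional[Sequence[str]] = None,
) -> list[DbsMeasurement]:
    """Simulate deep-bisulphite measurements for each donor and panel region.

    The donor-wise mean methylation is Binomial(depth, beta)/depth where
    beta is the region's age line plus donor-level Gaussian scatter
    (``beta_noise_sd``), clipped to [0, 1]. Defaults come from ``config``
    (or SimConfig defaults): depth 1000, scatter SD 0.03.
    """
    cfg = config or SimConfig()
    depth = cfg.dbs_depth if depth is None else depth
    seed = cfg.seed if seed is None else seed
    noise_sd = cfg.dbs_beta_noise_sd if beta_noise_sd is None else beta_noise_sd
    if depth < 1:
        raise ValueError("depth must be >= 1")
    ids = list(panel) if region_ids is None else list(region_ids)
    unknown = [r for r in ids if r not in panel]
    if unknown:
        raise KeyError(f"unknown region ids: {unknown}")
    rng = _rng(seed, _S_DBS)
    out = []
    for donor in donors:
        for region_id in ids:
            beta = float(panel[region_id].beta_at(donor.age))
            if noise_sd > 0:
                beta = float(np.clip(beta + rng.normal(0.0, noise_sd), 0.0, 1.0))
            k = int(rng.binomial(depth, beta))
            out.append(
                DbsMeasurement(
                    region_id=region_id,
                    donor_id=donor.donor_id,
                    mean_meth=k / depth,
                    reads=depth,
                )
            )
    return out


def generate_embryo_trajectories(
    region_ids: Sequence[str],
    escapee_flags: Mapping[str, bool],
    config: Optional[SimConfig] = None,
    seed: Optional[int] = None,
) -> list[EmbryoTrajectory]:
    """Simulate stage-wise embryo methylation with known escapee status.

    Flagged regions keep methylation >= 0.30 at every stage with a
    stage-to-stage range < 0.30; unflagged regions either demethylate below
    0.10 by the late-pronucleus stage or sit exactly on the range threshold.
    A configurable fraction of trajectories lands exactly on the 0.30
    boundaries so threshold conventions are exercised.
    """
    cfg = config or SimConfig()
    seed = cfg.seed if seed is None else seed
    stages = tuple(cfg.embryo_stages)
    if len(stages) < 2 or stages[-1] != "zygote_late_PN":
        raise ValueError("stage list must have >= 2 stages ending at zygote_late_PN")
    if not region_ids:
        raise ValueError("no regions supplied")
    missing = [r for r in region_ids if r not in escapee_flags]
    if missing:
        raise KeyError(f"regions without escapee flag: {missing}")
    rng = _rng(seed, _S_EMBRYO)
    n = len(stages)
    out = []
    for region_id in region_ids:
        flag = bool(escapee_flags[region_id])
        boundary = rng.random() < cfg.boundary_fraction
        if flag:
            if boundary:
                # minimum exactly at the persistence threshold
                start = rng.uniform(0.45, 0.58)
                values = np.linspace(start, 0.30, n)
            else:
                start = rng.uniform(0.55, 0.90)
                drop = rng.uniform(0.05, min(0.25, start - 0.35))
                frac = np.concatenate([[0.0], np.sort(rng.uniform(0, 1, n - 2)), [1.0]])
                values = start - drop * frac
        else:
            if boundary:
                # persistent but with range exactly at the variation threshold
                low = rng.uniform(0.35, 0.50)
                high = low + 0.30
                while high - low < 0.30:  # guard against float rounding
                    high = np.nextafter(high, 1.0)
                values = np.linspace(high, low, n)
            else:
                start = rng.uniform(0.60, 0.95)
                final = rng.uniform(0.02, 0.08)
                frac = np.concatenate([[0.0], np.sort(rng.uniform(0, 1, n - 2)), [1.0]])
                values = start - (start - final) * frac
        is_escapee = bool(
            values.min() >= 0.30 and (values.max() - values.min()) < 0.30
        )
        assert is_escapee == flag, "generator produced a trajectory off its flag"
        out.append(
            EmbryoTrajectory(
                region_id=region_id,
                stages=stages,
                meth=tuple(float(v) for v in values),
            )
        )
    return out
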
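"""Synthetic inputs with the statistical structure the analyses assume.

Four generators emulate the data-producing experiments end to end:

* Poisson beam-break counts with entrained or free-running periodic
  structure under LD/DD schedules (TriKinetics-style monitors),
* sinusoidal transcript oscillations sampled every 2 h with biological and
  technical qPCR replication against a flat reference gene,
* spliced/unspliced isoform pairs with a set splicing efficiency,
* random-background promoter sequences with planted IUPAC motifs.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .locomotor import ActivityDataset
from .schedules import LightSchedule

_DEFAULT_START = datetime(2016, 6, 1, 8, 0, 0)


# ---------------------------------------------------------------------------
# Locomotor activity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityPeak:
    """One circular-Gaussian activity bout anchored to lights-on."""

    center_zt: float
    width_sd: float
    height: float


@dataclass
class ActivitySimConfig:
    """Parameters of the beam-break count generator.

    Counts per bin are Poisson with rate ``baseline`` plus circular-Gaussian
    peaks recurring with period ``period_tau`` (hours); under an LD regime
    the rate is multiplied by ``dark_attenuation`` during the scotophase.
    ``arrhythmic_fraction`` of the flies get a within-fly permutation of
    their bin rates, destroying rhythm while preserving total activity.
    ``overdispersion`` switches the Poisson law to a negative binomial via
    gamma mixing (None = pure Poisson).
    """

    n_flies: int
    n_days: int
    schedule: LightSchedule
    bin_minutes: float = 5.0
    period_tau: float = 24.0
    peaks: Sequence[ActivityPeak] = field(default_factory=list)
    baseline: float = 2.0
    dark_attenuation: float = 0.3
    arrhythmic_fraction: float = 0.0
    temperature_label: float = 25.0
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError(f"n_flies must be >= 1, got {self.n_flies}")
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if self.baseline < 0:
            raise ValueError(f"baseline must be >= 0, got {self.baseline}")
        for pk in self.peaks:
            if pk.height < 0:
                raise ValueError(f"peak height must be >= 0, got {pk.height}")
            if pk.width_sd <= 0:
                raise ValueError(f"peak width_sd must be > 0, got {pk.width_sd}")
        bpd = 1440.0 / self.bin_minutes
        if abs(bpd - round(bpd)) > 1e-9:
            raise ValueError(
                f"bin_minutes={self.bin_minutes} does not divide the 1440-min day"
            )
        if not 0.0 <= self.dark_attenuation <= 1.0:
            raise ValueError(
                f"dark_attenuation must be in [0, 1], got {self.dark_attenuation}"
            )
        if not 0.0 <= self.arrhythmic_fraction <= 1.0:
            raise ValueError(
                f"arrhythmic_fraction must be in [0, 1], got {self.arrhythmic_fraction}"
            )
        if self.period_tau <= 0:
            raise ValueError(f"period_tau must be > 0, got {self.period_tau}")


def activity_rate(config: ActivitySimConfig) -> np.ndarray:
    """Expected counts/bin along the full recording, from the model itself.

    Peaks recur every ``period_tau`` hours starting from lights-on at time
    zero, so under DD a tau different from 24 h drifts across projected ZT
    exactly as a free-running fly would.
    """
    n_bins = int(round(config.n_days * 1440.0 / config.bin_minutes))
    t = (np.arange(n_bins) + 0.5) * config.bin_minutes / 60.0
    rate = np.full(n_bins, float(config.baseline))
    tau = config.period_tau
    for pk in config.peaks:
        # wrapped distance to the nearest peak occurrence on the tau-cycle
        d = (t - pk.center_zt + tau / 2.0) % tau - tau / 2.0
        rate += pk.height * np.exp(-0.5 * (d / pk.width_sd) ** 2)
    if config.schedule.regime_label == "LD":
        dark = (t % 24.0) >= config.schedule.hours_light
        rate[dark] *= config.dark_attenuation
    return rate


def simulate_activity(config: ActivitySimConfig) -> ActivityDataset:
    """Draw a beam-break dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    rate = activity_rate(config)
    n_bins = rate.size
    counts = np.empty((config.n_flies, n_bins), dtype=np.int64)
    n_arrhythmic = int(round(config.arrhythmic_fraction * config.n_flies))
    arrhythmic = np.zeros(config.n_flies, dtype=bool)
    if n_arrhythmic:
        arrhythmic[rng.choice(config.n_flies, size=n_arrhythmic, replace=False)] = True
    for f in range(config.n_flies):
        lam = rng.permutation(rate) if arrhythmic[f] else rate
        if config.overdispersion is not None:
            shape = 1.0 / config.overdispersion
            lam = lam * rng.gamma(shape, scale=config.overdispersion, size=n_bins)
        counts[f] = rng.poisson(lam)
    return ActivityDataset(
        fly_ids=[f"sim{f + 1:03d}" for f in range(config.n_flies)],
        counts=counts,
        bin_minutes=config.bin_minutes,
        start=_DEFAULT_START,
        schedule_segments=[(1, config.schedule)],
        temperature_label=config.temperature_label,
    )


# ---------------------------------------------------------------------------
# qPCR time courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth expression program of one simulated transcript.

    ``mesor`` is the cycle mean in relative units, ``amplitude`` the
    relative oscillation amplitude (fraction of mesor, < 1 so expression
    stays positive), ``peak_zt`` the acrophase in hours.
    """

    name: str
    mesor: float = 1.0
    amplitude: float = 0.5
    peak_zt: float = 14.0
    cycling: bool = True


@dataclass
class QpcrSimConfig:
    """Parameters of the Cq-table generator.

    For a cycling gene the true relative abundance is
    ``rel(t) = mesor * (1 + amplitude * cos(2*pi*(t - peak_zt)/24))``.
    Cq values are ``ref_gene_cq - log_eff(rel)`` plus additive Gaussian
    noise in cycle units: one biological term shared by the technical
    triplicate of a sample and one independent technical term per well.
    The flat reference gene is included in the output.
    """

    genes: Sequence[GeneSpec]
    condition_label: str = "25"
    sampling_interval: float = 2.0
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    ref_gene: str = "rp49"
    ref_gene_cq: float = 18.0
    tech_sd: float = 0.15
    bio_sd: float = 0.25
    efficiency: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.genes:
            if not 0.0 <= g.amplitude < 1.0:
                raise ValueError(
                    f"gene {g.name}: amplitude must be in [0, 1), got {g.amplitude}"
                )
            if g.mesor <= 0:
                raise ValueError(f"gene {g.name}: mesor must be > 0")
        if self.sampling_interval <= 0 or 24.0 % self.sampling_interval > 1e-9:
            raise ValueError(
                f"sampling_interval must divide 24 h, got {self.sampling_interval}"
            )
        if self.efficiency <= 1.0:
            raise ValueError(f"efficiency must be > 1, got {self.efficiency}")
        if self.tech_sd < 0 or self.bio_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def true_relative_expression(gene: GeneSpec, zt: np.ndarray) -> np.ndarray:
    """The generator's own rel(t); the oracle for round-trip tests."""
    if not gene.cycling:
        return np.full_like(np.asarray(zt, dtype=float), gene.mesor)
    return gene.mesor * (
        1.0 + gene.amplitude * np.cos(2.0 * np.pi * (np.asarray(zt, dtype=float) - gene.peak_zt) / 24.0)
    )


def simulate_qpcr(config: QpcrSimConfig) -> pd.DataFrame:
    """Simulate a long-format Cq table.

    Columns: ``gene, condition, zt, bio_rep, tech_rep, cq``.  The reference
    gene is emitted for every (zt, bio_rep) so downstream delta-Cq
    normalization always finds its rows.
    """
    rng = np.random.default_rng(config.seed)
    zts = np.arange(0.0, 24.0, config.sampling_interval)
    log_eff = math.log(config.efficiency)
    all_genes = list(config.genes) + [GeneSpec(config.ref_gene, 1.0, 0.0, 0.0, False)]
    records = []
    for gene in all_genes:
        rel = true_relative_expression(gene, zts)
        for it, zt in enumerate(zts):
            for b in range(config.n_bio_reps):
                bio = rng.normal(0.0, config.bio_sd) if config.bio_sd > 0 else 0.0
                base_cq = config.ref_gene_cq - math.log(rel[it]) / log_eff + bio
                for tch in range(config.n_tech_reps):
                    tech = rng.normal(0.0, config.tech_sd) if config.tech_sd > 0 else 0.0
                    records.append(
                        (gene.name, config.condition_label, float(zt), b + 1,
                         tch + 1, base_cq + tech)
                    )
    return pd.DataFrame.from_records(
        records, columns=["gene", "condition", "zt", "bio_rep", "tech_rep", "cq"]
    )


# ---------------------------------------------------------------------------
# Splice assays
# ---------------------------------------------------------------------------

def simulate_splice_assay(efficiency_by_condition: dict[str, float],
                          noise_sd: float = 0.05,
                          n_reps: int = 3,
                          seed: int = 0) -> pd.DataFrame:
    """Simulate spliced/unspliced isoform level pairs per condition.

    Each replicate draws independent multiplicative log-normal noise on the
    two isoform levels, so ``spliced / (spliced + unspliced)`` is centered
    on the requested splicing efficiency.  Efficiencies must be strictly
    inside (0, 1): a value of exactly 0 or 1 means one isoform is absent
    and the ratio degenerates.

    Columns: ``condition, replicate, spliced_level, unspliced_level``.
    """
    for cond, eff in efficiency_by_condition.items():
        if not 0.0 < eff < 1.0:
            raise ValueError(
                f"condition {cond!r}: efficiency must be strictly in (0, 1), got {eff}"
            )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for cond, eff in efficiency_by_condition.items():
        for r in range(n_reps):
            noise_s = math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            noise_u = math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            records.append((str(cond), r + 1, eff * noise_s, (1.0 - eff) * noise_u))
    return pd.DataFrame.from_records(
        records, columns=["condition", "replicate", "spliced_level", "unspliced_level"]
    )


# ---------------------------------------------------------------------------
# Promoter sequences
# ---------------------------------------------------------------------------

_IUPAC_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MotifPlant:
    """A motif to embed: explicit positions, or a count placed uniformly."""

    motif_iupac: str
    positions: Sequence[int] | None = None
    count: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if (self.positions is None) == (self.count is None):
            raise ValueError("give exactly one of positions or count")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for ch in self.motif_iupac.upper():
            if ch not in _IUPAC_BASES:
                raise ValueError(f"illegal IUPAC character {ch!r} in plant motif")


@dataclass
class PromoterSimConfig:
    length_bp: int
    gc_fraction: float = 0.5
    plants: Sequence[MotifPlant] = field(default_factory=list)
    name: str = "synthetic_promoter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"length_bp must be >= 1, got {self.length_bp}")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction must be in [0, 1], got {self.gc_fraction}")


def _concretize(motif: str, rng: np.random.Generator) -> str:
    """Pick one concrete word matching a (possibly degenerate) IUPAC motif."""
    return "".join(
        ch if len(_IUPAC_BASES[ch]) == 1 else _IUPAC_BASES[ch][rng.integers(len(_IUPAC_BASES[ch]))]
        for ch in motif.upper()
    )


def simulate_promoter(config: PromoterSimConfig) -> tuple[str, list[tuple[str, int, str]]]:
    """Random i.i.d. background sequence with planted motif instances.

    Returns ``(sequence, plant_map)`` where the plant map lists
    ``(motif_iupac, 0-based offset, strand)`` ground-truth instances; a
    minus-strand plant substitutes the reverse complement at the offset.
    Overlapping plants are rejected.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(list("ACGT"), size=config.length_bp, p=probs))

    occupied: list[tuple[int, int]] = []
    plant_map: list[tuple[str, int, str]] = []

    def overlaps(a: int, b: int) -> bool:
        return any(a < e and s < b for s, e in occupied)

    def place(plant: MotifPlant, pos: int) -> None:
        k = len(plant.motif_iupac)
        if pos < 0 or pos + k > config.length_bp:
            raise ValueError(f"plant {plant.motif_iupac!r} at {pos} outside sequence")
        if overlaps(pos, pos + k):
            raise ValueError(
                f"plant {plant.motif_iupac!r} at {pos} overlaps another plant"
            )
        word = _concretize(plant.motif_iupac, rng)
        if plant.strand == "-":
            word = word.translate(_COMPLEMENT)[::-1]
        seq[pos:pos + k] = list(word)
        occupied.append((pos, pos + k))
        plant_map.append((plant.motif_iupac.upper(), pos, plant.strand))

    for plant in config.plants:
        k = len(plant.motif_iupac)
        if k > config.length_bp:
            raise ValueError(
                f"plant {plant.motif_iupac!r} does not fit in {config.length_bp} bp"
            )
        if plant.positions is not None:
            for pos in plant.positions:
                place(plant, pos)
        else:
            free = config.length_bp - k + 1
            for _ in range(plant.count):  # uniform placement by rejection
                for _attempt in range(1000):
                    pos = int(rng.integers(free))
                    if not overlaps(pos, pos + k):
                        break
                else:
                    raise ValueError(
                        f"cannot place {plant.count} non-overlapping copies of "
                        f"{plant.motif_iupac!r} in {config.length_bp} bp"
                    )
                place(plant, pos)

    return "".join(seq), sorted(plant_map, key=lambda t: t[1])
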
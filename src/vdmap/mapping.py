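"""Per-chromosome kernel-density homozygosity mapping.

The mapping statistic: on each chromosome, estimate the density of
homozygous-alt SNP positions and of heterozygous SNP positions with a
Gaussian kernel, then combine them into the count-scaled score

    score(x) = n_hom * f_hom(x) - n_het * f_het(x)

whose peak marks the region where the pooled mutants are homozygous for the
mutagenized-strain haplotype while the strain polymorphisms that segregate
elsewhere are depleted.  The candidate interval is the contiguous run around
the peak where the score stays above a fraction of its maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .variants import GenomicInterval, VdmapError
from .zygosity import PartitionResult, ZygosityCall

SQRT_2PI = math.sqrt(2.0 * math.pi)

DEFAULT_BANDWIDTH_BP = 1_000_000.0
DEFAULT_GRID_STEP_BP = 100_000.0
DEFAULT_PEAK_FRACTION = 0.5


class MappingError(VdmapError):
    pass


def gaussian_kde_1d(positions, bandwidth: float, grid) -> np.ndarray:
    """Plain Gaussian KDE: f(x) = (1/(n h)) * sum_i phi((x - p_i)/h).

    No boundary correction is applied; near chromosome ends the density is
    attenuated because kernel mass falls outside the data range.  An empty
    position list yields a defined all-zero track rather than an error.
    """
    if bandwidth <= 0:
        raise MappingError(f"bandwidth must be positive, got {bandwidth}")
    grid = np.asarray(grid, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        return np.zeros_like(grid)
    out = np.empty_like(grid)
    norm = 1.0 / (positions.size * bandwidth * SQRT_2PI)
    # chunk the grid so the (grid x positions) matrix stays small
    chunk = max(1, int(4_000_000 // max(positions.size, 1)))
    for i in range(0, grid.size, chunk):
        z = (grid[i : i + chunk, None] - positions[None, :]) / bandwidth
        out[i : i + chunk] = np.exp(-0.5 * z * z).sum(axis=1) * norm
    return out


@dataclass
class DensityTrack:
    """Gridded hom/het SNP densities for one chromosome."""

    chrom: str
    grid: np.ndarray  # strictly increasing, constant step (bp)
    hom_density: np.ndarray  # 1/bp
    het_density: np.ndarray  # 1/bp
    n_hom: int
    n_het: int
    bandwidth: float  # bp

    @property
    def grid_step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 0.0


@dataclass
class MappingSignal:
    """Count-scaled hom-minus-het score on the track's grid."""

    chrom: str
    grid: np.ndarray
    score: np.ndarray  # n_hom*hom_density - n_het*het_density (count/bp)
    peak: float  # grid position attaining the maximum (first, i.e. lowest bp)

    @classmethod
    def from_track(cls, track: DensityTrack) -> "MappingSignal":
        score = track.n_hom * track.hom_density - track.n_het * track.het_density
        peak = float(track.grid[int(np.argmax(score))])
        return cls(track.chrom, track.grid, score, peak)

    @property
    def max_score(self) -> float:
        return float(self.score.max()) if self.score.size else 0.0


def build_tracks(
    calls: PartitionResult,
    chrom_lengths: dict[str, int],
    bandwidth: float = DEFAULT_BANDWIDTH_BP,
    grid_step: float = DEFAULT_GRID_STEP_BP,
) -> list[DensityTrack]:
    """One density track per chromosome that has any hom or het SNVs.

    Only SNV calls contribute (indels are kept for annotation but the
    mapping statistic is defined over SNPs).  A SNP beyond its declared
    chromosome length is a fatal error.
    """
    def snv_positions(call_list: list[ZygosityCall]) -> dict[str, list[float]]:
        by_chrom: dict[str, list[float]] = {}
        for call in call_list:
            v = call.variant
            if not v.is_snv:
                continue
            if v.chrom not in chrom_lengths:
                raise MappingError(f"no declared length for chromosome {v.chrom}")
            if v.pos > chrom_lengths[v.chrom]:
                raise MappingError(
                    f"SNP {v.chrom}:{v.pos} lies beyond declared chromosome "
                    f"length {chrom_lengths[v.chrom]}"
                )
            by_chrom.setdefault(v.chrom, []).append(float(v.pos))
        return by_chrom

    hom_by = snv_positions(calls.hom_alt)
    het_by = snv_positions(calls.het)
    tracks: list[DensityTrack] = []
    for chrom in sorted(set(hom_by) | set(het_by)):
        length = chrom_lengths[chrom]
        grid = np.arange(0.0, float(length) + 1.0, float(grid_step))
        hom = hom_by.get(chrom, [])
        het = het_by.get(chrom, [])
        tracks.append(
            DensityTrack(
                chrom=chrom,
                grid=grid,
                hom_density=gaussian_kde_1d(hom, bandwidth, grid),
                het_density=gaussian_kde_1d(het, bandwidth, grid),
                n_hom=len(hom),
                n_het=len(het),
                bandwidth=float(bandwidth),
            )
        )
    return tracks


@dataclass
class PeakCall:
    """Result of interval calling: an interval, or a status explaining none."""

    interval: GenomicInterval | None
    status: str  # "ok" or "no-signal"


def call_peak_interval(signal: MappingSignal, fraction_of_max: float = DEFAULT_PEAK_FRACTION) -> PeakCall:
    """Maximal contiguous grid run around the peak with score >= f * max.

    Returned half-open in bp ([first grid point, last grid point + step)).
    A signal that is nowhere positive yields a no-interval status rather
    than an exception.
    """
    if not (0 < fraction_of_max <= 1):
        raise MappingError(f"fraction_of_max must be in (0, 1], got {fraction_of_max}")
    if signal.score.size == 0 or signal.max_score <= 0:
        return PeakCall(None, "no-signal")
    threshold = fraction_of_max * signal.max_score
    peak_idx = int(np.argmax(signal.score))
    lo = peak_idx
    while lo > 0 and signal.score[lo - 1] >= threshold:
        lo -= 1
    hi = peak_idx
    while hi < signal.score.size - 1 and signal.score[hi + 1] >= threshold:
        hi += 1
    step = float(signal.grid[1] - signal.grid[0]) if signal.grid.size > 1 else 1.0
    start = int(signal.grid[lo])
    end = int(signal.grid[hi] + step)
    return PeakCall(GenomicInterval(signal.chrom, start, end, score=signal.max_score), "ok")


@dataclass(frozen=True)
class ChromRank:
    chrom: str
    max_score: float
    peak: float


def rank_chromosomes(signals: list[MappingSignal]) -> list[ChromRank]:
    """Chromosomes by max score descending; ties broken by name ascending."""
    if not signals:
        raise MappingError("rank_chromosomes requires at least one signal")
    ranks = [ChromRank(s.chrom, s.max_score, s.peak) for s in signals]
    return sorted(ranks, key=lambda r: (-r.max_score, r.chrom))


# ---------------------------------------------------------------------------
# Reporting


def write_density_tsv(tracks: list[DensityTrack], signals: list[MappingSignal], path) -> None:
    """Per-grid-point TSV: chrom, grid_pos, hom_density, het_density, score."""
    by_chrom = {s.chrom: s for s in signals}
    with open(path, "w") as fh:
        fh.write("chrom\tgrid_pos\thom_density\thet_density\tscore\n")
        for track in tracks:
            score = by_chrom[track.chrom].score
            for i in range(track.grid.size):
                fh.write(
                    f"{track.chrom}\t{int(track.grid[i])}\t"
                    f"{track.hom_density[i]:.6e}\t{track.het_density[i]:.6e}\t"
                    f"{score[i]:.6e}\n"
                )


def plot_tracks(tracks: list[DensityTrack], signals: list[MappingSignal], path) -> None:
    """Density-vs-position plot, one panel per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_chrom = {s.chrom: s for s in signals}
    n = len(tracks)
    fig, axes = plt.subplots(n, 1, figsize=(10, 2.2 * n), squeeze=False, sharex=False)
    for ax, track in zip(axes[:, 0], tracks):
        mb = track.grid / 1e6
        ax.plot(mb, track.hom_density, label=f"hom (n={track.n_hom})", color="firebrick")
        ax.plot(mb, track.het_density, label=f"het (n={track.n_het})", color="steelblue")
        sig = by_chrom[track.chrom]
        ax2 = ax.twinx()
        ax2.plot(mb, sig.score, color="gray", alpha=0.5, label="score")
        ax2.set_yticks([])
        ax.set_title(track.chrom, fontsize=9)
        ax.set_ylabel("density (1/bp)", fontsize=8)
        ax.legend(fontsize=7, loc="upper right")
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
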
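"""Evaluation statistics for simulated vs observed coverage.

Implements the comparison toolkit for capture simulations: per-position
coverage tracks, the earth mover's (Wasserstein-1) distance between
normalized coverage distributions, median-threshold high/low coverage
classification with precision/recall/F1, a matched-coverage uniform
baseline summarized over repeated draws with 95% confidence intervals, and
species-abundance tabulation from read assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass
class CoverageTrack:
    """Per-position fragment depth over one reference record."""

    genome_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")

    @property
    def total(self) -> int:
        return int(self.depth.sum())

    @property
    def normalized(self) -> np.ndarray:
        """Coverage normalized by its positional sum (a distribution)."""
        total = self.depth.sum()
        if total <= 0:
            raise ValueError(f"track {self.genome_id!r} has zero total coverage")
        return self.depth / total


def coverage_from_intervals(
    intervals: Iterable, genome_length: int, genome_id: str = ""
) -> CoverageTrack:
    """Depth track from half-open intervals via a difference array.

    ``intervals`` may be (start, end) pairs or any records with .start/.end
    (e.g. FragmentRecord). O(intervals + genome_length).
    """
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    for iv in intervals:
        s, e = (iv.start, iv.end) if hasattr(iv, "start") else (iv[0], iv[1])
        if not (0 <= s < e <= genome_length):
            raise ValueError(f"interval [{s},{e}) out of bounds (length {genome_length})")
        diff[s] += 1
        diff[e] -= 1
    return CoverageTrack(genome_id=genome_id, depth=np.cumsum(diff[:-1]))


def coverage_emd(track_a: CoverageTrack, track_b: CoverageTrack) -> float:
    """Earth mover's distance between two normalized coverage tracks.

    Positions are rescaled to [0, 1] (position i at i/L), making tracks of
    different genomes comparable on a common scale; the 1-D Wasserstein-1
    distance then equals the mean absolute difference of the two CDFs.
    Symmetric, non-negative, zero iff the normalized tracks are identical.
    """
    p = track_a.normalized
    q = track_b.normalized
    if p.shape != q.shape:
        raise ValueError("tracks must cover the same genome length")
    return float(np.abs(np.cumsum(p - q)).mean())


def high_coverage_labels(track: CoverageTrack) -> np.ndarray:
    """Label positions high-coverage when raw depth strictly exceeds the
    genome-wide median (ties at the median are low)."""
    return track.depth > np.median(track.depth)


@dataclass(frozen=True)
class ClassificationMetrics:
    """Precision/recall/F1 of simulated high-coverage calls against the
    observed labels as ground truth; undefined ratios are reported as 0."""

    f1: float
    precision: float
    recall: float
    threshold: float = float("nan")


def classification_metrics(
    observed_labels: np.ndarray,
    simulated_labels: np.ndarray,
    threshold: float = float("nan"),
) -> ClassificationMetrics:
    obs = np.asarray(observed_labels, dtype=bool)
    sim = np.asarray(simulated_labels, dtype=bool)
    if obs.shape != sim.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum(obs & sim))
    fp = int(np.sum(~obs & sim))
    fn = int(np.sum(obs & ~sim))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return ClassificationMetrics(
        f1=f1, precision=precision, recall=recall, threshold=threshold
    )


def compare_tracks(
    observed: CoverageTrack, simulated: CoverageTrack
) -> ClassificationMetrics:
    """Median-threshold classification of a simulated track against an
    observed one (observed labels are the ground truth)."""
    return classification_metrics(
        high_coverage_labels(observed),
        high_coverage_labels(simulated),
        threshold=float(np.median(simulated.depth)),
    )


def sample_uniform_track(
    genome_length: int,
    n_fragments: int,
    log_mu: float,
    log_sigma: float,
    rng: np.random.Generator,
) -> CoverageTrack:
    """One uniform-coverage draw: starts uniform over the genome, lengths
    lognormal (rounded, >= 1), intervals clipped at the genome end."""
    starts = rng.integers(0, genome_length, size=n_fragments)
    lengths = np.maximum(np.rint(rng.lognormal(log_mu, log_sigma, size=n_fragments)), 1)
    ends = np.minimum(starts + lengths.astype(np.int64), genome_length)
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    return CoverageTrack(genome_id="uniform", depth=np.cumsum(diff[:-1]))


@dataclass(frozen=True)
class UniformBaselineSummary:
    """Mean +/- 95% CI half-width of each metric over baseline iterations."""

    f1: tuple[float, float]
    precision: tuple[float, float]
    recall: tuple[float, float]
    n_iter: int
    n_fragments: int


def uniform_baseline(
    genome_length: int,
    log_mu: float,
    log_sigma: float,
    target_mean_coverage: float,
    observed_labels: np.ndarray,
    rng: np.random.Generator,
    n_iter: int = 100,
) -> UniformBaselineSummary:
    """Null model: repeated uniform-coverage simulations matched in depth.

    The fragment count per iteration is chosen so the expected mean
    coverage matches ``target_mean_coverage``: n = round(target * L /
    E[length]) with E[length] = exp(log_mu + log_sigma^2 / 2). Each
    iteration is classified against the observed labels and each metric
    summarized as mean +/- 1.96 * SD / sqrt(n_iter).
    """
    if target_mean_coverage <= 0:
        raise ValueError("target_mean_coverage must be > 0")
    mean_len = float(np.exp(log_mu + log_sigma**2 / 2.0))
    n_fragments = max(1, int(round(target_mean_coverage * genome_length / mean_len)))
    if n_iter == 1:
        warnings.warn("n_iter=1: confidence interval half-widths are 0", stacklevel=2)
    scores = np.empty((n_iter, 3))
    for i in range(n_iter):
        track = sample_uniform_track(genome_length, n_fragments, log_mu, log_sigma, rng)
        m = classification_metrics(observed_labels, high_coverage_labels(track))
        scores[i] = (m.f1, m.precision, m.recall)
    mean = scores.mean(axis=0)
    half = (
        1.96 * scores.std(axis=0, ddof=1) / np.sqrt(n_iter)
        if n_iter > 1
        else np.zeros(3)
    )
    return UniformBaselineSummary(
        f1=(float(mean[0]), float(half[0])),
        precision=(float(mean[1]), float(half[1])),
        recall=(float(mean[2]), float(half[2])),
        n_iter=n_iter,
        n_fragments=n_fragments,
    )


def species_abundance(
    assignments: Iterable, return_unassigned: bool = False
) -> dict[str, float] | tuple[dict[str, float], int]:
    """Percentage of assigned reads per species.

    ``assignments`` yields genome ids, or records with a .genome_id field
    (e.g. FragmentRecord), with None/"" marking unassigned reads, which are
    excluded from the denominator and counted separately (returned when
    ``return_unassigned`` is set).
    """
    counts: dict[str, int] = {}
    unassigned = 0
    for a in assignments:
        gid = getattr(a, "genome_id", a)
        if gid is None or gid == "":
            unassigned += 1
            continue
        counts[gid] = counts.get(gid, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no assigned reads")
    pct = {g: 100.0 * c / total for g, c in counts.items()}
    return (pct, unassigned) if return_unassigned else pct
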
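"""Hyperparameter estimation from an observed read library.

Two quantities drive the simulator and can be fitted from data: the
lognormal fragment-length parameters (maximum likelihood on log lengths)
and the capture/background split, recovered by classifying each read as
capture if its midpoint lies within half the median fragment length
(exp(log_mu)/2) of the nearest candidate bait-binding-site midpoint on the
same genome — the same length-L window the sampler uses to place capture
fragment centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

#: lower clamp for a degenerate (zero-spread) fitted log_sigma
SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class ReadObservation:
    """One observed read placement (0-based half-open)."""

    genome_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"read length must be positive: [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def fit_lognormal(lengths: Sequence[int] | np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit with zero location offset.

    Returns (log_mu, log_sigma): the mean and population standard deviation
    of ln(lengths) — identical to scipy's ``lognorm.fit(x, floc=0)`` MLE.
    A zero spread (all lengths equal) is clamped to a small floor with a
    warning so the result stays a valid lognormal.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 lengths to fit a lognormal")
    if np.any(x <= 0):
        raise ValueError("all lengths must be positive")
    logs = np.log(x)
    log_mu = float(logs.mean())
    log_sigma = float(logs.std(ddof=0))
    if log_sigma < SIGMA_FLOOR:
        warnings.warn(
            "degenerate length distribution: fitted log_sigma clamped to "
            f"{SIGMA_FLOOR}",
            stacklevel=2,
        )
        log_sigma = SIGMA_FLOOR
    return log_mu, log_sigma


def _site_midpoints_by_genome(sites: Sequence) -> dict[str, np.ndarray]:
    """Sorted site midpoints keyed by both organism and record id."""
    by_key: dict[str, list[int]] = {}
    for s in sites:
        mid = (s.start + s.end) // 2
        by_key.setdefault(s.genome_id, []).append(mid)
        rid = getattr(s, "record_id", s.genome_id)
        if rid != s.genome_id:
            by_key.setdefault(rid, []).append(mid)
    return {k: np.sort(np.asarray(v)) for k, v in by_key.items()}


def estimate_capture_fraction(
    reads: Sequence[ReadObservation],
    sites: Sequence,
    log_mu: float,
) -> float:
    """Fraction of reads within exp(log_mu)/2 of a candidate binding site.

    Distances are midpoint-to-midpoint on the same genome, found with a
    sorted-midpoint binary search (O((R+S) log S)). Reads on genomes with
    no candidate site are background. The window radius uses the median
    fragment length exp(log_mu) on the natural scale.
    """
    if len(reads) == 0:
        raise ValueError("no reads to classify")
    radius = float(np.exp(log_mu)) / 2.0
    midpoints = _site_midpoints_by_genome(sites)
    captured = 0
    for r in reads:
        mids = midpoints.get(r.genome_id)
        if mids is None or mids.size == 0:
            continue
        m = r.midpoint
        i = int(np.searchsorted(mids, m))
        nearest = min(
            (abs(m - mids[j]) for j in (i - 1, i) if 0 <= j < mids.size),
        )
        if nearest <= radius:
            captured += 1
    return captured / len(reads)


def reads_from_fragments(fragments: Sequence) -> list[ReadObservation]:
    """View simulator fragments (or any start/end records) as observations.

    Coordinates live on the FASTA record, so the record id (equal to the
    genome id for single-record genomes) keys the observation.
    """
    return [
        ReadObservation(
            genome_id=getattr(f, "record_id", f.genome_id), start=f.start, end=f.end
        )
        for f in fragments
    ]
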
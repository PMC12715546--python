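"""Fragment sampling: the two-level multinomial capture scheme plus the
abundance-weighted uniform background.

Capture fragments arise from a hierarchy of conditioned multinomials: N
binding events are split across baits in proportion to relative
concentration, each bait's events across its candidate sites in proportion
to fractional occupancy, and each event yields a fragment whose length is
lognormal and whose integer center is uniform in a window of that length
centered on the binding-site midpoint. Background fragments are placed
uniformly within genomes, with per-genome counts multinomial in the
genomic abundances. All randomness flows through one numpy Generator, so a
fixed seed reproduces the fragment list exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .io_align import Bait, ReferenceGenome
from .thermo import EnergyModel, ScoredSite, score_sites_by_bait

logger = logging.getLogger("rampsim")

CAPTURE = "capture"
BACKGROUND = "background"


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters of a capture simulation.

    total_fragments is split into N capture and N' background fragments by
    capture_fraction. temperature_C is the hybridization temperature (70 C
    in typical capture protocols). log_mu/log_sigma parameterize the
    fragment-length lognormal: ln L ~ Normal(log_mu, log_sigma^2); lengths
    are rounded to the nearest integer and clamped at min_fragment_length.
    """

    total_fragments: int
    capture_fraction: float
    log_mu: float
    log_sigma: float
    seed: int
    temperature_C: float = 70.0
    min_fragment_length: int = 50

    def __post_init__(self) -> None:
        if self.total_fragments < 0:
            raise ValueError("total_fragments must be >= 0")
        if not 0.0 <= self.capture_fraction <= 1.0:
            raise ValueError("capture_fraction must be in [0, 1]")
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be > 0")
        if self.min_fragment_length < 1:
            raise ValueError("min_fragment_length must be >= 1")


@dataclass(frozen=True)
class FragmentRecord:
    """One sampled double-stranded fragment (0-based half-open interval)."""

    genome_id: str
    record_id: str
    start: int
    end: int
    origin: str  # CAPTURE or BACKGROUND
    bait_id: str | None = None
    site_index: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad fragment interval [{self.start}, {self.end})")
        if (self.origin == CAPTURE) != (self.bait_id is not None):
            raise ValueError("bait_id must be present iff origin is capture")

    @property
    def length(self) -> int:
        return self.end - self.start


def split_counts(config: SimulationConfig) -> tuple[int, int]:
    """Split total_fragments into (N capture, N' background).

    N = round(capture_fraction * total), with Python's round-half-even on
    exact .5 ties; N' is the remainder.
    """
    n = int(round(config.capture_fraction * config.total_fragments))
    return n, config.total_fragments - n


def sample_bait_counts(
    n: int, baits: Sequence[Bait], rng: np.random.Generator
) -> dict[str, int]:
    """Draw binding-event counts per bait: Mult(N, pi), pi_p = c_p / sum c.

    Returns a dict in bait order whose values sum to N.
    """
    if n < 0:
        raise ValueError("N must be >= 0")
    conc = np.array([b.concentration for b in baits], dtype=float)
    if len(baits) == 0 or conc.sum() <= 0:
        raise ValueError("need at least one bait with positive concentration")
    counts = rng.multinomial(n, conc / conc.sum())
    return {b.id: int(c) for b, c in zip(baits, counts)}


def _sample_lengths(
    k: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    lengths = np.rint(rng.lognormal(config.log_mu, config.log_sigma, size=k))
    return np.maximum(lengths, config.min_fragment_length).astype(np.int64)


def sample_capture_fragments(
    bait_counts: Mapping[str, int],
    scored_sites_by_bait: Mapping[str, Sequence[ScoredSite]],
    genomes: Sequence[ReferenceGenome],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[FragmentRecord]:
    """Sample capture fragments for every bait with allocated binding events.

    Per bait p with N_p events: sites are drawn from Mult(N_p, occupancies);
    each event draws a lognormal length L and a uniform integer center in
    the window [m - floor(L/2), m + ceil(L/2)) on the site midpoint m, and
    yields the interval [center - floor(L/2), center - floor(L/2) + L)
    clipped to the record bounds. Events of baits with no candidate site —
    and the rare event whose clipped interval is empty — are dropped with a
    warning and show up in the run summary via the conservation identity
    |capture| + dropped = N.
    """
    record_lengths = {
        rid: len(seq) for g in genomes for rid, seq in g.records.items()
    }
    fragments: list[FragmentRecord] = []
    for bait_id, n_p in bait_counts.items():
        if n_p == 0:
            continue
        scored = scored_sites_by_bait.get(bait_id)
        if not scored:
            logger.warning(
                "bait %s drew %d binding events but has no candidate site; "
                "events dropped",
                bait_id,
                n_p,
            )
            continue
        occ = np.array([s.occupancy for s in scored])
        site_counts = rng.multinomial(n_p, occ / occ.sum())
        for site_index, (ss, count) in enumerate(zip(scored, site_counts)):
            if count == 0:
                continue
            site = ss.site
            glen = record_lengths[site.record_id]
            lengths = _sample_lengths(count, config, rng)
            # uniform integer center in the length-L window on the midpoint
            offsets = rng.integers(0, lengths)
            centers = site.midpoint - lengths // 2 + offsets
            starts = centers - lengths // 2
            ends = starts + lengths
            starts = np.maximum(starts, 0)
            ends = np.minimum(ends, glen)
            for s0, e0 in zip(starts, ends):
                if e0 <= s0:
                    logger.warning(
                        "capture fragment for bait %s clipped to an empty "
                        "interval at record end; event dropped",
                        bait_id,
                    )
                    continue
                fragments.append(
                    FragmentRecord(
                        genome_id=site.genome_id,
                        record_id=site.record_id,
                        start=int(s0),
                        end=int(e0),
                        origin=CAPTURE,
                        bait_id=bait_id,
                        site_index=site_index,
                    )
                )
    return fragments


def sample_background(
    n_prime: int,
    genomes: Sequence[ReferenceGenome],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[FragmentRecord]:
    """Sample N' background fragments uniformly within genomes.

    Per-genome counts are Mult(N', (a_g)); within a multi-record genome the
    record is chosen in proportion to its length; start positions are
    uniform over the record and intervals clipped at the right end.
    """
    if n_prime == 0:
        return []
    abundances = np.array([g.abundance for g in genomes], dtype=float)
    genome_counts = rng.multinomial(n_prime, abundances / abundances.sum())
    fragments: list[FragmentRecord] = []
    for g, n_g in zip(genomes, genome_counts):
        if n_g == 0:
            continue
        rids = list(g.records)
        rec_lens = np.array([len(g.records[r]) for r in rids], dtype=float)
        rec_counts = (
            rng.multinomial(n_g, rec_lens / rec_lens.sum())
            if len(rids) > 1
            else np.array([n_g])
        )
        for rid, n_r in zip(rids, rec_counts):
            if n_r == 0:
                continue
            rlen = len(g.records[rid])
            starts = rng.integers(0, rlen, size=n_r)
            lengths = _sample_lengths(int(n_r), config, rng)
            ends = np.minimum(starts + lengths, rlen)
            fragments.extend(
                FragmentRecord(
                    genome_id=g.id,
                    record_id=rid,
                    start=int(s),
                    end=int(e),
                    origin=BACKGROUND,
                )
                for s, e in zip(starts, ends)
            )
    return fragments


def run_simulation(
    genomes: Sequence[ReferenceGenome],
    baits: Sequence[Bait],
    sites: Sequence,
    config: SimulationConfig,
    model: EnergyModel | None = None,
) -> tuple[list[FragmentRecord], dict]:
    """Score sites, then run the full capture + background sampling pipeline.

    Returns the fragment list (capture first, then background, in draw
    order) and a run summary with realized counts, per-bait events, dropped
    events and the seed. Identical seed and inputs give a bit-identical
    fragment list.
    """
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = EnergyModel.at_celsius(config.temperature_C)
    abundances = {g.id: g.abundance for g in genomes}
    scored = score_sites_by_bait(sites, model, abundances)

    n_capture, n_background = split_counts(config)
    bait_counts = (
        sample_bait_counts(n_capture, baits, rng) if n_capture > 0 else {}
    )
    capture = sample_capture_fragments(bait_counts, scored, genomes, config, rng)
    background = sample_background(n_background, genomes, config, rng)
    fragments = capture + background

    realized_per_bait = {b.id: 0 for b in baits}
    for f in capture:
        realized_per_bait[f.bait_id] += 1
    dropped = {
        bid: bait_counts.get(bid, 0) - realized_per_bait[bid]
        for bid in realized_per_bait
        if bait_counts.get(bid, 0) - realized_per_bait[bid] > 0
    }
    summary = {
        "seed": config.seed,
        "config": asdict(config),
        "n_capture_target": n_capture,
        "n_background_target": n_background,
        "n_capture_realized": len(capture),
        "n_background_realized": len(background),
        "n_dropped": n_capture - len(capture),
        "bait_event_counts": bait_counts,
        "dropped_by_bait": dropped,
        "n_scored_baits": len(scored),
    }
    return fragments, summary
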
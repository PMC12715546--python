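"""Nearest-neighbor hybridization thermodynamics and Boltzmann scoring.

The free energy of a bait-site duplex is estimated with the unified
nearest-neighbor model: the duplex is decomposed into adjacent base-pair
stacks, each contributing tabulated enthalpy and entropy, and

    dG(T) = sum over stacks of (dH_stack - T * dS_stack).

Mismatched positions contribute no stacking energy: any stack whose two
flanking positions are not both Watson-Crick paired is dropped from the sum
(a stack physically requires both flanking pairs). An all-mismatch site
therefore has E = 0 and scores exactly its genome's abundance.

Energies feed the Boltzmann-weighted score S((x,g),p) = a_g exp(-E / RT)
and per-bait fractional occupancies I((x,g),p) = S / sum(S), the expected
fraction of bait p molecules bound at each of its candidate sites — the
Langmuir fractional-occupancy form with the roles of probe and target
swapped (fragments saturate the baits after pre-hybridization PCR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_align import HybridizationSite, revcomp

logger = logging.getLogger("rampsim")

#: universal gas constant, kcal/(mol*K)
GAS_CONSTANT = 1.987e-3

_DEFAULT_PARAM_FILE = "santalucia1998_unified.tsv"

# Duplex initiation corrections of the unified set, applied per duplex end
# when enabled (kcal/mol and cal/(mol*K)). Off by default: they are constant
# per-duplex offsets that the per-bait occupancy normalization largely
# cancels for panels of equal-length baits.
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)


def load_nn_parameters(
    path: str | Path | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Load a nearest-neighbor parameter table.

    The file format is plain text: ``stack<TAB>dH<TAB>dS`` with dH in
    kcal/mol and dS in cal/(mol*K), one line per Watson-Crick stack (the
    stack is the top-strand dinucleotide read 5'->3'). Alternative
    parameter sets can be dropped in via ``path``.
    """
    if path is None:
        text = (
            resources.files("rampsim").joinpath("data", _DEFAULT_PARAM_FILE).read_text()
        )
    else:
        text = Path(path).read_text()
    dH: dict[str, float] = {}
    dS: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        stack, h, s = line.split("\t")
        dH[stack] = float(h)
        dS[stack] = float(s)
    return dH, dS


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor energy model evaluated at a fixed temperature.

    Parameters
    ----------
    nn_dH, nn_dS
        Stack enthalpies (kcal/mol) and entropies (cal/(mol*K)) for the 16
        Watson-Crick dinucleotide stacks.
    temperature
        Hybridization temperature in Kelvin; enters both dG = dH - T dS and
        the Boltzmann factor exp(-E/RT).
    include_initiation
        Apply per-end duplex initiation corrections (default off).
    """

    nn_dH: Mapping[str, float]
    nn_dS: Mapping[str, float]
    temperature: float
    gas_constant: float = GAS_CONSTANT
    include_initiation: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        stacks = {a + b for a in "ACGT" for b in "ACGT"}
        missing = stacks - set(self.nn_dH) | stacks - set(self.nn_dS)
        if missing:
            raise ValueError(f"missing nearest-neighbor stacks: {sorted(missing)}")
        for s in stacks:
            rc = revcomp(s)
            if not (
                np.isclose(self.nn_dH[s], self.nn_dH[rc])
                and np.isclose(self.nn_dS[s], self.nn_dS[rc])
            ):
                raise ValueError(
                    f"parameter table breaks complementary-stack symmetry at {s}/{rc}"
                )

    @classmethod
    def at_celsius(
        cls, temperature_c: float, params_path: str | Path | None = None, **kw
    ) -> "EnergyModel":
        """Build the model at a temperature given in degrees Celsius."""
        dH, dS = load_nn_parameters(params_path)
        return cls(nn_dH=dH, nn_dS=dS, temperature=temperature_c + 273.15, **kw)

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature

    def stack_dg(self, stack: str) -> float:
        """dG of one stack at the model temperature, kcal/mol."""
        return self.nn_dH[stack] - self.temperature * self.nn_dS[stack] * 1e-3


@dataclass(frozen=True)
class ScoredSite:
    """A hybridization site with its Boltzmann score and occupancy."""

    site: HybridizationSite
    score: float
    occupancy: float
    log_score: float = field(default=float("nan"), compare=False)


def site_energy(
    site_sequence: str,
    bait_sequence: str,
    match_mask: np.ndarray | Sequence[bool],
    model: EnergyModel,
) -> float:
    """Hybridization free energy of a candidate duplex, kcal/mol.

    Sums dH - T*dS over dinucleotide steps whose two flanking positions are
    both matched; steps touching a mismatched position contribute 0. A step
    containing N (ambiguous base) is treated as mismatched, never an error.
    """
    mask = np.asarray(match_mask, dtype=bool)
    n = len(site_sequence)
    if not (n == len(bait_sequence) == len(mask)):
        raise ValueError("site sequence, bait sequence and mask lengths differ")
    if n < 2:
        raise ValueError("nearest-neighbor model needs at least one dinucleotide step")
    energy = 0.0
    for i in range(n - 1):
        if not (mask[i] and mask[i + 1]):
            continue
        stack = site_sequence[i : i + 2]
        if "N" in stack:
            continue
        energy += model.stack_dg(stack)
    if model.include_initiation and mask.any():
        for endpos in (0, n - 1):
            if mask[endpos]:
                h, s = _INIT_GC if site_sequence[endpos] in "GC" else _INIT_AT
                energy += h - model.temperature * s * 1e-3
    return energy


def annotate_energies(
    sites: Sequence[HybridizationSite], model: EnergyModel
) -> None:
    """Fill ``site.energy`` in place for each candidate site."""
    for s in sites:
        s.energy = site_energy(s.site_sequence, s.bait_sequence, s.match_mask, model)


def log_binding_score(energy: float, abundance: float, model: EnergyModel) -> float:
    """ln S = ln(a_g) - E/(RT); the overflow-safe representation."""
    if not 0.0 < abundance <= 1.0:
        raise ValueError(f"abundance must be in (0, 1], got {abundance}")
    return float(np.log(abundance) - energy / model.rt)


def binding_score(
    site: HybridizationSite, model: EnergyModel, abundance: float
) -> float:
    """Abundance-weighted Boltzmann score S((x,g),p) = a_g exp(-E/RT).

    Strictly positive, strictly decreasing in E and linear in a_g. For very
    long perfect duplexes ln S can exceed the float range; occupancies are
    always computed from log scores, so downstream results are unaffected.
    """
    if np.isnan(site.energy):
        raise ValueError("site.energy not computed; call annotate_energies first")
    return float(np.exp(log_binding_score(site.energy, abundance, model)))


def occupancies(
    sites_of_bait: Sequence[HybridizationSite],
    model: EnergyModel,
    abundances: Mapping[str, float],
) -> list[ScoredSite]:
    """Fractional occupancies of one bait over its candidate sites.

    Normalizes Boltzmann scores via a max-shifted softmax of log scores
    (|E|/RT can exceed 150 for long perfect duplexes). Occupancies sum to 1
    and are invariant under rescaling all abundances by a common factor.
    """
    if len(sites_of_bait) == 0:
        raise ValueError("occupancies undefined for an empty site set")
    logs = np.array(
        [
            log_binding_score(s.energy, abundances[s.genome_id], model)
            for s in sites_of_bait
        ]
    )
    shifted = np.exp(logs - logs.max())
    occ = shifted / shifted.sum()
    return [
        ScoredSite(
            site=s,
            score=float(np.exp(np.clip(lg, -745.0, 709.0))),
            occupancy=float(o),
            log_score=float(lg),
        )
        for s, lg, o in zip(sites_of_bait, logs, occ)
    ]


def score_sites_by_bait(
    sites: Sequence[HybridizationSite],
    model: EnergyModel,
    abundances: Mapping[str, float],
) -> dict[str, list[ScoredSite]]:
    """Group candidate sites by bait and compute per-bait occupancies.

    Sites with uncomputed energies are annotated first. Baits with no
    candidate site simply do not appear in the result (they capture
    nothing; the sampler logs and reports the dropped events).
    """
    by_bait: dict[str, list[HybridizationSite]] = {}
    for s in sites:
        if np.isnan(s.energy):
            s.energy = site_energy(s.site_sequence, s.bait_sequence, s.match_mask, model)
        by_bait.setdefault(s.bait_id, []).append(s)
    return {
        bid: occupancies(ss, model, abundances) for bid, ss in by_bait.items()
    }
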
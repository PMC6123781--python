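"""Synthetic parts, registries, and titer measurements.

The simulator emulates the statistical structure the Learn stage assumes:
log10 titer is a linear function of the design factors (a per-level effect
for each factor, an optional gene-order effect) plus i.i.d. Gaussian noise
on the log scale — i.e. log-normal multiplicative noise on titers, which
keeps titers positive and reproduces the orders-of-magnitude spread seen
in combinatorial expression libraries.  DNA parts are uniform-random
sequences at a requested GC content.  Every operation draws all of its
randomness from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .construct_builder import Part, PartRegistry
from .doe import Library

__all__ = [
    "GroundTruth",
    "random_dna",
    "random_parts",
    "registry_for_space",
    "simulate_titers",
]

MIN_PART_LENGTH = 40  # bridging-oligo halves must fit inside the part


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA with GC content exact to the nearest achievable count.

    The number of G+C bases is round(gc * length), positions and the G/C
    vs A/T identity are uniform, so observed GC differs from the request by
    less than one base.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("GC content must lie in [0, 1]")
    n_gc = int(round(gc * length))
    bases = np.empty(length, dtype="<U1")
    strong = rng.choice(["G", "C"], size=n_gc)
    weak = rng.choice(["A", "T"], size=length - n_gc)
    bases[:n_gc] = strong
    bases[n_gc:] = weak
    return "".join(bases[rng.permutation(length)])


def _termini_support_tm(seq: str, target_tm: float, max_half: int) -> bool:
    from .lcr_planner import melting_temperature

    span = min(max_half, len(seq))
    return (
        melting_temperature(seq[:span]) >= target_tm
        and melting_temperature(seq[-span:]) >= target_tm
    )


def random_parts(
    ids_roles: Mapping[str, str],
    lengths: Mapping[str, int],
    seed: int,
    gc: float = 0.5,
    junction_tm: Optional[float] = 70.0,
    max_half: int = 60,
) -> PartRegistry:
    """A reproducible registry of random parts.

    ``ids_roles`` maps part ID to role; ``lengths`` maps part ID to length
    (every part must be at least 40 nt so that bridging-oligo halves can
    anneal inside it).  The same seed always yields the same sequences.

    Parts destined for ligase-cycling assembly are designed upstream with
    assembly-compatible termini; the generator emulates that screen: when
    ``junction_tm`` is set, sequences are resampled until both terminal
    ``max_half``-nt windows can melt at or above the target, so every
    junction of a compiled construct admits a bridging oligo.  Pass
    ``junction_tm=None`` for unscreened (adversarial) parts.
    """
    rng = np.random.default_rng(seed)
    registry = PartRegistry()
    for pid in ids_roles:  # deterministic: insertion order of the mapping
        length = lengths[pid]
        if length < MIN_PART_LENGTH:
            raise ValueError(
                f"part {pid!r}: length {length} < {MIN_PART_LENGTH} nt minimum "
                "(bridging halves must fit)"
            )
        for _ in range(200):
            seq = random_dna(length, gc, rng)
            if junction_tm is None or _termini_support_tm(seq, junction_tm, max_half):
                break
        else:
            raise ValueError(
                f"part {pid!r}: could not draw termini reaching "
                f"Tm >= {junction_tm:g} degC at GC {gc:g} within {max_half} nt"
            )
        registry.add(Part(id=pid, role=ids_roles[pid], sequence=seq))
    return registry


DEFAULT_LENGTHS = {"backbone": 2500, "promoter": 60, "gene": 900, "terminator": 60}


def registry_for_space(space, seed: int, gc: float = 0.5,
                       lengths: Optional[Mapping[str, int]] = None) -> PartRegistry:
    """Registry holding one random part per factor level / gene of a space.

    Factor levels (except the ``none`` label) become parts whose role is
    inferred from the factor name; genes become gene parts.  Lengths per
    role default to typical part sizes (backbone 2.5 kb, genes 0.9 kb,
    promoters/terminators 60 nt).
    """
    sizes = dict(DEFAULT_LENGTHS)
    if lengths:
        sizes.update(lengths)
    ids_roles: Dict[str, str] = {}
    for f in space.factors:
        role = "backbone" if "backbone" in f.name else "promoter"
        for level in f.levels:
            if level == "none" or level in ids_roles:
                continue
            ids_roles[level] = role
    if space.order_factor is not None:
        for gene in space.order_factor.genes:
            ids_roles[gene] = "gene"
    part_lengths = {pid: sizes[role] for pid, role in ids_roles.items()}
    return random_parts(ids_roles, part_lengths, seed=seed, gc=gc)


@dataclass(frozen=True)
class GroundTruth:
    """The planted effect structure behind simulated titers.

    ``effects[factor][level]`` is the additive contribution to log10 titer
    (missing entries contribute zero); ``order_effects`` optionally keys a
    contribution by the dash-joined gene ordering.  ``noise_sd`` is the
    log10-scale Gaussian noise standard deviation and ``seed`` is
    mandatory — all simulator randomness flows from it.
    """

    baseline: float
    effects: Mapping[str, Mapping[str, float]]
    noise_sd: float
    n_replicates: int
    seed: int
    order_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "effects", {k: dict(v) for k, v in dict(self.effects).items()}
        )
        object.__setattr__(self, "order_effects", dict(self.order_effects))
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def linear_predictor(self, point) -> float:
        lp = self.baseline
        for fac, level in point.assignment.items():
            lp += self.effects.get(fac, {}).get(level, 0.0)
        if point.ordering:
            lp += self.order_effects.get("-".join(point.ordering), 0.0)
        return lp


def simulate_titers(library: Library, truth: GroundTruth) -> pd.DataFrame:
    """Simulated replicate-level titers for every library construct.

    titer = 10 ** (baseline + sum of level effects + N(0, sd)) per
    replicate; rows are ordered (construct, replicate) and the generator is
    seeded from ``truth.seed``, so output is deterministic.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    for point in library.points:
        lp = truth.linear_predictor(point)
        noise = rng.normal(0.0, truth.noise_sd, size=truth.n_replicates) \
            if truth.noise_sd > 0 else np.zeros(truth.n_replicates)
        for r in range(truth.n_replicates):
            rows.append(
                {
                    "construct_id": point.id,
                    "replicate": r + 1,
                    "titer": float(10.0 ** (lp + noise[r])),
                }
            )
    return pd.DataFrame(rows, columns=["construct_id", "replicate", "titer"])
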
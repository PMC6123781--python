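"""Ligase cycling reaction (LCR) assembly planning.

LCR joins double-stranded parts via single-stranded bridging oligos: each
bridge spans one part junction, its left half annealing to the 3' end of
the upstream part and its right half to the 5' start of the downstream
part.  Both halves are grown until their predicted duplex melting
temperature reaches the assembly target (70 degC by default), predicted by
nearest-neighbor thermodynamics with a monovalent-salt correction.  A
circular plasmid of n parts needs n bridges (one per junction, including
the closure junction), and bridges shared between constructs are pooled
once per library.

The planner also emits the three robotics worklist stages used on a
liquid-handling deck — part dilution to the working concentration, per-
construct bridging-oligo pooling, and LCR reaction setup — plus a seeded
random injection-sequence permutation for downstream analytics.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

from .construct_builder import Part, PlasmidRecord

__all__ = [
    "TmConditions",
    "BridgingOligo",
    "Worklist",
    "PlateLayout",
    "WorklistSet",
    "LcrPlanError",
    "melting_temperature",
    "design_bridge",
    "plan_assembly",
    "pool_oligos",
    "generate_worklists",
    "injection_sequence",
]

_DNA_RE = re.compile(r"^[ACGT]+$")


class LcrPlanError(ValueError):
    """Raised when an assembly plan or worklist cannot be produced."""


@dataclass(frozen=True)
class TmConditions:
    """Hybridization conditions for the nearest-neighbor Tm model.

    Defaults: 50 mM Na+, 250 nM oligo (the annealing strand in excess).
    All values are configurable; they parameterize the unified
    nearest-neighbor table with the entropic salt correction
    dS' = dS + 0.368 (N-1) ln[Na+].
    """

    na_mM: float = 50.0
    mg_mM: float = 0.0
    oligo_nM: float = 250.0

    def describe(self) -> str:
        return (
            f"NN unified parameters, {self.na_mM:g} mM Na+, "
            f"{self.mg_mM:g} mM Mg2+, {self.oligo_nM:g} nM oligo"
        )


DEFAULT_CONDITIONS = TmConditions()


def melting_temperature(seq: str, conditions: TmConditions = DEFAULT_CONDITIONS) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    Uses the unified DNA nearest-neighbor ΔH/ΔS parameters with duplex
    initiation and terminal-AT penalties, a monovalent-salt entropy
    correction, and the stated oligo concentration.  Symmetric under
    reverse complement (the duplex is the same molecule).
    """
    seq = str(seq).upper()
    if len(seq) < 2:
        raise ValueError("Tm needs at least one nearest-neighbor stack (len >= 2)")
    if not _DNA_RE.match(seq):
        raise ValueError(f"ambiguous or non-DNA characters in {seq!r}")
    return float(
        _mt.Tm_NN(
            Seq(seq),
            nn_table=_mt.DNA_NN3,
            Na=conditions.na_mM,
            Mg=conditions.mg_mM,
            dnac1=conditions.oligo_nM,
            dnac2=0.0,
            saltcorr=5,
        )
    )


@dataclass(frozen=True)
class BridgingOligo:
    """A junction-spanning bridge.

    ``sequence`` is the junction context on the construct's sense strand,
    ``left_half`` the 3'-terminal subsequence of the upstream part and
    ``right_half`` the 5'-initial subsequence of the downstream part (so
    ``left_half + right_half == sequence``).  The physical oligo to order
    is the reverse complement (:meth:`order_sequence`), which anneals
    across both single-stranded part termini during ligase cycling.
    """

    junction: Tuple[str, str]
    left_half: str
    right_half: str
    tm_left: float
    tm_right: float

    @property
    def sequence(self) -> str:
        return self.left_half + self.right_half

    def order_sequence(self) -> str:
        return str(Seq(self.sequence).reverse_complement())

    @property
    def id(self) -> str:
        import hashlib

        return "BO" + hashlib.sha1(self.sequence.encode()).hexdigest()[:8]


def design_bridge(
    upstream: Part,
    downstream: Part,
    target_tm: float = 70.0,
    min_half: int = 15,
    max_half: int = 60,
    conditions: TmConditions = DEFAULT_CONDITIONS,
) -> BridgingOligo:
    """Design the bridging oligo for one part junction.

    Each half is the shortest terminal subsequence, no shorter than
    ``min_half`` nt, whose predicted Tm reaches ``target_tm``; growth stops
    at ``max_half`` nt with an error naming the junction if the target is
    unreachable.  Deterministic: identical junction context yields an
    identical oligo, which is the deduplication key across a library.
    """

    def _grow(part: Part, take_tail: bool) -> Tuple[str, float]:
        seq = part.sequence
        for length in range(min_half, max_half + 1):
            if length > len(seq):
                break
            half = seq[-length:] if take_tail else seq[:length]
            tm = melting_temperature(half, conditions)
            if tm >= target_tm:
                return half, tm
        raise LcrPlanError(
            f"junction {upstream.id}->{downstream.id}: cannot reach "
            f"Tm >= {target_tm:g} degC on the "
            f"{'upstream 3-prime' if take_tail else 'downstream 5-prime'} half "
            f"within {min(max_half, len(seq))} nt"
        )

    left, tm_left = _grow(upstream, take_tail=True)
    right, tm_right = _grow(downstream, take_tail=False)
    return BridgingOligo(
        junction=(upstream.id, downstream.id),
        left_half=left,
        right_half=right,
        tm_left=tm_left,
        tm_right=tm_right,
    )


def plan_assembly(
    record: PlasmidRecord,
    target_tm: float = 70.0,
    min_half: int = 15,
    max_half: int = 60,
    conditions: TmConditions = DEFAULT_CONDITIONS,
) -> List[BridgingOligo]:
    """Bridging oligos for every junction of a circular assembly.

    A circular record of n parts has n junctions — consecutive pairs plus
    the closure junction from the last part back to the first — so the
    plan holds exactly n oligos, in junction order.
    """
    feats = record.features
    if len(feats) < 2:
        raise LcrPlanError(
            f"record {record.id} has {len(feats)} part(s); LCR bridging needs "
            "at least two parts to form a junction"
        )
    parts = [
        Part(id=f.part_id, role=f.role, sequence=record.feature_sequence(f))
        for f in feats
    ]
    oligos = []
    for i, up in enumerate(parts):
        down = parts[(i + 1) % len(parts)]
        oligos.append(
            design_bridge(up, down, target_tm=target_tm, min_half=min_half,
                          max_half=max_half, conditions=conditions)
        )
    return oligos


def pool_oligos(
    plans: Mapping[str, Sequence[BridgingOligo]],
) -> Tuple[List[BridgingOligo], Dict[str, List[str]]]:
    """Deduplicate bridges across a library by junction context.

    Returns the unique oligo pool (first-appearance order over constructs
    sorted by ID, for run-to-run stability) and, per construct, the IDs of
    the oligos it uses.
    """
    pool: Dict[str, BridgingOligo] = {}
    usage: Dict[str, List[str]] = {}
    for construct_id in sorted(plans):
        ids = []
        for oligo in plans[construct_id]:
            if oligo.sequence not in pool:
                pool[oligo.sequence] = oligo
            ids.append(pool[oligo.sequence].id)
        usage[construct_id] = ids
    return list(pool.values()), usage


# ---------------------------------------------------------------------------
# Worklists


@dataclass(frozen=True)
class PlateLayout:
    """Source-well map: reagent ID -> (labware barcode, well)."""

    sources: Mapping[str, Tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", dict(self.sources))

    def lookup(self, reagent_id: str) -> Tuple[str, str]:
        return self.sources[reagent_id]

    @staticmethod
    def auto(reagent_ids: Sequence[str], labware_prefix: str = "SRC") -> "PlateLayout":
        """Assign reagents to 96-well plates row-major, in given order."""
        sources = {}
        for i, rid in enumerate(reagent_ids):
            plate = f"{labware_prefix}_{i // 96 + 1}"
            sources[rid] = (plate, well_name(i % 96))
        return PlateLayout(sources)


def well_name(index: int) -> str:
    """Row-major 96-well name: 0 -> A1, 11 -> A12, 95 -> H12."""
    if not 0 <= index < 96:
        raise ValueError("96-well plate index out of range")
    return f"{'ABCDEFGH'[index // 12]}{index % 12 + 1}"


_WORKLIST_COLUMNS = (
    "source_labware",
    "source_well",
    "destination_labware",
    "destination_well",
    "volume_ul",
    "reagent_id",
)


@dataclass(frozen=True)
class Worklist:
    """A robotics pipetting recipe: ordered transfer rows."""

    name: str
    rows: Tuple[Tuple[str, str, str, str, float, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(tuple(r) for r in self.rows))
        for r in self.rows:
            if r[4] <= 0:
                raise ValueError(f"non-positive transfer volume in row {r!r}")
            _validate_well(r[3])

    def to_csv(self) -> str:
        """Comma-separated, header row, LF line endings."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(_WORKLIST_COLUMNS)
        for r in self.rows:
            writer.writerow([r[0], r[1], r[2], r[3], f"{r[4]:.2f}", r[5]])
        return buf.getvalue()

    def write_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(self.to_csv())

    def destination_totals(self) -> Dict[Tuple[str, str], float]:
        totals: Dict[Tuple[str, str], float] = {}
        for r in self.rows:
            key = (r[2], r[3])
            totals[key] = totals.get(key, 0.0) + r[4]
        return totals


def _validate_well(well: str) -> None:
    m = re.match(r"^([A-H])(\d{1,2})$", well)
    if not m or not 1 <= int(m.group(2)) <= 12:
        raise ValueError(f"invalid 96-well name {well!r}")


@dataclass(frozen=True)
class WorklistSet:
    """The three LCR pipetting stages plus the analytics injection order."""

    part_dilution: Worklist
    oligo_pooling: Worklist
    lcr_setup: Worklist
    injection_order: Tuple[str, ...]

    def stages(self) -> Dict[str, Worklist]:
        return {
            "part_dilution": self.part_dilution,
            "oligo_pooling": self.oligo_pooling,
            "lcr_setup": self.lcr_setup,
        }

    def write_dir(self, directory) -> None:
        """Write the stage CSVs plus injection_sequence.csv into a directory."""
        import os

        os.makedirs(directory, exist_ok=True)
        for name, wl in self.stages().items():
            wl.write_csv(os.path.join(directory, f"{name}.csv"))
        with open(
            os.path.join(directory, "injection_sequence.csv"),
            "w",
            newline="",
            encoding="utf-8",
        ) as fh:
            fh.write("injection_index,sample_id\n")
            for i, sid in enumerate(self.injection_order, start=1):
                fh.write(f"{i},{sid}\n")


def generate_worklists(
    plans: Mapping[str, Sequence[BridgingOligo]],
    part_usage: Mapping[str, Sequence[str]],
    layout: PlateLayout,
    seed: int,
    reaction_volume_ul: float = 25.0,
    part_volume_ul: float = 1.0,
    oligo_pool_volume_ul: float = 2.0,
    dilution_volume_ul: float = 50.0,
) -> WorklistSet:
    """Emit the three LCR worklist stages plus the injection sequence.

    Stage 1 dilutes every used part to the 75 nM working concentration;
    stage 2 pools each construct's bridging oligos into a per-construct
    pool well; stage 3 sets up the LCR reactions — each destination well
    receives its diluted parts, its oligo pool, and a master-mix top-up so
    that the per-well total equals ``reaction_volume_ul`` exactly.  The
    ``seed`` drives only the randomized analytics injection order; all
    pipetting rows are deterministic, so equal seeds give byte-identical
    CSV files.
    """
    construct_ids = sorted(plans)
    if set(part_usage) != set(plans):
        raise LcrPlanError("part_usage and plans must cover the same constructs")

    pool, oligo_usage = pool_oligos(plans)
    needed_parts: List[str] = []
    for cid in construct_ids:
        for pid in part_usage[cid]:
            if pid not in needed_parts:
                needed_parts.append(pid)

    required = needed_parts + [o.id for o in pool]
    if construct_ids:
        required += ["water", "master_mix"]
    missing = [rid for rid in required if rid not in layout.sources]
    if missing:
        raise LcrPlanError(
            "plate layout lacks source wells for: " + ", ".join(sorted(missing))
        )

    # Stage 1: part dilution to 75 nM working stocks, one well per part
    dilution_rows = []
    for i, pid in enumerate(needed_parts):
        src_plate, src_well = layout.lookup(pid)
        dest = well_name(i % 96)
        dest_plate = f"DIL_{i // 96 + 1}"
        stock_ul = round(dilution_volume_ul * 0.25, 2)  # 4x stock -> 75 nM final
        water_plate, water_well = layout.lookup("water")
        dilution_rows.append(
            (src_plate, src_well, dest_plate, dest, stock_ul, pid)
        )
        dilution_rows.append(
            (water_plate, water_well, dest_plate, dest,
             dilution_volume_ul - stock_ul, "water")
        )
    part_dilution_well = {
        pid: (f"DIL_{i // 96 + 1}", well_name(i % 96))
        for i, pid in enumerate(needed_parts)
    }

    # Stage 2: per-construct bridging-oligo pooling
    pooling_rows = []
    pool_well_of: Dict[str, Tuple[str, str]] = {}
    for i, cid in enumerate(construct_ids):
        dest_plate = f"POOL_{i // 96 + 1}"
        dest = well_name(i % 96)
        pool_well_of[cid] = (dest_plate, dest)
        for oid in oligo_usage[cid]:
            src_plate, src_well = layout.lookup(oid)
            pooling_rows.append((src_plate, src_well, dest_plate, dest, 2.0, oid))

    # Stage 3: LCR setup; totals per destination equal the reaction volume
    lcr_rows = []
    for i, cid in enumerate(construct_ids):
        dest_plate = f"LCR_{i // 96 + 1}"
        dest = well_name(i % 96)
        used = 0.0
        for pid in part_usage[cid]:
            plate, well = part_dilution_well[pid]
            lcr_rows.append((plate, well, dest_plate, dest, part_volume_ul, pid))
            used += part_volume_ul
        plate, well = pool_well_of[cid]
        lcr_rows.append(
            (plate, well, dest_plate, dest, oligo_pool_volume_ul, f"oligo_pool:{cid}")
        )
        used += oligo_pool_volume_ul
        top_up = reaction_volume_ul - used
        if top_up <= 0:
            raise LcrPlanError(
                f"construct {cid}: transfers ({used:g} uL) exceed the "
                f"{reaction_volume_ul:g} uL reaction volume"
            )
        mm_plate, mm_well = layout.lookup("master_mix")
        lcr_rows.append((mm_plate, mm_well, dest_plate, dest, top_up, "master_mix"))

    return WorklistSet(
        part_dilution=Worklist("part_dilution", tuple(dilution_rows)),
        oligo_pooling=Worklist("oligo_pooling", tuple(pooling_rows)),
        lcr_setup=Worklist("lcr_setup", tuple(lcr_rows)),
        injection_order=tuple(injection_sequence(construct_ids, seed)),
    )


def injection_sequence(sample_ids: Sequence[str], seed: int) -> List[str]:
    """Randomized analytics injection order, reproducible from the seed.

    Instrument injection sequences are randomized to decorrelate run order
    from plate position; the permutation is drawn from a seeded generator
    so the same seed yields the same order.
    """
    rng = np.random.default_rng(seed)
    ids = list(sample_ids)
    return [ids[i] for i in rng.permutation(len(ids))]
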
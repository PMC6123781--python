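"""Compile pathway designs into annotated circular plasmid sequences.

A :class:`ConstructTemplate` is an ordered list of part slots — one
backbone slot, then per gene position an optional promoter slot and a gene
slot, plus optional fixed parts such as terminators.  Compiling a design
point concatenates the referenced parts in template order (ligase cycling
reaction assembly is scarless, so no junction sequence is inserted) and
records one feature per part on a circular record.  Coordinates are
0-based half-open on the plus strand internally; GenBank IO converts to
the format's 1-based convention and emits join-style locations for
features spanning the origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .design_space import DesignPoint

__all__ = [
    "Part",
    "PartRegistry",
    "Slot",
    "ConstructTemplate",
    "Feature",
    "PlasmidRecord",
    "CompileError",
    "compile_construct",
    "operon_template",
    "write_genbank",
    "read_genbank",
    "write_parts_fasta",
    "read_parts_fasta",
]

_DNA_RE = re.compile(r"^[ACGT]+$")

ROLES = ("backbone", "promoter", "gene", "terminator")

#: Level label that omits an optional slot entirely.
NONE_LEVEL = "none"


class CompileError(ValueError):
    """Raised when a design point cannot be compiled against a registry."""


@dataclass(frozen=True)
class Part:
    """A DNA part: backbone, promoter, gene (CDS cassette), or terminator."""

    id: str
    role: str
    sequence: str
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", str(self.sequence).upper())
        object.__setattr__(self, "metadata", dict(self.metadata))
        if not self.id:
            raise ValueError("part id must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown part role {self.role!r}")
        if not self.sequence or not _DNA_RE.match(self.sequence):
            raise ValueError(
                f"part {self.id!r}: sequence must be non-empty over A/C/G/T"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class PartRegistry:
    """Part collection keyed by ID, with FASTA round-tripping."""

    def __init__(self, parts: Iterable[Part] = ()) -> None:
        self._parts: Dict[str, Part] = {}
        for p in parts:
            self.add(p)

    def add(self, part: Part) -> None:
        if part.id in self._parts:
            raise ValueError(f"duplicate part id {part.id!r}")
        self._parts[part.id] = part

    def get(self, part_id: str) -> Part:
        try:
            return self._parts[part_id]
        except KeyError:
            raise KeyError(f"part {part_id!r} not in registry") from None

    def __contains__(self, part_id: str) -> bool:
        return part_id in self._parts

    def __iter__(self):
        return iter(self._parts.values())

    def __len__(self) -> int:
        return len(self._parts)

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(self._parts)


@dataclass(frozen=True)
class Slot:
    """One position in the construct template.

    Exactly one of the three bindings is set: ``factor`` (slot filled by a
    factor level, e.g. promoter or backbone choice), ``gene_position``
    (filled by the design's gene ordering) or ``part`` (a fixed part).
    """

    role: str
    factor: Optional[str] = None
    gene_position: Optional[int] = None
    part: Optional[str] = None
    optional: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown slot role {self.role!r}")
        bindings = sum(
            x is not None for x in (self.factor, self.gene_position, self.part)
        )
        if bindings != 1:
            raise ValueError(
                "slot must bind exactly one of factor / gene_position / part"
            )


@dataclass(frozen=True)
class ConstructTemplate:
    """Ordered slot layout with exactly one backbone slot."""

    slots: Tuple[Slot, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "slots", tuple(self.slots))
        n_backbone = sum(1 for s in self.slots if s.role == "backbone")
        if n_backbone != 1:
            raise ValueError(
                f"template must have exactly one backbone slot, found {n_backbone}"
            )

    def __iter__(self):
        return iter(self.slots)


def operon_template(
    n_genes: int,
    backbone_factor: str = "backbone",
    promoter_factor_fmt: str = "promoter_slot_{pos}",
    first_promoter_in_backbone: bool = True,
    terminator_part: Optional[str] = None,
) -> ConstructTemplate:
    """Standard pathway-operon layout.

    Backbone first (carrying the promoter upstream of position 0 when
    ``first_promoter_in_backbone``), then per gene position an optional
    intergenic promoter slot followed by the gene slot, and an optional
    fixed terminator after the last gene.
    """
    slots: List[Slot] = [Slot(role="backbone", factor=backbone_factor)]
    for pos in range(n_genes):
        if pos > 0 or not first_promoter_in_backbone:
            slots.append(
                Slot(
                    role="promoter",
                    factor=promoter_factor_fmt.format(pos=pos),
                    optional=True,
                )
            )
        slots.append(Slot(role="gene", gene_position=pos))
    if terminator_part is not None:
        slots.append(Slot(role="terminator", part=terminator_part))
    return ConstructTemplate(tuple(slots))


@dataclass(frozen=True)
class Feature:
    """An annotated part interval, 0-based half-open, plus strand."""

    part_id: str
    role: str
    start: int
    end: int
    strand: int = 1


@dataclass(frozen=True)
class PlasmidRecord:
    """A compiled circular plasmid: sequence plus part features."""

    id: str
    sequence: str
    features: Tuple[Feature, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))

    def __len__(self) -> int:
        return len(self.sequence)

    def part_ids(self) -> Tuple[str, ...]:
        return tuple(f.part_id for f in self.features)

    def feature_sequence(self, feature: Feature) -> str:
        """Sequence under a feature; handles origin-spanning intervals."""
        if feature.end >= feature.start:
            return self.sequence[feature.start : feature.end]
        return self.sequence[feature.start :] + self.sequence[: feature.end]

    def validate_tiling(self) -> None:
        """Check that features partition [0, L) without gaps or overlap."""
        covered = 0
        pos = 0
        for f in self.features:
            if f.start != pos:
                raise ValueError(
                    f"feature {f.part_id} starts at {f.start}, expected {pos}"
                )
            if f.end <= f.start:
                raise ValueError(f"feature {f.part_id} has non-positive extent")
            covered += f.end - f.start
            pos = f.end
        if covered != len(self.sequence):
            raise ValueError(
                f"features cover {covered} nt of a {len(self.sequence)} nt record"
            )


def compile_construct(
    point: DesignPoint,
    registry: PartRegistry,
    template: ConstructTemplate,
    none_level: str = NONE_LEVEL,
    record_id: Optional[str] = None,
) -> PlasmidRecord:
    """Compile a design point into an annotated circular plasmid.

    Slots are laid down in template order; a promoter slot whose assigned
    level equals ``none_level`` is omitted entirely (no feature, no
    sequence).  Concatenation is seamless — ligase cycling reaction leaves
    no assembly scars.  Deterministic in all inputs.
    """
    chunks: List[str] = []
    feats: List[Feature] = []
    pos = 0
    for slot in template:
        if slot.factor is not None:
            if slot.factor not in point.assignment:
                raise CompileError(
                    f"design point {point.id} assigns no level to factor "
                    f"{slot.factor!r}"
                )
            level = point.assignment[slot.factor]
            if level == none_level:
                if not slot.optional and slot.role != "promoter":
                    raise CompileError(
                        f"slot {slot.role}/{slot.factor} is mandatory but level "
                        f"is {none_level!r}"
                    )
                continue
            part_id = level
        elif slot.gene_position is not None:
            if slot.gene_position >= len(point.ordering):
                raise CompileError(
                    f"template gene position {slot.gene_position} exceeds the "
                    f"design's {len(point.ordering)}-gene ordering"
                )
            part_id = point.ordering[slot.gene_position]
        else:
            part_id = slot.part  # fixed part
        if part_id not in registry:
            raise CompileError(
                f"slot {slot.role} (level/part {part_id!r}) references a part "
                "missing from the registry"
            )
        part = registry.get(part_id)
        chunks.append(part.sequence)
        feats.append(
            Feature(part_id=part.id, role=slot.role, start=pos,
                    end=pos + len(part))
        )
        pos += len(part)
    record = PlasmidRecord(
        id=record_id or point.id,
        sequence="".join(chunks),
        features=tuple(feats),
        circular=True,
    )
    record.validate_tiling()
    return record


# ---------------------------------------------------------------------------
# GenBank / FASTA IO (Biopython-backed)

_GB_TYPE = {
    "backbone": "misc_feature",
    "promoter": "promoter",
    "gene": "CDS",
    "terminator": "terminator",
}
_GB_TYPE_INV = {v: k for k, v in _GB_TYPE.items()}


def _to_seqrecord(record: PlasmidRecord) -> SeqRecord:
    sr = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                   description="")
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular" if record.circular else "linear"
    L = len(record.sequence)
    for f in record.features:
        if f.end > f.start:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        else:  # spans the origin of a circular record -> join location
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start, L, strand=f.strand),
                    SimpleLocation(0, f.end, strand=f.strand),
                ]
            )
        sr.features.append(
            SeqFeature(
                loc,
                type=_GB_TYPE.get(f.role, "misc_feature"),
                qualifiers={"label": [f.part_id], "note": [f"role:{f.role}"]},
            )
        )
    return sr


def _from_seqrecord(sr: SeqRecord) -> PlasmidRecord:
    feats: List[Feature] = []
    for sf in sr.features:
        qual = sf.qualifiers
        part_id = (qual.get("label") or [sf.type])[0]
        role = _GB_TYPE_INV.get(sf.type, "backbone")
        for note in qual.get("note", []):
            if note.startswith("role:"):
                role = note[5:]
        strand = sf.location.strand or 1
        if isinstance(sf.location, CompoundLocation):
            parts = sorted(sf.location.parts, key=lambda p: int(p.start))
            # origin-spanning join: [x, L) + [0, y)
            start = int(parts[-1].start)
            end = int(parts[0].end)
        else:
            start = int(sf.location.start)
            end = int(sf.location.end)
        feats.append(Feature(part_id=part_id, role=role, start=start, end=end,
                             strand=strand))
    return PlasmidRecord(
        id=sr.id,
        sequence=str(sr.seq).upper(),
        features=tuple(feats),
        circular=sr.annotations.get("topology", "linear") == "circular",
    )


def write_genbank(record: PlasmidRecord, destination) -> None:
    """Write a plasmid to GenBank (1-based closed coordinates on disk)."""
    SeqIO.write(_to_seqrecord(record), destination, "genbank")


def read_genbank(source) -> PlasmidRecord:
    """Read one GenBank record back into a :class:`PlasmidRecord`."""
    sr = SeqIO.read(source, "genbank")
    return _from_seqrecord(sr)


def write_parts_fasta(registry: PartRegistry, destination) -> None:
    """Write all registry parts as FASTA; the description carries the role."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=f"role={p.role}")
        for p in registry
    ]
    SeqIO.write(records, destination, "fasta")


def read_parts_fasta(source, default_role: str = "gene") -> PartRegistry:
    """Read parts from FASTA, recovering roles from ``role=`` descriptions."""
    registry = PartRegistry()
    for sr in SeqIO.parse(source, "fasta"):
        role = default_role
        for token in sr.description.split():
            if token.startswith("role="):
                role = token[5:]
        registry.add(Part(id=sr.id, role=role, sequence=str(sr.seq)))
    return registry
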
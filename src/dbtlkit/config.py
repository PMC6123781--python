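"""Structured-configuration IO for design spaces and constraint sets.

Design templates and constraints travel as YAML (JSON is a YAML subset, so
either dialect loads).  Factor levels reference part registry IDs; the
template section mirrors :class:`dbtlkit.construct_builder.ConstructTemplate`
slot by slot.
"""

from __future__ import annotations

from typing import Optional

import yaml

from .construct_builder import ConstructTemplate, Slot
from .design_space import (
    ConstraintSet,
    DesignSpace,
    Factor,
    GeneOrderFactor,
)

__all__ = [
    "load_design_space",
    "save_design_space",
    "load_constraints",
    "save_constraints",
]


def _space_to_dict(space: DesignSpace) -> dict:
    doc: dict = {
        "factors": [
            {
                "name": f.name,
                "kind": f.kind,
                "levels": list(f.levels),
                **(
                    {"ordinal_rank": list(f.ordinal_rank)}
                    if f.ordinal_rank is not None
                    else {}
                ),
            }
            for f in space.factors
        ]
    }
    if space.order_factor is not None:
        of = space.order_factor
        doc["gene_order"] = {
            "genes": list(of.genes),
            "mode": of.mode,
            **({"fixed": dict(of.fixed)} if of.fixed else {}),
            **(
                {"explicit": [list(o) for o in of.explicit]}
                if of.explicit is not None
                else {}
            ),
        }
    if space.template is not None:
        doc["template"] = [
            {
                "role": s.role,
                **({"factor": s.factor} if s.factor is not None else {}),
                **(
                    {"gene_position": s.gene_position}
                    if s.gene_position is not None
                    else {}
                ),
                **({"part": s.part} if s.part is not None else {}),
                **({"optional": True} if s.optional else {}),
            }
            for s in space.template
        ]
    return doc


def save_design_space(space: DesignSpace, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_space_to_dict(space), fh, sort_keys=False)


def load_design_space(path) -> DesignSpace:
    """Load a design template: factors, gene-order factor, construct slots."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    factors = tuple(
        Factor(
            name=f["name"],
            levels=tuple(f["levels"]),
            kind=f.get("kind", "categorical"),
            ordinal_rank=tuple(f["ordinal_rank"]) if "ordinal_rank" in f else None,
        )
        for f in doc.get("factors", [])
    )
    order = None
    if "gene_order" in doc:
        g = doc["gene_order"]
        order = GeneOrderFactor(
            genes=tuple(g["genes"]),
            mode=g.get("mode", "all_permutations"),
            fixed=g.get("fixed", {}),
            explicit=tuple(tuple(o) for o in g["explicit"])
            if "explicit" in g
            else None,
        )
    template: Optional[ConstructTemplate] = None
    if "template" in doc:
        template = ConstructTemplate(
            tuple(
                Slot(
                    role=s["role"],
                    factor=s.get("factor"),
                    gene_position=s.get("gene_position"),
                    part=s.get("part"),
                    optional=s.get("optional", False),
                )
                for s in doc["template"]
            )
        )
    return DesignSpace(factors=factors, order_factor=order, template=template)


def save_constraints(constraints: ConstraintSet, path) -> None:
    doc: dict = {}
    if constraints.fixed_levels:
        doc["fixed_levels"] = dict(constraints.fixed_levels)
    if constraints.allowed_levels:
        doc["allowed_levels"] = {
            k: list(v) for k, v in constraints.allowed_levels.items()
        }
    if constraints.fixed_positions:
        doc["fixed_positions"] = dict(constraints.fixed_positions)
    if constraints.allowed_orderings is not None:
        doc["allowed_orderings"] = [list(o) for o in constraints.allowed_orderings]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_constraints(path) -> ConstraintSet:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return ConstraintSet(
        fixed_levels=doc.get("fixed_levels", {}),
        allowed_levels={
            k: tuple(v) for k, v in doc.get("allowed_levels", {}).items()
        },
        fixed_positions=doc.get("fixed_positions", {}),
        allowed_orderings=tuple(tuple(o) for o in doc["allowed_orderings"])
        if "allowed_orderings" in doc
        else None,
    )
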
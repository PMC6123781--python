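"""Ready-made design spaces for the shipped pathway case studies.

Two four-enzyme pathways are bundled as worked examples: the flavonoid
(2S)-pinocembrin pathway (PAL, 4CL, CHS, CHI) and the benzylisoquinoline
alkaloid reticuline/scoulerine pathway (6OMT, CNMT, 4OMT, BBE).  Both use
the same construct architecture — a vector backbone carrying the first
promoter, four genes in variable order, and an optional promoter at each
of the three intergenic slots — giving a 4 x 3 x 3 x 3 x 24 = 2592-point
first-round space.

Two complementary factor views are provided.  The *slot view* is what gets
built: one composite 4-level backbone factor (origin x first promoter) and
one promoter factor per intergenic slot.  The *gene view* re-expresses a
built library for analysis: an ordinal copy-number factor plus one
promoter factor per gene (the promoter physically upstream of that gene,
wherever the gene landed), which is the natural frame for effect
interpretation and for rule propagation into the next round.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .construct_builder import ConstructTemplate, operon_template
from .design_space import (
    CATEGORICAL,
    ORDINAL,
    ConstraintSet,
    DesignPoint,
    DesignSpace,
    Factor,
    GeneOrderFactor,
)
from .doe import Library
from .learn import RulePolicy
from .synthetic import GroundTruth

__all__ = [
    "PROMOTERS",
    "NONE",
    "pinocembrin_round1_space",
    "alkaloid_space",
    "chassis_crossed_space",
    "round2_constraints",
    "gene_view_factors",
    "to_gene_view",
    "gene_view_candidate_space",
    "pinocembrin_rule_policy",
    "pinocembrin_ground_truth",
]

NONE = "none"
WEAK = "P_lacUV5"
STRONG = "P_trc"
PROMOTERS = (NONE, WEAK, STRONG)

PINOCEMBRIN_GENES = ("PAL", "4CL", "CHS", "CHI")
ALKALOID_GENES = ("6OMT", "CNMT", "4OMT", "BBE")


def _four_gene_space(
    genes: Sequence[str], origins: Tuple[str, str]
) -> DesignSpace:
    """Backbone (origin x first promoter) + 3 intergenic slots + gene order."""
    low, high = origins
    backbone = Factor(
        "backbone",
        (
            f"{low}-{WEAK}",
            f"{low}-{STRONG}",
            f"{high}-{WEAK}",
            f"{high}-{STRONG}",
        ),
        kind=CATEGORICAL,
    )
    slots = [
        Factor(f"promoter_slot_{pos}", PROMOTERS, kind=CATEGORICAL)
        for pos in (1, 2, 3)
    ]
    template = operon_template(
        n_genes=len(genes),
        backbone_factor="backbone",
        promoter_factor_fmt="promoter_slot_{pos}",
        first_promoter_in_backbone=True,
    )
    return DesignSpace(
        factors=(backbone, *slots),
        order_factor=GeneOrderFactor(tuple(genes)),
        template=template,
    )


def pinocembrin_round1_space() -> DesignSpace:
    """First-round flavonoid space: 4 x 3 x 3 x 3 x 24 = 2592 configurations.

    Four expression levels by backbone selection (pSC101/p15a origin, each
    paired with the weak P_lacUV5 or strong P_trc first promoter), a
    no/weak/strong promoter at each intergenic slot, and all 24 orderings
    of PAL, 4CL, CHS, CHI.
    """
    return _four_gene_space(PINOCEMBRIN_GENES, ("pSC101", "p15a"))


def alkaloid_space() -> DesignSpace:
    """Alkaloid pathway space, same slot structure over pBBR1/ColE1 origins."""
    return _four_gene_space(ALKALOID_GENES, ("pBBR1", "ColE1"))


def chassis_crossed_space(n_strains: int = 9) -> DesignSpace:
    """Round-1 space crossed with a chassis-strain factor (default 9 strains).

    2592 x 9 = 23328 configurations: the count of distinct pathway-design x
    host combinations a full screening campaign would face.
    """
    base = pinocembrin_round1_space()
    chassis = Factor(
        "chassis", tuple(f"strain_{i + 1}" for i in range(n_strains))
    )
    return DesignSpace(
        factors=(*base.factors, chassis),
        order_factor=base.order_factor,
        template=base.template,
    )


def round2_constraints(backbone_level: Optional[str] = None) -> ConstraintSet:
    """The focused round-2 rules on the slot-view round-1 space.

    Encodes the learned design rules: one backbone for all constructs, CHI
    fixed at the operon front (directly downstream of the backbone
    promoter), PAL parked at the 3' end, 4CL and CHS free to swap in the
    middle with full promoter menus, and the final intergenic slot (in
    front of the last gene, PAL) reduced to a two-level presence menu.
    Restricting the 2592-point space this way leaves the 2 x 3 x 3 x 2 =
    36-construct full factorial of the second round.
    """
    backbone_level = backbone_level or f"p15a-{STRONG}"
    return ConstraintSet(
        fixed_levels={"backbone": backbone_level},
        allowed_levels={"promoter_slot_3": (NONE, STRONG)},
        fixed_positions={"CHI": 0, "PAL": 3},
    )


# ---------------------------------------------------------------------------
# Gene view: recode a slot-view library for analysis


_COPY_RANK = {"pSC101": 0, "p15a": 1, "pBBR1": 0, "ColE1": 2}


def gene_view_factors(
    genes: Sequence[str], copy_levels: Sequence[str]
) -> Tuple[Factor, ...]:
    copy_number = Factor(
        "copy_number",
        tuple(copy_levels),
        kind=ORDINAL,
        ordinal_rank=tuple(_COPY_RANK.get(lv, i) for i, lv in enumerate(copy_levels)),
    )
    promoters = tuple(
        Factor(f"promoter_{g}", PROMOTERS, kind=CATEGORICAL) for g in genes
    )
    return (copy_number, *promoters)


def to_gene_view(library: Library) -> Library:
    """Re-express a slot-view library per gene: copy number + gene promoters.

    The backbone level ``origin-promoter`` splits into the ordinal
    ``copy_number`` (the origin) and the promoter of whichever gene sits at
    position 0; the promoter of the gene at position j > 0 is the level of
    intergenic slot j.  Orderings are preserved.
    """
    if library.space is None:
        raise ValueError("library carries no space to recode")
    genes = library.space.order_factor.genes
    origins: List[str] = []
    points = []
    for p in library.points:
        origin, first_prom = p.assignment["backbone"].split("-", 1)
        if origin not in origins:
            origins.append(origin)
        assignment = {"copy_number": origin}
        for j, gene in enumerate(p.ordering):
            level = first_prom if j == 0 else p.assignment[f"promoter_slot_{j}"]
            assignment[f"promoter_{gene}"] = level
        points.append(
            DesignPoint(assignment=assignment, ordering=p.ordering, id=p.id)
        )
    copy_levels = sorted(origins, key=lambda o: _COPY_RANK.get(o, 99))
    space = DesignSpace(
        factors=gene_view_factors(genes, copy_levels),
        order_factor=GeneOrderFactor(genes),
    )
    return Library(
        points=tuple(points),
        provenance=library.provenance + "+gene_view",
        compression_ratio=library.compression_ratio,
        space=space,
    )


def gene_view_candidate_space(
    genes: Sequence[str] = PINOCEMBRIN_GENES,
    copy_levels: Sequence[str] = ("pSC101", "p15a", "ColE1"),
) -> DesignSpace:
    """Next-round candidate space in the gene view.

    The copy-number menu is extended to the high-copy ColE1 origin — the
    redesign is allowed to go beyond the levels screened in round 1, which
    is exactly what the beneficial-extreme rule exploits.
    """
    return DesignSpace(
        factors=gene_view_factors(genes, copy_levels),
        order_factor=GeneOrderFactor(tuple(genes)),
    )


def pinocembrin_rule_policy(alpha: float = 0.05) -> RulePolicy:
    """Rule policy for the flavonoid case.

    PAL is flagged non-limiting by the accumulated upstream intermediate
    (cinnamic acid is high in every construct, so PAL expression is not the
    bottleneck even where its promoter tests significant).
    """
    return RulePolicy(
        alpha=alpha,
        none_level=NONE,
        promoter_gene_map={f"promoter_{g}": g for g in PINOCEMBRIN_GENES},
        nonlimiting_genes=("PAL",),
    )


def pinocembrin_ground_truth(
    seed: int,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
) -> GroundTruth:
    """Plausible planted effect structure for the flavonoid simulations.

    Gene-view effects on log10 titer: copy number is the dominant positive
    ordinal effect (high-copy ColE1 best), the CHI promoter the strongest
    promoter effect, CHS and 4CL intermediate, PAL negligible (its product
    accumulates regardless).  Baseline and spans put round-1 titers in the
    1e-3 to 1e-1 mg/L decade range.
    """
    return GroundTruth(
        baseline=-1.9,
        effects={
            "copy_number": {"pSC101": -0.45, "p15a": 0.0, "ColE1": 0.9},
            "promoter_CHI": {NONE: -0.55, WEAK: 0.15, STRONG: 0.4},
            "promoter_CHS": {NONE: -0.25, WEAK: 0.05, STRONG: 0.2},
            "promoter_4CL": {NONE: -0.2, WEAK: 0.05, STRONG: 0.15},
            "promoter_PAL": {NONE: 0.0, WEAK: 0.0, STRONG: 0.05},
        },
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        seed=seed,
    )
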
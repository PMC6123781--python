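"""Combinatorial pathway design spaces.

A design space couples a set of discrete factors (promoter choice per
intergenic slot, vector backbone, chassis strain, ...) with a gene-order
factor describing how the pathway genes may be permuted within the
construct.  The full factorial cardinality is the product of the factor
level counts times the number of admissible gene orderings; the point of
the downstream DoE machinery is that this space is counted and constrained
symbolically and only materialized when small enough to build.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "CATEGORICAL",
    "ORDINAL",
    "Factor",
    "GeneOrderFactor",
    "DesignSpace",
    "DesignPoint",
    "ConstraintSet",
    "DesignSpaceError",
    "ConstraintError",
    "count_designs",
    "enumerate_designs",
    "apply_constraints",
]

CATEGORICAL = "categorical"
ORDINAL = "ordinal"

#: Default cap on materialization; larger spaces must be reduced by DoE first.
DEFAULT_ENUMERATION_CAP = 10**6


class DesignSpaceError(ValueError):
    """Raised for structurally invalid spaces, factors, or design points."""


class ConstraintError(DesignSpaceError):
    """Raised when a constraint set is inapplicable or contradictory."""


@dataclass(frozen=True)
class Factor:
    """A discrete design factor.

    Parameters
    ----------
    name:
        Identifier, unique within a space.
    levels:
        Ordered level labels.  For part-typed factors the labels double as
        part registry IDs (``"none"`` conventionally marks an omitted part).
    kind:
        ``"categorical"`` or ``"ordinal"``.  Ordinal factors (e.g. plasmid
        copy number low < medium < high) carry a total order used by the
        Learn stage to estimate a direction of effect.
    ordinal_rank:
        Optional integer rank per level; defaults to the declaration index
        for ordinal factors.
    """

    name: str
    levels: Tuple[str, ...]
    kind: str = CATEGORICAL
    ordinal_rank: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if not self.name:
            raise DesignSpaceError("factor name must be non-empty")
        if self.kind not in (CATEGORICAL, ORDINAL):
            raise DesignSpaceError(f"unknown factor kind {self.kind!r}")
        if len(self.levels) == 0:
            raise DesignSpaceError(
                f"factor {self.name!r} has no levels: degenerate design space"
            )
        if len(set(self.levels)) != len(self.levels):
            raise DesignSpaceError(f"factor {self.name!r} has duplicate levels")
        if self.ordinal_rank is not None:
            object.__setattr__(self, "ordinal_rank", tuple(self.ordinal_rank))
            if len(self.ordinal_rank) != len(self.levels):
                raise DesignSpaceError(
                    f"factor {self.name!r}: ordinal_rank length mismatch"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def rank_of(self, level: str) -> int:
        """Ordinal rank of a level (declaration index if ranks unset)."""
        idx = self.levels.index(level)
        return self.ordinal_rank[idx] if self.ordinal_rank is not None else idx

    def restrict(self, allowed: Sequence[str]) -> "Factor":
        """New factor keeping only ``allowed`` levels, in declared order."""
        allowed_set = set(allowed)
        unknown = allowed_set - set(self.levels)
        if unknown:
            raise ConstraintError(
                f"factor {self.name!r}: unknown levels {sorted(unknown)}"
            )
        keep = [i for i, lv in enumerate(self.levels) if lv in allowed_set]
        if not keep:
            raise ConstraintError(
                f"factor {self.name!r}: constraint leaves no admissible level"
            )
        ranks = (
            tuple(self.ordinal_rank[i] for i in keep)
            if self.ordinal_rank is not None
            else None
        )
        return Factor(
            self.name,
            tuple(self.levels[i] for i in keep),
            kind=self.kind,
            ordinal_rank=ranks,
        )


ALL_PERMUTATIONS = "all_permutations"
LATIN_SQUARE = "latin_square"
FIXED_POSITIONS = "fixed_positions"


@dataclass(frozen=True)
class GeneOrderFactor:
    """Positional arrangement of the pathway genes.

    Modes
    -----
    ``all_permutations``
        Every permutation of the genes not pinned by ``fixed`` (n! over the
        unfixed genes; 24 orderings for four free genes).
    ``latin_square``
        The n orderings given by the rows of the cyclic n x n Latin square,
        in which every gene occupies every position exactly once across the
        set — the positional-balance reduction from n! to n.
    ``fixed_positions``
        A single ordering, fully specified by ``fixed``.

    ``explicit`` (set by constraint application) overrides the mode with a
    literal list of admissible orderings.
    """

    genes: Tuple[str, ...]
    mode: str = ALL_PERMUTATIONS
    fixed: Mapping[str, int] = field(default_factory=dict)  # gene -> position
    explicit: Optional[Tuple[Tuple[str, ...], ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "fixed", dict(self.fixed))
        if len(set(self.genes)) != len(self.genes):
            raise DesignSpaceError("gene identifiers must be unique")
        if not self.genes:
            raise DesignSpaceError("gene-order factor needs at least one gene")
        if self.mode not in (ALL_PERMUTATIONS, LATIN_SQUARE, FIXED_POSITIONS):
            raise DesignSpaceError(f"unknown gene-order mode {self.mode!r}")
        n = len(self.genes)
        for gene, pos in self.fixed.items():
            if gene not in self.genes:
                raise DesignSpaceError(f"fixed position for unknown gene {gene!r}")
            if not (0 <= pos < n):
                raise DesignSpaceError(
                    f"fixed position {pos} for gene {gene!r} out of range 0..{n - 1}"
                )
        if len(set(self.fixed.values())) != len(self.fixed):
            raise DesignSpaceError("two genes fixed to the same position")
        if self.mode == FIXED_POSITIONS and len(self.fixed) != n:
            raise DesignSpaceError("fixed_positions mode requires every gene pinned")
        if self.explicit is not None:
            object.__setattr__(
                self, "explicit", tuple(tuple(o) for o in self.explicit)
            )
            for o in self.explicit:
                if sorted(o) != sorted(self.genes):
                    raise DesignSpaceError(
                        f"explicit ordering {o!r} is not a permutation of the genes"
                    )
            if not self.explicit:
                raise ConstraintError("explicit ordering list is empty")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def n_orderings(self) -> int:
        """Number of admissible orderings, computed without materialization."""
        if self.explicit is not None:
            return len(self.explicit)
        if self.mode == FIXED_POSITIONS:
            return 1
        if self.mode == LATIN_SQUARE:
            return self.n_genes
        return math.factorial(self.n_genes - len(self.fixed))

    def orderings(self) -> Iterator[Tuple[str, ...]]:
        """Yield admissible orderings in deterministic order."""
        if self.explicit is not None:
            yield from self.explicit
            return
        if self.mode == LATIN_SQUARE:
            n = self.n_genes
            for i in range(n):
                yield tuple(self.genes[(i + j) % n] for j in range(n))
            return
        n = self.n_genes
        free_positions = [p for p in range(n) if p not in self.fixed.values()]
        free_genes = [g for g in self.genes if g not in self.fixed]
        base: list = [None] * n
        for gene, pos in self.fixed.items():
            base[pos] = gene
        for perm in itertools.permutations(free_genes):
            out = list(base)
            for pos, gene in zip(free_positions, perm):
                out[pos] = gene
            yield tuple(out)

    def with_fixed(self, extra: Mapping[str, int]) -> "GeneOrderFactor":
        merged = dict(self.fixed)
        for gene, pos in extra.items():
            if gene in merged and merged[gene] != pos:
                raise ConstraintError(
                    f"gene {gene!r} already fixed at {merged[gene]}, cannot fix at {pos}"
                )
            merged[gene] = pos
        mode = self.mode
        if mode != LATIN_SQUARE and len(merged) == self.n_genes:
            mode = FIXED_POSITIONS
        return GeneOrderFactor(self.genes, mode=mode, fixed=merged,
                               explicit=self.explicit)


@dataclass(frozen=True)
class DesignPoint:
    """One construct design: a level per factor plus a gene ordering.

    The ID is a canonical-serialization hash, so identical designs receive
    identical IDs across runs and machines.
    """

    assignment: Mapping[str, str]
    ordering: Tuple[str, ...]
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        object.__setattr__(self, "ordering", tuple(self.ordering))
        if not self.id:
            object.__setattr__(self, "id", self._derive_id())

    def _derive_id(self) -> str:
        canonical = ";".join(
            f"{k}={self.assignment[k]}" for k in sorted(self.assignment)
        )
        canonical += "|" + ",".join(self.ordering)
        return "D" + hashlib.sha1(canonical.encode()).hexdigest()[:10]

    def level(self, factor: str) -> str:
        return self.assignment[factor]

    def position_of(self, gene: str) -> int:
        return self.ordering.index(gene)


@dataclass(frozen=True)
class ConstraintSet:
    """Design rules expressed as restrictions of a space.

    ``fixed_levels`` pins a factor to one level, ``allowed_levels`` trims a
    factor's menu, ``fixed_positions`` pins genes to construct positions and
    ``allowed_orderings`` whitelists gene orderings outright.  An empty
    constraint set is the identity.
    """

    fixed_levels: Mapping[str, str] = field(default_factory=dict)
    allowed_levels: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)
    fixed_positions: Mapping[str, int] = field(default_factory=dict)
    allowed_orderings: Optional[Tuple[Tuple[str, ...], ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_levels", dict(self.fixed_levels))
        object.__setattr__(
            self,
            "allowed_levels",
            {k: tuple(v) for k, v in dict(self.allowed_levels).items()},
        )
        object.__setattr__(self, "fixed_positions", dict(self.fixed_positions))
        if self.allowed_orderings is not None:
            object.__setattr__(
                self,
                "allowed_orderings",
                tuple(tuple(o) for o in self.allowed_orderings),
            )
        for fac, levels in self.allowed_levels.items():
            if len(levels) == 0:
                raise ConstraintError(f"allowed_levels for {fac!r} is empty")

    def is_empty(self) -> bool:
        return (
            not self.fixed_levels
            and not self.allowed_levels
            and not self.fixed_positions
            and self.allowed_orderings is None
        )

    def satisfied_by(self, point: DesignPoint) -> bool:
        for fac, level in self.fixed_levels.items():
            if point.assignment.get(fac) != level:
                return False
        for fac, levels in self.allowed_levels.items():
            if point.assignment.get(fac) not in levels:
                return False
        for gene, pos in self.fixed_positions.items():
            if gene not in point.ordering or point.position_of(gene) != pos:
                return False
        if self.allowed_orderings is not None:
            if tuple(point.ordering) not in self.allowed_orderings:
                return False
        return True


@dataclass(frozen=True)
class DesignSpace:
    """Factors + gene-order factor (+ optional construct template).

    The template (see :mod:`dbtlkit.construct_builder`) links factor levels
    to physical part slots; it is carried along but not needed for counting
    or enumeration.
    """

    factors: Tuple[Factor, ...]
    order_factor: Optional[GeneOrderFactor] = None
    template: Optional[object] = None  # ConstructTemplate; untyped to avoid cycle

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if len(self.factors) == 0 and self.order_factor is None:
            raise DesignSpaceError("design space has no factors")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise DesignSpaceError("duplicate factor names")

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def factor_names(self) -> Tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def count(self) -> int:
        n = 1
        for f in self.factors:
            n *= f.n_levels
        if self.order_factor is not None:
            n *= self.order_factor.n_orderings()
        return n

    def enumerate(self, cap: int = DEFAULT_ENUMERATION_CAP) -> Iterator[DesignPoint]:
        total = self.count()
        if total > cap:
            raise DesignSpaceError(
                f"space has {total} points, above the materialization cap {cap}; "
                "reduce it first (orthogonal array / fractional factorial)"
            )
        level_axes = [f.levels for f in self.factors]
        orderings: Iterable[Tuple[str, ...]] = (
            list(self.order_factor.orderings()) if self.order_factor else [()]
        )
        for combo in itertools.product(*level_axes):
            assignment = dict(zip(self.factor_names, combo))
            for ordering in orderings:
                yield DesignPoint(assignment=assignment, ordering=ordering)

    def contains(self, point: DesignPoint) -> bool:
        if set(point.assignment) != set(self.factor_names):
            return False
        for f in self.factors:
            if point.assignment[f.name] not in f.levels:
                return False
        if self.order_factor is None:
            return point.ordering == ()
        if sorted(point.ordering) != sorted(self.order_factor.genes):
            return False
        # membership in the admissible ordering set
        if self.order_factor.explicit is not None:
            return tuple(point.ordering) in self.order_factor.explicit
        if self.order_factor.mode == LATIN_SQUARE:
            return tuple(point.ordering) in set(self.order_factor.orderings())
        for gene, pos in self.order_factor.fixed.items():
            if point.ordering[pos] != gene:
                return False
        return True

    def constrain(self, constraints: ConstraintSet) -> "DesignSpace":
        return apply_constraints(self, constraints)


def count_designs(space: DesignSpace) -> int:
    """Cardinality of the full factorial, computed symbolically.

    Never materializes design points, so chassis-crossed spaces with tens of
    thousands of configurations count in microseconds.
    """
    return space.count()


def enumerate_designs(
    space: DesignSpace, cap: int = DEFAULT_ENUMERATION_CAP
) -> Iterator[DesignPoint]:
    """Stream every design point exactly once.

    Order is deterministic and lexicographic: factor levels vary in
    declaration order (slowest first), gene orderings innermost.
    """
    return space.enumerate(cap=cap)


def apply_constraints(space: DesignSpace, constraints: ConstraintSet) -> DesignSpace:
    """Restrict a space by a constraint set, returning a new space.

    The returned space enumerates exactly the points of ``space`` satisfying
    the constraints.  Contradictory constraints (an empty result) raise
    :class:`ConstraintError` rather than silently producing a null space.
    """
    known = set(space.factor_names)
    for fac in list(constraints.fixed_levels) + list(constraints.allowed_levels):
        if fac not in known:
            raise ConstraintError(f"constraint references unknown factor {fac!r}")

    new_factors = []
    for f in space.factors:
        if f.name in constraints.fixed_levels:
            level = constraints.fixed_levels[f.name]
            allowed = [level]
            if f.name in constraints.allowed_levels and (
                level not in constraints.allowed_levels[f.name]
            ):
                raise ConstraintError(
                    f"factor {f.name!r}: fixed level {level!r} excluded by "
                    "allowed_levels — contradictory constraints"
                )
        elif f.name in constraints.allowed_levels:
            allowed = list(constraints.allowed_levels[f.name])
        else:
            new_factors.append(f)
            continue
        new_factors.append(f.restrict(allowed))

    order = space.order_factor
    if order is not None:
        for gene in constraints.fixed_positions:
            if gene not in order.genes:
                raise ConstraintError(f"constraint references unknown gene {gene!r}")
        if constraints.allowed_orderings is not None:
            admissible = [
                o
                for o in constraints.allowed_orderings
                if all(
                    o[pos] == gene
                    for gene, pos in constraints.fixed_positions.items()
                )
            ]
            # intersect with what the current space already admits
            probe = GeneOrderFactor(order.genes, mode=order.mode,
                                    fixed=order.fixed, explicit=order.explicit)
            current = set(probe.orderings())
            admissible = [o for o in admissible if tuple(o) in current]
            if not admissible:
                raise ConstraintError(
                    "ordering constraints admit no gene ordering — "
                    "contradictory constraints"
                )
            order = GeneOrderFactor(order.genes, mode=order.mode,
                                    explicit=tuple(tuple(o) for o in admissible))
        elif constraints.fixed_positions:
            if order.explicit is not None or order.mode == LATIN_SQUARE:
                admissible = [
                    o
                    for o in order.orderings()
                    if all(
                        o[pos] == gene
                        for gene, pos in constraints.fixed_positions.items()
                    )
                ]
                if not admissible:
                    raise ConstraintError(
                        "position constraints admit no gene ordering"
                    )
                order = GeneOrderFactor(order.genes, mode=order.mode,
                                        explicit=tuple(admissible))
            else:
                order = order.with_fixed(constraints.fixed_positions)
    elif constraints.fixed_positions or constraints.allowed_orderings is not None:
        raise ConstraintError("space has no gene-order factor to constrain")

    new_space = DesignSpace(tuple(new_factors), order, space.template)
    if new_space.count() == 0:
        raise ConstraintError("constraints produce an empty design space")
    return new_space
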
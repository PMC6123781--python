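"""Design-of-experiments reduction of combinatorial pathway libraries.

The central object is a strength-2 mixed-level orthogonal array: a runs x
factors level matrix in which every ordered pair of columns contains every
level pair equally often, so all main effects are estimable without
confounding.  The 16-run array over five 4-level columns is built from the
finite field GF(4) (runs are the points of GF(4)^2, columns the five
distinct lines u*a + v*b), four-level columns are collapsed onto three- or
two-level factors (e.g. {none, none, weak-promoter, strong-promoter}), and
a cyclic Latin square turns the gene-order column into n positionally
balanced orderings out of the n! permutations.  Together these reduce a
4 x 3 x 3 x 3 x 24 = 2592-point pathway space to 16 representative
constructs, a 162:1 compression.

Regular two-level fractional factorials (defining-word construction with
alias/resolution accounting) are provided as the alternative reduction.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .design_space import (
    DesignPoint,
    DesignSpace,
    DesignSpaceError,
    Factor,
    GeneOrderFactor,
    LATIN_SQUARE,
)

__all__ = [
    "OrthogonalArray",
    "LatinSquare",
    "Library",
    "construct_oa_16_4pow5",
    "collapse_levels",
    "latin_square",
    "reduce_library",
    "fractional_factorial",
    "choose_strategy",
    "FULL_FACTORIAL",
    "ORTHOGONAL_ARRAY",
]

FULL_FACTORIAL = "full_factorial"
ORTHOGONAL_ARRAY = "orthogonal_array"


# ---------------------------------------------------------------------------
# GF(4) arithmetic.  Elements 0,1,2,3 encode 0, 1, x, x+1 with the field
# defined modulo x^2 + x + 1; addition is carry-less XOR.

_GF4_MUL = (
    (0, 0, 0, 0),
    (0, 1, 2, 3),
    (0, 2, 3, 1),
    (0, 3, 1, 2),
)


def _gf4_add(a: int, b: int) -> int:
    return a ^ b


def _gf4_mul(a: int, b: int) -> int:
    return _GF4_MUL[a][b]


@dataclass(frozen=True)
class OrthogonalArray:
    """A runs x factors level-index matrix with a strength guarantee."""

    array: np.ndarray  # shape (runs, n_columns), integer level indices
    level_counts: Tuple[int, ...]
    strength: int = 2

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=int)
        object.__setattr__(self, "array", arr)
        object.__setattr__(self, "level_counts", tuple(self.level_counts))
        if arr.ndim != 2 or arr.shape[1] != len(self.level_counts):
            raise ValueError("array shape inconsistent with level_counts")
        for j, s in enumerate(self.level_counts):
            col = arr[:, j]
            if col.min() < 0 or col.max() >= s:
                raise ValueError(f"column {j} has level indices outside [0, {s})")

    @property
    def runs(self) -> int:
        return self.array.shape[0]

    @property
    def n_columns(self) -> int:
        return self.array.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.array[:, j]

    def verify_strength2(self) -> bool:
        """Exhaustive pair-count check of the strength-2 balance property."""
        for i, j in itertools.combinations(range(self.n_columns), 2):
            si, sj = self.level_counts[i], self.level_counts[j]
            if self.runs % (si * sj) != 0:
                return False
            expected = self.runs // (si * sj)
            counts: Dict[Tuple[int, int], int] = {}
            for a, b in zip(self.array[:, i], self.array[:, j]):
                counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
            for a in range(si):
                for b in range(sj):
                    if counts.get((a, b), 0) != expected:
                        return False
        return True


def construct_oa_16_4pow5() -> OrthogonalArray:
    """The OA(16, 4^5, 2): five 4-level columns in 16 runs at strength 2.

    Finite-field construction: runs are indexed by pairs (a, b) in GF(4)^2;
    the five columns are the distinct linear forms u*a + v*b for
    (u, v) in {(1,0), (0,1), (1,1), (1,2), (1,3)} — one representative per
    line through the origin.  Any two such forms are linearly independent,
    so each of the 16 level pairs appears exactly once per column pair.
    """
    coeffs = [(1, 0), (0, 1), (1, 1), (1, 2), (1, 3)]
    rows = []
    for a in range(4):
        for b in range(4):
            rows.append(
                [_gf4_add(_gf4_mul(u, a), _gf4_mul(v, b)) for (u, v) in coeffs]
            )
    return OrthogonalArray(np.array(rows, dtype=int), level_counts=(4,) * 5)


def collapse_levels(
    oa: OrthogonalArray, column: int, collapse_map: Mapping[int, str]
) -> List[str]:
    """Map a column's level indices onto labels, merging levels.

    Collapsing is how a 4-level OA column drives a 3-level factor: two of
    the four levels map to the same label (typically the no-promoter state),
    preserving orthogonality while biasing the label balance (8/4/4 in 16
    runs).  The map must cover every level of the column.
    """
    levels_present = sorted(set(int(v) for v in oa.column(column)))
    missing = [lv for lv in levels_present if lv not in collapse_map]
    if missing:
        raise ValueError(
            f"collapse map for column {column} is missing levels {missing}"
        )
    return [collapse_map[int(v)] for v in oa.column(column)]


@dataclass(frozen=True)
class LatinSquare:
    """An n x n grid with every symbol once per row and column."""

    n: int
    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=int)
        object.__setattr__(self, "grid", grid)
        if grid.shape != (self.n, self.n):
            raise ValueError("grid shape mismatch")
        target = set(range(self.n))
        for i in range(self.n):
            if set(grid[i, :].tolist()) != target or set(grid[:, i].tolist()) != target:
                raise ValueError("not a Latin square")

    def row_ordering(self, i: int, genes: Sequence[str]) -> Tuple[str, ...]:
        """Interpret row ``i`` as a gene ordering (symbol = gene index)."""
        if len(genes) != self.n:
            raise ValueError("gene count must equal square order")
        return tuple(genes[self.grid[i, j]] for j in range(self.n))


def latin_square(n: int) -> LatinSquare:
    """The cyclic Latin square of order n: grid[i][j] = (i + j) mod n.

    Rows give n gene orderings in which every gene occupies every position
    exactly once across the set, replacing the n! permutations of the
    gene-order factor with n positionally balanced representatives.
    """
    if n < 1:
        raise ValueError("Latin square order must be >= 1")
    i = np.arange(n)
    return LatinSquare(n, (i[:, None] + i[None, :]) % n)


@dataclass(frozen=True)
class Library:
    """A reduced construct library: the set of designs to actually build."""

    points: Tuple[DesignPoint, ...]
    provenance: str
    compression_ratio: Fraction
    space: Optional[DesignSpace] = None
    resolution: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValueError("library contains duplicate design points")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def point_by_id(self, construct_id: str) -> DesignPoint:
        for p in self.points:
            if p.id == construct_id:
                return p
        raise KeyError(construct_id)

    def to_frame(self):
        """Tabular view: one row per construct, factor levels + ordering."""
        import pandas as pd

        rows = []
        for p in self.points:
            row = {"construct_id": p.id}
            row.update(p.assignment)
            if p.ordering:
                row["gene_order"] = "-".join(p.ordering)
            rows.append(row)
        return pd.DataFrame(rows)


def _collapse_map_for(factor: Factor) -> Dict[int, str]:
    """Collapse a 4-level OA column onto a factor with <= 4 levels.

    The lowest OA level indices merge onto the factor's first level:
    3 levels -> {0,1 -> L0; 2 -> L1; 3 -> L2} (two indices share the
    no-promoter state), 2 levels -> {0,1 -> L0; 2,3 -> L1}, 4 levels -> identity.
    """
    s = factor.n_levels
    if s == 4:
        return {i: factor.levels[i] for i in range(4)}
    if s == 3:
        return {0: factor.levels[0], 1: factor.levels[0],
                2: factor.levels[1], 3: factor.levels[2]}
    if s == 2:
        return {0: factor.levels[0], 1: factor.levels[0],
                2: factor.levels[1], 3: factor.levels[1]}
    if s == 1:
        return {i: factor.levels[0] for i in range(4)}
    raise DesignSpaceError(
        f"factor {factor.name!r} has {s} levels; a 4-level OA column cannot "
        "drive more than 4 levels"
    )


def reduce_library(space: DesignSpace, n_runs: int = 16) -> Library:
    """Reduce a pathway design space to an OA-guided construct library.

    OA columns are assigned to factors in declaration order; factors with
    fewer than four levels are driven through level collapsing, and the
    final column selects a row of the cyclic Latin square as the gene
    ordering.  Deterministic: no randomness anywhere.
    """
    if n_runs != 16:
        raise DesignSpaceError(
            f"no orthogonal array construction available for {n_runs} runs; "
            "only the 16-run GF(4) array is implemented"
        )
    n_factor_cols = len(space.factors)
    n_cols_needed = n_factor_cols + (1 if space.order_factor is not None else 0)
    oa = construct_oa_16_4pow5()
    if n_cols_needed > oa.n_columns:
        raise DesignSpaceError(
            f"space needs {n_cols_needed} OA columns but the 16-run array "
            f"has {oa.n_columns}"
        )

    label_columns: List[List[str]] = []
    for j, factor in enumerate(space.factors):
        label_columns.append(collapse_levels(oa, j, _collapse_map_for(factor)))

    orderings: List[Tuple[str, ...]]
    if space.order_factor is not None:
        genes = space.order_factor.genes
        n = len(genes)
        if n > 4:
            raise DesignSpaceError(
                f"gene-order factor has {n} genes; the 4-level OA column can "
                "select at most 4 Latin-square rows"
            )
        square = latin_square(n)
        order_col = oa.column(n_factor_cols)
        # collapse the 4 OA levels onto the n rows (identity when n == 4)
        orderings = [square.row_ordering(int(v) % n, genes) for v in order_col]
    else:
        orderings = [()] * oa.runs

    points = []
    seen = set()
    for r in range(oa.runs):
        assignment = {
            f.name: label_columns[j][r] for j, f in enumerate(space.factors)
        }
        point = DesignPoint(assignment=assignment, ordering=orderings[r])
        if point.id in seen:  # pragma: no cover - OA rows are distinct
            continue
        seen.add(point.id)
        points.append(point)

    for p in points:
        if not space.contains(p):
            raise DesignSpaceError(
                f"reduced point {p.id} falls outside the source space"
            )

    return Library(
        points=tuple(points),
        provenance=f"oa16_4^5+latin_square(n={space.order_factor.n_genes})"
        if space.order_factor
        else "oa16_4^5",
        compression_ratio=Fraction(space.count(), len(points)),
        space=space,
    )


# ---------------------------------------------------------------------------
# Regular two-level fractional factorials


def _parse_generator(gen: str, names: Sequence[str]) -> Tuple[str, frozenset]:
    """Parse 'D=ABC' into (new factor 'D', word frozenset {'A','B','C'})."""
    gen = gen.replace(" ", "").upper()
    if "=" not in gen:
        raise ValueError(f"generator {gen!r} must have the form 'D=ABC'")
    left, right = gen.split("=", 1)
    if len(left) != 1:
        raise ValueError(f"generator left side {left!r} must be one factor")
    word = frozenset(right)
    if not word or any(ch not in names for ch in word):
        raise ValueError(f"generator word {right!r} uses unknown factors")
    return left, word


def fractional_factorial(k: int, generators: Sequence[str]) -> Library:
    """A regular 2^(k-p) fractional factorial from defining words.

    Factors are lettered A, B, C, ...; each generator such as ``"D=AB"``
    aliases a new factor with an interaction of the base factors.  The
    defining relation is the group generated by the words ``D*AB`` etc.;
    resolution is the shortest word length in that relation.  Aliasing a
    main effect with the identity (a length-1 word) is rejected.
    """
    if k < 1 or k > 26:
        raise ValueError("k must be between 1 and 26")
    p = len(generators)
    if p >= k:
        raise ValueError("need at least one base factor (p < k)")
    names = list(string.ascii_uppercase[:k])
    generated = {}
    for gen in generators:
        left, word = _parse_generator(gen, names)
        if left not in names:
            raise ValueError(f"generator {gen!r} defines unknown factor {left!r}")
        if left in generated:
            raise ValueError(f"factor {left!r} defined by two generators")
        generated[left] = word
    base = [n for n in names if n not in generated]
    if len(base) != k - p:
        raise ValueError("generators must define exactly p distinct factors")
    for left, word in generated.items():
        if any(w in generated for w in word):
            raise ValueError(
                f"generator word for {left!r} may only use base factors"
            )

    # defining relation: group generated by the words {left} ∪ word
    gen_words = [frozenset({left}) | word for left, word in generated.items()]
    relation = {frozenset()}
    for w in gen_words:
        relation |= {r ^ w for r in relation}
    nontrivial = [w for w in relation if w]
    for w in nontrivial:
        if len(w) == 1:
            raise ValueError(
                f"main effect {sorted(w)[0]!r} is aliased with the identity"
            )
    resolution = min((len(w) for w in nontrivial), default=None)

    points = []
    for combo in itertools.product((-1, 1), repeat=len(base)):
        signs = dict(zip(base, combo))
        for left, word in generated.items():
            signs[left] = math.prod(signs[w] for w in word)
        assignment = {n: ("+" if signs[n] > 0 else "-") for n in names}
        points.append(DesignPoint(assignment=assignment, ordering=()))

    return Library(
        points=tuple(points),
        provenance=f"2^({k}-{p}) regular fraction"
        + (f", resolution {resolution}" if resolution else ""),
        compression_ratio=Fraction(2**k, 2 ** (k - p)),
        resolution=resolution,
    )


def choose_strategy(space: DesignSpace, max_build: int) -> str:
    """Full factorial if the space fits the build budget, else DoE reduction.

    Mirrors the round-2 decision: a 36-point focused space under a 48-build
    budget is assembled in full, while the 2592-point first round is
    reduced to a 16-run orthogonal-array library.
    """
    if max_build < 1:
        raise ValueError("max_build must be >= 1")
    return FULL_FACTORIAL if space.count() <= max_build else ORTHOGONAL_ARRAY
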
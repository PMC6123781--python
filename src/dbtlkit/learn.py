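"""Learn stage: factor-effect estimation and design-rule propagation.

Production titers from a screened library are modeled by ordinary least
squares with main effects only: categorical factors (promoter identity,
gene order) enter through sum-to-zero contrasts, ordinal factors (plasmid
copy number) through their integer rank.  Each factor's significance is
the F-test of zero effect from a drop-one nested model comparison.  The
default response is log10 titer, since titers in these libraries span
orders of magnitude and the effect structure is multiplicative.

Significant effects are translated into design constraints for the next
build round by an explicit rule policy: a beneficial ordinal factor is
fixed at its best extreme, the strongest promoter factor is constrained
promoter-present with its gene moved to the front of the operon (directly
downstream of a promoter), intermediate factors keep their full level
menu, and genes flagged non-limiting by an auxiliary indicator (e.g. an
accumulated upstream intermediate) are parked at the end of the operon
without a dedicated promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design_space import (
    CATEGORICAL,
    ORDINAL,
    ConstraintSet,
    DesignSpace,
    Factor,
)
from .doe import Library

__all__ = [
    "EffectTable",
    "RulePolicy",
    "LearnError",
    "load_measurements",
    "validate_measurements",
    "fit_effects",
    "rank_factors",
    "propagate_rules",
]

MEASUREMENT_COLUMNS = ("construct_id", "replicate", "titer")

GENE_ORDER_FACTOR = "gene_order"


class LearnError(ValueError):
    """Raised for unusable measurement tables or inestimable models."""


def load_measurements(source) -> pd.DataFrame:
    """Read a construct/replicate/titer CSV and validate it."""
    df = pd.read_csv(source)
    validate_measurements(df)
    return df


def validate_measurements(df: pd.DataFrame) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise LearnError(f"measurement table lacks columns {missing}")
    if (df["titer"] < 0).any():
        raise LearnError("titers must be non-negative")


@dataclass(frozen=True)
class EffectTable:
    """Fitted main effects with per-factor F tests.

    ``table`` has one row per factor: kind, numerator df, F statistic,
    p-value and (for ordinal factors) the direction of effect.  ``effects``
    maps each categorical factor to sum-to-zero level effects and each
    ordinal factor to a per-rank-unit slope.  Factors without variation in
    the library are listed with NaN statistics (inestimable, not an error).
    """

    table: pd.DataFrame
    effects: Mapping[str, Mapping[str, float]]
    r_squared: float
    df_resid: int
    response: str
    factor_order: Tuple[str, ...]

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "p_value"])

    def direction(self, factor: str) -> float:
        """Sign of an ordinal factor's slope (+1, -1, or 0)."""
        eff = self.effects[factor]
        if "slope" not in eff:
            raise KeyError(f"factor {factor!r} is not ordinal")
        return float(np.sign(eff["slope"]))

    def best_level(self, factor: str) -> str:
        """Level with the largest estimated effect."""
        eff = {k: v for k, v in self.effects[factor].items() if k != "slope"}
        return max(sorted(eff), key=lambda k: eff[k])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _encode_categorical(levels: Sequence[str], values: pd.Series) -> np.ndarray:
    """Sum-to-zero contrast columns (k levels -> k-1 columns)."""
    k = len(levels)
    X = np.zeros((len(values), k - 1))
    index = {lv: i for i, lv in enumerate(levels)}
    for row, v in enumerate(values):
        i = index[v]
        if i < k - 1:
            X[row, i] = 1.0
        else:
            X[row, :] = -1.0
    return X


def _design_blocks(
    library: Library,
    construct_ids: pd.Series,
    factors: Sequence[Factor],
    include_gene_order: bool,
) -> Tuple[Dict[str, np.ndarray], Dict[str, List[str]], Dict[str, str], int]:
    points = {p.id: p for p in library.points}
    unknown = sorted(set(construct_ids) - set(points))
    if unknown:
        raise LearnError(f"measurements reference unknown constructs {unknown}")

    blocks: Dict[str, np.ndarray] = {}
    level_lists: Dict[str, List[str]] = {}
    kinds: Dict[str, str] = {}
    n = len(construct_ids)

    for f in factors:
        observed = construct_ids.map(lambda cid: points[cid].assignment[f.name])
        present = [lv for lv in f.levels if lv in set(observed)]
        kinds[f.name] = f.kind
        level_lists[f.name] = present
        if len(present) < 2:
            continue  # constant in this library: inestimable, flagged later
        if f.kind == ORDINAL:
            ranks = observed.map(f.rank_of).to_numpy(dtype=float)
            blocks[f.name] = ranks.reshape(n, 1)
        else:
            blocks[f.name] = _encode_categorical(present, observed)

    if include_gene_order and library.points and library.points[0].ordering:
        labels = construct_ids.map(
            lambda cid: "-".join(points[cid].ordering)
        )
        present = sorted(set(labels))
        kinds[GENE_ORDER_FACTOR] = CATEGORICAL
        level_lists[GENE_ORDER_FACTOR] = present
        if len(present) >= 2:
            blocks[GENE_ORDER_FACTOR] = _encode_categorical(present, labels)
    return blocks, level_lists, kinds, n


def fit_effects(
    library: Library,
    measurements: pd.DataFrame,
    response_transform: str = "log10",
    include_gene_order: bool = True,
    factors: Optional[Sequence[Factor]] = None,
) -> EffectTable:
    """Main-effects least squares fit of titer on design factors.

    Fits replicate-level responses (default log10 titer; an offset of one
    tenth of the smallest positive titer is added only when zeros occur).
    Per-factor significance is the F test of zero effect from the drop-one
    nested model comparison.  Deterministic; raises on rank-deficient
    designs, naming the aliased factors.
    """
    validate_measurements(measurements)
    if factors is None:
        if library.space is None:
            raise LearnError("library carries no space; pass factors explicitly")
        factors = library.space.factors

    y_raw = measurements["titer"].to_numpy(dtype=float)
    if response_transform == "log10":
        eps = 0.0
        if (y_raw <= 0).any():
            positive = y_raw[y_raw > 0]
            if positive.size == 0:
                raise LearnError("all titers are zero; nothing to fit")
            eps = positive.min() / 10.0
        y = np.log10(y_raw + eps)
        response = f"log10(titer + {eps:g})" if eps else "log10(titer)"
    elif response_transform == "identity":
        y = y_raw.copy()
        response = "titer"
    else:
        raise LearnError(f"unknown response transform {response_transform!r}")

    blocks, level_lists, kinds, n = _design_blocks(
        library, measurements["construct_id"], factors, include_gene_order
    )
    block_names = list(blocks)
    X = np.hstack([np.ones((n, 1))] + [blocks[b] for b in block_names])
    n_params = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < n_params:
        aliased = [
            b
            for b in block_names
            if np.linalg.matrix_rank(
                np.hstack(
                    [np.ones((n, 1))]
                    + [blocks[o] for o in block_names if o != b]
                )
            )
            == rank
        ]
        raise LearnError(
            "design matrix is rank deficient; aliased factors: "
            + ", ".join(aliased or block_names)
        )
    df_resid = n - n_params
    if df_resid < 1:
        raise LearnError(
            f"no residual degrees of freedom ({n} observations, "
            f"{n_params} parameters)"
        )

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss_full = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - rss_full / tss if tss > 0 else 1.0

    # drop-one F tests
    rows = []
    effects: Dict[str, Dict[str, float]] = {}
    col = 1
    coef_of: Dict[str, np.ndarray] = {}
    for b in block_names:
        q = blocks[b].shape[1]
        coef_of[b] = beta[col : col + q]
        col += q
    sigma2 = rss_full / df_resid
    for name in level_lists:
        if name not in blocks:
            rows.append((name, kinds[name], 0, np.nan, np.nan))
            effects[name] = {}
            continue
        X_r = np.hstack(
            [np.ones((n, 1))] + [blocks[o] for o in block_names if o != name]
        )
        beta_r, _, _, _ = np.linalg.lstsq(X_r, y, rcond=None)
        resid_r = y - X_r @ beta_r
        rss_r = float(resid_r @ resid_r)
        q = blocks[name].shape[1]
        if sigma2 <= 0:
            # perfect fit: zero residual variance; infinite evidence if the
            # factor explains anything at all
            F = np.inf if rss_r > 1e-16 else 0.0
            p = 0.0 if rss_r > 1e-16 else 1.0
        else:
            F = ((rss_r - rss_full) / q) / sigma2
            p = float(stats.f.sf(F, q, df_resid))
        rows.append((name, kinds[name], q, float(F), p))

        if kinds[name] == ORDINAL:
            effects[name] = {"slope": float(coef_of[name][0])}
        else:
            levels = level_lists[name]
            coefs = coef_of[name]
            eff = {lv: float(c) for lv, c in zip(levels[:-1], coefs)}
            eff[levels[-1]] = float(-coefs.sum())
            effects[name] = eff

    table = pd.DataFrame(
        rows, columns=["factor", "kind", "df", "F", "p_value"]
    ).set_index("factor")
    return EffectTable(
        table=table,
        effects=effects,
        r_squared=r_squared,
        df_resid=df_resid,
        response=response,
        factor_order=tuple(level_lists),
    )


def rank_factors(effects: EffectTable) -> List[str]:
    """Factors by ascending p-value; ties (and NaNs, last) keep declaration order."""
    order = {f: i for i, f in enumerate(effects.factor_order)}
    names = list(effects.factor_order)
    return sorted(
        names,
        key=lambda f: (
            np.isnan(effects.p_value(f)),
            effects.p_value(f) if not np.isnan(effects.p_value(f)) else 0.0,
            order[f],
        ),
    )


@dataclass(frozen=True)
class RulePolicy:
    """How fitted effects become next-round design constraints.

    ``promoter_gene_map`` names the promoter factors and the gene each one
    drives; ``nonlimiting_genes`` lists genes flagged by an auxiliary
    indicator (e.g. accumulated upstream intermediate) as not limiting
    production, whose position is parked at the operon 3' end with no
    dedicated promoter.
    """

    alpha: float = 0.05
    none_level: str = "none"
    promoter_gene_map: Mapping[str, str] = field(default_factory=dict)
    nonlimiting_genes: Tuple[str, ...] = ()
    front_position: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "promoter_gene_map", dict(self.promoter_gene_map))
        object.__setattr__(self, "nonlimiting_genes", tuple(self.nonlimiting_genes))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def propagate_rules(
    effects: EffectTable,
    space: DesignSpace,
    policy: RulePolicy,
) -> ConstraintSet:
    """Translate an effect table into constraints on the next-round space.

    Rules, in order:

    a. every significant ordinal factor is fixed at the extreme level of
       ``space``'s menu in its beneficial direction (best rank for a
       positive slope);
    b. the most significant promoter factor is constrained promoter-present
       (the no-promoter level is dropped) and its gene is fixed at the
       front of the operon, directly downstream of a promoter;
    c. other promoter factors keep their full level menus — their effects
       are explored again in the focused round;
    d. non-limiting genes are fixed at the last operon position and their
       promoter factor, when present in the space, is fixed to the
       no-promoter level.

    The returned :class:`ConstraintSet` is valid against ``space``.
    """
    for fac in policy.promoter_gene_map:
        if fac not in effects.factor_order:
            raise LearnError(f"policy references unknown factor {fac!r}")

    space_names = set(space.factor_names)
    fixed_levels: Dict[str, str] = {}
    allowed_levels: Dict[str, Tuple[str, ...]] = {}
    fixed_positions: Dict[str, int] = {}

    # rule (a): ordinal factors
    for name in effects.factor_order:
        if name not in space_names:
            continue
        row_kind = effects.table.loc[name, "kind"]
        p = effects.p_value(name)
        if row_kind == ORDINAL and not np.isnan(p) and p < policy.alpha:
            direction = effects.direction(name)
            if direction == 0:
                continue
            factor = space.factor(name)
            extreme = max(factor.levels, key=factor.rank_of) if direction > 0 \
                else min(factor.levels, key=factor.rank_of)
            fixed_levels[name] = extreme

    # rules (b)/(c): promoter factors
    promoter_factors = [
        f for f in rank_factors(effects) if f in policy.promoter_gene_map
    ]
    significant = [
        f
        for f in promoter_factors
        if not np.isnan(effects.p_value(f)) and effects.p_value(f) < policy.alpha
    ]
    n_genes = space.order_factor.n_genes if space.order_factor else 0
    if significant:
        top = significant[0]
        gene = policy.promoter_gene_map[top]
        if top in space_names:
            factor = space.factor(top)
            present = tuple(
                lv for lv in factor.levels if lv != policy.none_level
            )
            if present and len(present) < factor.n_levels:
                allowed_levels[top] = present
        if space.order_factor and gene in space.order_factor.genes:
            fixed_positions[gene] = policy.front_position

    # rule (d): non-limiting genes
    for gene in policy.nonlimiting_genes:
        if space.order_factor and gene in space.order_factor.genes:
            if gene in fixed_positions:
                raise LearnError(
                    f"gene {gene!r} is both promoter-led and non-limiting"
                )
            fixed_positions[gene] = n_genes - 1
        for fac, g in policy.promoter_gene_map.items():
            if g == gene and fac in space_names:
                if policy.none_level in space.factor(fac).levels:
                    fixed_levels[fac] = policy.none_level

    return ConstraintSet(
        fixed_levels=fixed_levels,
        allowed_levels=allowed_levels,
        fixed_positions=fixed_positions,
    )
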
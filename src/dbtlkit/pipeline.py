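"""End-to-end seeded DBTL cycle on synthetic data.

Wires the full loop together: reduce the first-round combinatorial space
to a 16-construct orthogonal-array library, compile the constructs and
plan their ligase-cycling assembly, simulate a titer screen from a planted
ground truth, fit the factor effects, propagate the learned rules into a
focused second-round space, build its full factorial, and simulate the
second screen.  Everything is driven by one seed; the shipped demo writes
byte-identical artifacts for equal seeds.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .construct_builder import compile_construct, write_genbank
from .design_space import ConstraintSet, DesignSpace, apply_constraints
from .doe import (
    FULL_FACTORIAL,
    Library,
    choose_strategy,
    reduce_library,
)
from .fractions_util import ratio_str
from .learn import EffectTable, fit_effects, propagate_rules, rank_factors
from .lcr_planner import PlateLayout, generate_worklists, plan_assembly, pool_oligos
from .presets import (
    gene_view_candidate_space,
    pinocembrin_ground_truth,
    pinocembrin_round1_space,
    pinocembrin_rule_policy,
    to_gene_view,
)
from .synthetic import GroundTruth, registry_for_space, simulate_titers

__all__ = ["DbtlResult", "full_factorial_library", "run_dbtl_cycle", "run_demo"]


def full_factorial_library(space: DesignSpace, provenance: str = "full_factorial") -> Library:
    """Materialize a (small) space as a library: compression ratio 1."""
    points = tuple(space.enumerate())
    from fractions import Fraction

    return Library(
        points=points,
        provenance=provenance,
        compression_ratio=Fraction(1, 1),
        space=space,
    )


@dataclass
class DbtlResult:
    """Artifacts of one simulated DBTL cycle."""

    round1_space: DesignSpace
    round1_library: Library
    round1_measurements: pd.DataFrame
    effects: EffectTable
    constraints: ConstraintSet
    round2_space: DesignSpace
    round2_strategy: str
    round2_library: Library
    round2_measurements: pd.DataFrame

    def best_median_titer(self, round_: int) -> float:
        meas = self.round1_measurements if round_ == 1 else self.round2_measurements
        return float(meas.groupby("construct_id")["titer"].median().max())

    @property
    def improved(self) -> bool:
        """Did the focused round beat the best first-round construct?"""
        return self.best_median_titer(2) > self.best_median_titer(1)


def run_dbtl_cycle(
    seed: int,
    truth: Optional[GroundTruth] = None,
    max_build: int = 48,
    alpha: float = 0.05,
) -> DbtlResult:
    """One full Design-Build(-in-silico)-Test-Learn-redesign cycle.

    The first round reduces the 2592-point flavonoid space to a 16-run
    orthogonal-array library; the Learn stage fits gene-view effects and
    propagates rules into the candidate redesign space; the second round is
    assembled as a full factorial when it fits ``max_build``, otherwise it
    is reduced again.  Two sub-seeds (drawn from ``seed``) drive the two
    simulated screens.
    """
    rng = np.random.default_rng(seed)
    sub1, sub2 = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    space1 = pinocembrin_round1_space()
    lib1 = reduce_library(space1, n_runs=16)
    gv1 = to_gene_view(lib1)
    if truth is None:
        truth = pinocembrin_ground_truth(seed=sub1)
    else:
        truth = GroundTruth(
            baseline=truth.baseline,
            effects=truth.effects,
            noise_sd=truth.noise_sd,
            n_replicates=truth.n_replicates,
            seed=sub1,
            order_effects=truth.order_effects,
        )
    meas1 = simulate_titers(gv1, truth)

    effects = fit_effects(gv1, meas1)
    policy = pinocembrin_rule_policy(alpha=alpha)
    candidate = gene_view_candidate_space()
    constraints = propagate_rules(effects, candidate, policy)
    space2 = apply_constraints(candidate, constraints)

    strategy = choose_strategy(space2, max_build=max_build)
    if strategy == FULL_FACTORIAL:
        lib2 = full_factorial_library(space2, provenance="round2_full_factorial")
    else:
        lib2 = reduce_library(space2, n_runs=16)

    truth2 = GroundTruth(
        baseline=truth.baseline,
        effects=truth.effects,
        noise_sd=truth.noise_sd,
        n_replicates=truth.n_replicates,
        seed=sub2,
        order_effects=truth.order_effects,
    )
    meas2 = simulate_titers(lib2, truth2)

    return DbtlResult(
        round1_space=space1,
        round1_library=lib1,
        round1_measurements=meas1,
        effects=effects,
        constraints=constraints,
        round2_space=space2,
        round2_strategy=strategy,
        round2_library=lib2,
        round2_measurements=meas2,
    )


def run_demo(seed: int, out_dir: str) -> DbtlResult:
    """Run the cycle and write its artifacts under ``out_dir``.

    Writes the round-1 library table, the first construct's GenBank record,
    the deduplicated bridging-oligo order sheet, the three assembly
    worklists plus injection sequence, both measurement tables, the effect
    table and the propagated constraints.  Equal seeds yield byte-identical
    files.
    """
    os.makedirs(out_dir, exist_ok=True)
    result = run_dbtl_cycle(seed)

    result.round1_library.to_frame().to_csv(
        os.path.join(out_dir, "round1_library.csv"), index=False
    )

    space1 = result.round1_space
    registry = registry_for_space(space1, seed=seed)
    records = [
        compile_construct(p, registry, space1.template)
        for p in result.round1_library
    ]
    write_genbank(records[0], os.path.join(out_dir, "first_construct.gb"))

    plans = {r.id: plan_assembly(r) for r in records}
    pool, _usage = pool_oligos(plans)
    with open(os.path.join(out_dir, "oligo_order_sheet.csv"), "w",
              encoding="utf-8", newline="") as fh:
        fh.write("oligo_id,sequence,length_nt\n")
        for o in pool:
            seq = o.order_sequence()
            fh.write(f"{o.id},{seq},{len(seq)}\n")

    part_usage = {r.id: list(r.part_ids()) for r in records}
    reagents = list(registry.ids) + [o.id for o in pool] + ["water", "master_mix"]
    layout = PlateLayout.auto(reagents)
    worklists = generate_worklists(plans, part_usage, layout, seed=seed)
    worklists.write_dir(os.path.join(out_dir, "worklists"))

    result.round1_measurements.to_csv(
        os.path.join(out_dir, "round1_measurements.csv"), index=False
    )
    result.effects.to_frame().to_csv(os.path.join(out_dir, "effect_table.csv"))
    from .config import save_constraints

    save_constraints(result.constraints, os.path.join(out_dir, "round2_constraints.yaml"))
    result.round2_library.to_frame().to_csv(
        os.path.join(out_dir, "round2_library.csv"), index=False
    )
    result.round2_measurements.to_csv(
        os.path.join(out_dir, "round2_measurements.csv"), index=False
    )

    with open(os.path.join(out_dir, "summary.txt"), "w", encoding="utf-8") as fh:
        fh.write(
            "round1: {} constructs from {} configurations (compression {})\n".format(
                len(result.round1_library),
                result.round1_space.count(),
                ratio_str(result.round1_library.compression_ratio),
            )
        )
        fh.write(
            "round2: {} constructs ({})\n".format(
                len(result.round2_library), result.round2_strategy
            )
        )
        fh.write(
            "best median titer round1: {:.4g}\n".format(result.best_median_titer(1))
        )
        fh.write(
            "best median titer round2: {:.4g}\n".format(result.best_median_titer(2))
        )
        fh.write("factor ranking: {}\n".format(", ".join(rank_factors(result.effects))))
    return result
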
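"""Bridging-oligo design, Tm model, and worklist generation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbtlkit.construct_builder import Part, compile_construct
from dbtlkit.lcr_planner import (
    LcrPlanError,
    PlateLayout,
    TmConditions,
    design_bridge,
    generate_worklists,
    injection_sequence,
    melting_temperature,
    plan_assembly,
    pool_oligos,
    well_name,
)

# ---------------------------------------------------------------------------
# Independent oracle: direct dH/dS summation from the published unified
# nearest-neighbor table (values typed here independently of the package).

_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2), "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3), "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0), "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4), "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}


def hand_tm(seq: str, na_mM: float = 50.0, conc_nM: float = 250.0) -> float:
    """Manual nearest-neighbor Tm: sum stacks, add initiation and terminal
    penalties, entropic salt correction, concentration term."""
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dh / (ds + 1.987 * math.log(conc_nM * 1e-9)) - 273.15


DNA = st.text(alphabet="ACGT", min_size=8, max_size=40)


class TestMeltingTemperature:
    def test_twenty_mer_matches_hand_computation(self):
        """Frozen oracle value from the manual dH/dS summation."""
        seq = "AGCGTACCGGTTAGCATGCA"
        assert hand_tm(seq) == pytest.approx(60.5695, abs=1e-3)
        assert melting_temperature(seq) == pytest.approx(60.5695, abs=0.05)

    @settings(deadline=None, max_examples=50)
    @given(seq=DNA)
    def test_agrees_with_summation_oracle_everywhere(self, seq):
        assert melting_temperature(seq) == pytest.approx(hand_tm(seq), abs=0.05)

    @settings(deadline=None, max_examples=30)
    @given(seq=DNA)
    def test_reverse_complement_symmetry(self, seq):
        """The duplex is the same molecule read from the other strand."""
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[b] for b in reversed(seq))
        assert melting_temperature(rc) == pytest.approx(
            melting_temperature(seq), abs=1e-6
        )

    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temperature("G" * 10 + "C" * 10) > melting_temperature(
            "A" * 10 + "T" * 10
        )

    def test_homogeneous_extension_monotone(self):
        tms = [melting_temperature("AT" * k) for k in range(3, 12)]
        assert all(b >= a for a, b in zip(tms, tms[1:]))

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError, match="ambiguous|non-DNA"):
            melting_temperature("ACGTNACGT")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("A")


@pytest.fixture
def junction_parts():
    up = Part("up", "gene", ("ACGGT" * 40))
    down = Part("down", "gene", ("TTGCA" * 40))
    return up, down


class TestDesignBridge:
    def test_both_halves_reach_target(self, junction_parts):
        oligo = design_bridge(*junction_parts, target_tm=70.0)
        assert oligo.tm_left >= 70.0 and oligo.tm_right >= 70.0

    def test_halves_are_terminal_subsequences(self, junction_parts):
        up, down = junction_parts
        oligo = design_bridge(up, down)
        assert up.sequence.endswith(oligo.left_half)
        assert down.sequence.startswith(oligo.right_half)
        assert oligo.left_half + oligo.right_half == oligo.sequence

    def test_minimality_by_brute_force_scan(self, junction_parts):
        """No admissible shorter half exists: every candidate length below
        the chosen one (down to the 15 nt floor) misses the Tm target."""
        up, down = junction_parts
        oligo = design_bridge(up, down, target_tm=70.0, min_half=15)
        for length in range(15, len(oligo.left_half)):
            assert melting_temperature(up.sequence[-length:]) < 70.0
        for length in range(15, len(oligo.right_half)):
            assert melting_temperature(down.sequence[:length]) < 70.0

    def test_identical_context_gives_identical_oligo(self, junction_parts):
        up, down = junction_parts
        assert design_bridge(up, down) == design_bridge(up, down)

    def test_unreachable_target_names_junction(self):
        up = Part("shortA", "promoter", "AT" * 25)
        down = Part("shortB", "promoter", "TA" * 25)
        with pytest.raises(LcrPlanError, match="shortA"):
            design_bridge(up, down, target_tm=90.0, max_half=30)


class TestPlanAssembly:
    def test_five_part_plasmid_needs_five_bridges(self, round1_space, library16, registry):
        rec = next(
            compile_construct(p, registry, round1_space.template)
            for p in library16
            if len(
                compile_construct(p, registry, round1_space.template).features
            )
            == 5
        )
        oligos = plan_assembly(rec)
        assert len(oligos) == 5
        junctions = [o.junction for o in oligos]
        # closure junction present: last part bridges back to the first
        assert junctions[-1] == (rec.features[-1].part_id, rec.features[0].part_id)

    def test_all_halves_anneal_exactly(self, round1_space, library16, registry):
        rec = compile_construct(library16.points[0], registry, round1_space.template)
        parts = {f.part_id: rec.feature_sequence(f) for f in rec.features}
        for o in plan_assembly(rec):
            up, down = o.junction
            assert parts[up].endswith(o.left_half)
            assert parts[down].startswith(o.right_half)

    def test_shared_junction_pooled_once(self, round1_space, library16, registry):
        records = [
            compile_construct(p, registry, round1_space.template)
            for p in list(library16)[:6]
        ]
        plans = {r.id: plan_assembly(r) for r in records}
        pool, usage = pool_oligos(plans)
        total = sum(len(v) for v in plans.values())
        assert len(pool) < total  # shared junctions deduplicated
        assert len({o.sequence for o in pool}) == len(pool)
        # brute-force pool comparison: every used oligo id is in the pool
        ids = {o.id for o in pool}
        assert all(set(u) <= ids for u in usage.values())

    def test_single_part_record_rejected(self):
        from dbtlkit.construct_builder import Feature, PlasmidRecord

        rec = PlasmidRecord(
            id="solo", sequence="ACGT" * 30, features=(Feature("bb", "backbone", 0, 120),)
        )
        with pytest.raises(LcrPlanError, match="at least two"):
            plan_assembly(rec)


class TestWorklists:
    @pytest.fixture
    def full_plan(self, round1_space, library16, registry):
        records = [
            compile_construct(p, registry, round1_space.template) for p in library16
        ]
        plans = {r.id: plan_assembly(r) for r in records}
        part_usage = {r.id: list(r.part_ids()) for r in records}
        pool, _ = pool_oligos(plans)
        layout = PlateLayout.auto(
            list(registry.ids) + [o.id for o in pool] + ["water", "master_mix"]
        )
        return plans, part_usage, layout

    def test_sixteen_destinations_each_served_once(self, full_plan):
        """Brute-force audit: every construct's LCR well receives each of its
        parts exactly once, its oligo pool once, and a master-mix top-up."""
        plans, part_usage, layout = full_plan
        wls = generate_worklists(plans, part_usage, layout, seed=1)
        lcr = wls.lcr_setup
        dests = {r[3] for r in lcr.rows}
        assert len(dests) == 16
        by_dest = {}
        for row in lcr.rows:
            by_dest.setdefault(row[3], []).append(row[5])
        # wells are assigned row-major in sorted-construct order
        for i, cid in enumerate(sorted(plans)):
            reagents = by_dest[well_name(i)]
            # one transfer per required part instance (a promoter part may
            # legitimately appear at two junctions of the same construct)
            for pid in set(part_usage[cid]):
                assert reagents.count(pid) == part_usage[cid].count(pid)
            assert reagents.count(f"oligo_pool:{cid}") == 1
            assert reagents.count("master_mix") == 1

    def test_reaction_volume_exact(self, full_plan):
        plans, part_usage, layout = full_plan
        wls = generate_worklists(plans, part_usage, layout, seed=1,
                                 reaction_volume_ul=25.0)
        for total in wls.lcr_setup.destination_totals().values():
            assert total == pytest.approx(25.0)

    def test_same_seed_byte_identical(self, full_plan, tmp_path):
        plans, part_usage, layout = full_plan
        a = generate_worklists(plans, part_usage, layout, seed=7)
        b = generate_worklists(plans, part_usage, layout, seed=7)
        assert a.lcr_setup.to_csv() == b.lcr_setup.to_csv()
        assert a.injection_order == b.injection_order
        d1, d2 = tmp_path / "a", tmp_path / "b"
        a.write_dir(d1)
        b.write_dir(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_empty_library_valid_header_only(self):
        wls = generate_worklists({}, {}, PlateLayout({}), seed=1)
        csv = wls.lcr_setup.to_csv()
        assert csv.splitlines() == [
            "source_labware,source_well,destination_labware,destination_well,"
            "volume_ul,reagent_id"
        ]

    def test_missing_source_lists_reagents(self, full_plan):
        plans, part_usage, _ = full_plan
        with pytest.raises(LcrPlanError, match="lacks source wells"):
            generate_worklists(plans, part_usage, PlateLayout({}), seed=1)

    def test_injection_sequence_seeded_permutation(self):
        ids = [f"s{i}" for i in range(10)]
        a = injection_sequence(ids, seed=5)
        b = injection_sequence(ids, seed=5)
        c = injection_sequence(ids, seed=6)
        assert a == b
        assert sorted(a) == sorted(ids)
        assert a != c  # different seed shuffles differently

    def test_well_names_row_major(self):
        assert well_name(0) == "A1"
        assert well_name(11) == "A12"
        assert well_name(95) == "H12"
        with pytest.raises(ValueError):
            well_name(96)
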
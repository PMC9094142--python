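import math
import random

import numpy as np
import pandas as pd
import pytest

from bulkmap import simpop
from bulkmap.finemap import (
    RecombinantPlant,
    refine_interval,
    screen_recombinants,
)
from bulkmap.intervals import GenomicInterval
from bulkmap.linkage import GenotypeMatrix


def _matrix(rows, markers, positions, codings=None):
    df = pd.DataFrame(
        rows, columns=markers,
        index=pd.Index([f"p{i}" for i in range(len(rows))], name="plant_id"),
    )
    return GenotypeMatrix(
        df,
        dict(zip(markers, positions)),
        codings or {m: "codominant" for m in markers},
    )


class TestScreenRecombinants:
    def test_same_class_not_recombinant(self):
        gm = _matrix([["H", "H"], ["A", "A"], ["B", "B"]],
                     ["L", "R"], [100, 200])
        recs = screen_recombinants(gm, "L", "R", {})
        assert recs == []

    def test_class_change_is_recombinant(self):
        gm = _matrix([["A", "H"]], ["L", "R"], [100, 200])
        recs = screen_recombinants(gm, "L", "R", {"p0": "yellow"})
        assert len(recs) == 1
        assert recs[0].id == "p0"
        assert recs[0].phenotype == "yellow"

    def test_missing_at_flank_skipped(self):
        gm = _matrix([["U", "H"], ["A", "B"]], ["L", "R"], [100, 200])
        recs = screen_recombinants(gm, "L", "R", {})
        assert [r.id for r in recs] == ["p1"]

    def test_missing_flank_marker_errors(self):
        gm = _matrix([["A", "H"]], ["L", "R"], [100, 200])
        with pytest.raises(ValueError, match="not in matrix"):
            screen_recombinants(gm, "L", "X", {})

    def test_simulated_count_matches_selfing_expectation(self):
        # flanks 42.7 kb apart; recombinant class-change probability from
        # enumerating the two-locus selfing table
        genome = simpop.GenomeModel(
            "c", 1_000_000, 30.0, np.array([500_000, 542_700])
        )
        d = 42_700 / 1e6 * 30.0 / 100
        r = (1 - math.exp(-2 * d)) / 2
        q = {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2,
             (0, 1): r / 2, (1, 0): r / 2}
        p_same = 0.0
        for (a1, b1), p1 in q.items():
            for (a2, b2), p2 in q.items():
                if a1 + a2 == b1 + b2:
                    p_same += p1 * p2
        expect = 2975 * (1 - p_same)

        locus = simpop.CausalLocus(position_bp=500_000)
        parent = simpop.f1_plant(genome)
        offspring = simpop.make_f23_screen(
            [parent], 2975, genome, locus, 500_000, 542_700, rng=13
        )
        frame = simpop.genotype_matrix_frame(
            offspring, genome, [500_000, 542_700], ["L", "R"]
        )
        gm = GenotypeMatrix(frame, {"L": 500_000, "R": 542_700},
                            {"L": "codominant", "R": "codominant"})
        recs = screen_recombinants(gm, "L", "R",
                                   {p.id: p.phenotype for p in offspring})
        assert abs(len(recs) - expect) < 5 * math.sqrt(expect) + 3


def oracle_feasible_positions(
    plants, marker_positions, candidates, dominant_phenotype="black",
    recessive_hom="A",
):
    """Exhaustive enumeration oracle for substitution mapping.

    The genotype between two adjacent markers may match either neighbour
    (one unobserved crossover per gap); outside the outermost markers it
    matches the nearest marker. A locus position is feasible for a plant
    iff some admissible genotype there satisfies its phenotype constraint.
    """

    def marker_ok(g, phenotype):
        if g == "U":
            return True
        if phenotype == dominant_phenotype:
            return g != recessive_hom
        return g == recessive_hom

    feasible = []
    for p in candidates:
        ok_all = True
        for plant in plants:
            i = np.searchsorted(marker_positions, p)
            if i < len(marker_positions) and marker_positions[i] == p:
                ok = marker_ok(plant.genotypes[i], plant.phenotype)
            else:
                neighbours = []
                if i > 0:
                    neighbours.append(plant.genotypes[i - 1])
                if i < len(marker_positions):
                    neighbours.append(plant.genotypes[i])
                ok = any(marker_ok(g, plant.phenotype) for g in neighbours)
            if not ok:
                ok_all = False
                break
        if ok_all:
            feasible.append(p)
    return feasible


class TestRefineInterval:
    CURRENT = GenomicInterval("c", 1, 10_000)
    MARKERS = [1000, 2000, 3000, 4000, 5000]

    def test_zero_recombinants_unchanged(self):
        out = refine_interval([], self.MARKERS, self.CURRENT)
        assert out == self.CURRENT

    def test_recessive_plant_excludes_dominant_segments(self):
        # genotypes B,B,H,A,A at m1..m5: dominant allele present at m1-m3,
        # so the locus must lie right of m3; the bound lands at m3
        plant = RecombinantPlant("rp", ("B", "B", "H", "A", "A"), "yellow")
        out = refine_interval([plant], self.MARKERS, self.CURRENT)
        assert out.start == 3000
        assert out.end == self.CURRENT.end
        # oracle agreement: every feasible position is inside the interval
        candidates = list(range(1, 10_001, 100)) + self.MARKERS
        feasible = oracle_feasible_positions([plant], self.MARKERS,
                                             sorted(set(candidates)))
        assert feasible
        assert min(feasible) >= out.start
        assert max(feasible) <= out.end

    def test_two_plants_bracket_the_locus(self):
        yellow = RecombinantPlant("y", ("H", "H", "A", "A", "A"), "yellow")
        black = RecombinantPlant("b", ("H", "H", "H", "A", "A"), "black")
        out = refine_interval([yellow, black], self.MARKERS, self.CURRENT)
        # yellow: locus right of m2; black: locus left of m4
        assert out.start == 2000
        assert out.end == 4000

    def test_midpoint_boundary_is_tighter(self):
        plant = RecombinantPlant("rp", ("B", "B", "H", "A", "A"), "yellow")
        marker = refine_interval([plant], self.MARKERS, self.CURRENT)
        mid = refine_interval([plant], self.MARKERS, self.CURRENT,
                              boundary="midpoint")
        assert mid.start == 3500
        assert mid.length_bp < marker.length_bp

    def test_dominant_plant_het_regions_uninformative(self):
        plant = RecombinantPlant("d", ("H", "H", "H", "B", "B"), "black")
        out = refine_interval([plant], self.MARKERS, self.CURRENT)
        assert out == GenomicInterval("c", 1, 10_000)

    def test_dominant_plant_recessive_hom_excluded(self):
        plant = RecombinantPlant("d", ("A", "A", "H", "H", "H"), "black")
        out = refine_interval([plant], self.MARKERS, self.CURRENT)
        assert out.start == 2000

    def test_order_independence(self):
        plants = [
            RecombinantPlant("y", ("H", "H", "A", "A", "A"), "yellow"),
            RecombinantPlant("b", ("H", "H", "H", "A", "A"), "black"),
            RecombinantPlant("z", ("A", "H", "H", "H", "H"), "black"),
        ]
        expected = refine_interval(plants, self.MARKERS, self.CURRENT)
        rnd = random.Random(0)
        for _ in range(5):
            rnd.shuffle(plants)
            assert refine_interval(plants, self.MARKERS, self.CURRENT) == expected

    def test_monotonicity_adding_plants(self):
        plants = [
            RecombinantPlant("y", ("H", "H", "A", "A", "A"), "yellow"),
            RecombinantPlant("b", ("H", "H", "H", "A", "A"), "black"),
            RecombinantPlant("z", ("A", "A", "H", "H", "H"), "yellow"),
        ]
        widths = []
        for k in range(len(plants) + 1):
            out = refine_interval(plants[:k], self.MARKERS, self.CURRENT)
            widths.append(out.length_bp)
        assert widths == sorted(widths, reverse=True)

    def test_conflicting_plants_error(self):
        a = RecombinantPlant("a", ("A", "B", "B", "B", "B"), "yellow")
        b = RecombinantPlant("b", ("B", "B", "B", "B", "A"), "yellow")
        with pytest.raises(ValueError, match="check plants"):
            refine_interval([a, b], self.MARKERS, self.CURRENT)

    def test_plant_with_no_compatible_marker_errors(self):
        p = RecombinantPlant("x", ("H", "H", "H", "H", "B"), "yellow")
        with pytest.raises(ValueError, match="no marker position"):
            refine_interval([p], self.MARKERS, self.CURRENT)

    def test_unsorted_markers_rejected(self):
        p = RecombinantPlant("x", ("A", "A"), "yellow")
        with pytest.raises(ValueError, match="increasing"):
            refine_interval([p], [200, 100], self.CURRENT)

    def test_marker_outside_interval_rejected(self):
        p = RecombinantPlant("x", ("A", "A"), "yellow")
        with pytest.raises(ValueError, match="outside"):
            refine_interval([p], [100, 20_000], self.CURRENT)


class TestSimulatedScreens:
    def _run_screen(self, seed, n_offspring=400):
        genome = simpop.GenomeModel(
            "c", 2_000_000, 25.0, np.arange(100_000, 2_000_001, 100_000)
        )
        locus = simpop.CausalLocus(position_bp=1_000_000)
        parents = simpop.make_f2(30, genome, locus, rng=seed)
        flanks = (700_000, 1_300_000)
        offspring = simpop.make_f23_screen(
            parents, n_offspring, genome, locus, *flanks, rng=seed + 1
        )
        markers = [p for p in genome.snp_positions
                   if flanks[0] <= p <= flanks[1]]
        names = [f"m{p}" for p in markers]
        frame = simpop.genotype_matrix_frame(offspring, genome, markers, names)
        gm = GenotypeMatrix(frame, dict(zip(names, markers)),
                            {n: "codominant" for n in names})
        recs = screen_recombinants(
            gm, names[0], names[-1],
            {p.id: p.phenotype for p in offspring},
        )
        current = GenomicInterval("c", flanks[0], flanks[1])
        refined = refine_interval(recs, markers, current)
        return recs, refined, locus

    def test_containment_over_seeded_runs(self):
        for seed in range(20):
            recs, refined, locus = self._run_screen(seed * 10)
            assert refined.contains(locus.position_bp), seed

    def test_width_shrinks_with_more_recombinants(self):
        genome = simpop.GenomeModel(
            "c", 2_000_000, 25.0, np.arange(100_000, 2_000_001, 100_000)
        )
        locus = simpop.CausalLocus(position_bp=1_000_000)
        parents = simpop.make_f2(30, genome, locus, rng=99)
        flanks = (700_000, 1_300_000)
        markers = [p for p in genome.snp_positions
                   if flanks[0] <= p <= flanks[1]]
        names = [f"m{p}" for p in markers]
        current = GenomicInterval("c", *flanks)
        widths = []
        for n_off in (50, 400, 2000):
            offspring = simpop.make_f23_screen(
                parents, n_off, genome, locus, *flanks, rng=7
            )
            frame = simpop.genotype_matrix_frame(offspring, genome, markers,
                                                 names)
            gm = GenotypeMatrix(frame, dict(zip(names, markers)),
                                {n: "codominant" for n in names})
            recs = screen_recombinants(
                gm, names[0], names[-1],
                {p.id: p.phenotype for p in offspring},
            )
            widths.append(refine_interval(recs, markers, current).length_bp)
        assert widths[-1] <= widths[0]
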
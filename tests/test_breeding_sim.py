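import numpy as np
import pytest
from scipy import stats

import heterosim as hs
from heterosim.breeding_sim import (
    _self_progeny,
    population_from_dict,
    population_to_dict,
)

from conftest import build_pipeline, complementary_parents, homozygous_distinct_lines


@pytest.fixture(scope="module")
def pipe(bottleneck):
    return build_pipeline(bottleneck, levels=11)


def _founders(pipe, size, seed, line_id="line0"):
    return hs.found_population(
        pipe.evaluator, pipe.space, size, np.random.default_rng(seed), line_id=line_id
    )


def _het_individual(pipe, a_idx=0, b_idx=-1, name="het"):
    g = {l: (float(v[a_idx]), float(v[b_idx])) for l, v in pipe.space.items()}
    return hs.Individual(name, hs.Genotype(g), pipe.evaluator)


# ---------------------------------------------------------------------------
# cross
# ---------------------------------------------------------------------------


def test_cross_of_homozygous_parents_is_forced(pipe):
    a, b = complementary_parents(pipe)
    rng = np.random.default_rng(0)
    for _ in range(5):
        g = hs.cross(a, b, rng)
        for locus in g.alleles:
            assert g.alleles[locus] == (
                a.genotype.alleles[locus][0],
                b.genotype.alleles[locus][0],
            )


def test_cross_mendelian_ratios(pipe):
    het = _het_individual(pipe)
    rng = np.random.default_rng(123)
    locus = next(iter(pipe.space))
    lo, hi = pipe.space[locus][0], pipe.space[locus][-1]
    counts = {(lo, lo): 0, (lo, hi): 0, (hi, lo): 0, (hi, hi): 0}
    n = 10_000
    for _ in range(n):
        g = hs.cross(het, het, rng)
        counts[g.alleles[locus]] += 1
    p = stats.chisquare(list(counts.values())).pvalue
    assert p > 0.01
    hom = (counts[(lo, lo)] + counts[(hi, hi)]) / n
    assert hom == pytest.approx(0.5, abs=0.03)


def test_cross_determinism(pipe):
    a, b = _founders(pipe, 2, 1).individuals
    g1 = hs.cross(a, b, np.random.default_rng(99))
    g2 = hs.cross(a, b, np.random.default_rng(99))
    assert g1 == g2


def test_cross_mismatched_loci_raises(pipe):
    a = _het_individual(pipe)
    partial = dict(a.genotype.alleles)
    partial.pop(next(iter(partial)))
    b = hs.Individual("b", hs.Genotype(partial), pipe.evaluator)
    with pytest.raises(hs.StructuralError):
        hs.cross(a, b, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# truncation_select
# ---------------------------------------------------------------------------


def test_select_top_5_percent_of_500(pipe):
    pop = _founders(pipe, 500, 2)
    parents = hs.truncation_select(pop, 0.05)
    assert len(parents) == 25
    threshold = min(p.biomass_rate for p in parents)
    others = [i for i in pop if i.id not in {p.id for p in parents}]
    assert all(i.biomass_rate <= threshold + 1e-12 for i in others)


def test_select_everything_is_order_stable(pipe):
    pop = _founders(pipe, 20, 3)
    assert hs.truncation_select(pop, 1.0) == pop.individuals


def test_select_ties_broken_by_id(pipe):
    a, b = complementary_parents(pipe)
    clones = [
        hs.Individual(f"c{i}", a.genotype, pipe.evaluator) for i in (3, 1, 2, 0)
    ]
    pop = hs.Population(clones)
    picked = hs.truncation_select(pop, 0.5)
    assert [p.id for p in picked] == ["c0", "c1"]


def test_select_rejects_bad_fraction(pipe):
    with pytest.raises(hs.ConfigError):
        hs.truncation_select(_founders(pipe, 4, 4), 0.0)


# ---------------------------------------------------------------------------
# make_offspring_generation
# ---------------------------------------------------------------------------


def test_two_parents_no_selfing(pipe):
    parents = _founders(pipe, 2, 5).individuals
    pop = hs.make_offspring_generation(parents, 10, False, np.random.default_rng(0))
    ids = {parents[0].id, parents[1].id}
    for ind in pop:
        assert set(ind.parent_ids) == ids


def test_single_parent_selfing(pipe):
    parent = _founders(pipe, 1, 6).individuals[0]
    pop = hs.make_offspring_generation([parent], 8, True, np.random.default_rng(0))
    for ind in pop:
        assert ind.parent_ids == (parent.id, parent.id)
        assert ind.selfed


def test_single_parent_without_selfing_raises(pipe):
    parent = _founders(pipe, 1, 6).individuals[0]
    with pytest.raises(hs.ConfigError):
        hs.make_offspring_generation([parent], 8, False, np.random.default_rng(0))


def test_offspring_alleles_contained_in_parental_union(pipe):
    parents = _founders(pipe, 5, 7).individuals
    pop = hs.make_offspring_generation(parents, 50, False, np.random.default_rng(1))
    union = {
        locus: {v for p in parents for v in p.genotype.alleles[locus]}
        for locus in pipe.space
    }
    for ind in pop:
        for locus, values in ind.genotype.alleles.items():
            assert set(values) <= union[locus]


# ---------------------------------------------------------------------------
# run_inbreeding
# ---------------------------------------------------------------------------


def test_zero_generations_returns_founders(pipe):
    founders = _founders(pipe, 10, 8)
    config = hs.SelectionConfig(population_size=10, selection_fraction=0.5, generations=0)
    lineage = hs.run_inbreeding(founders, config, np.random.default_rng(0))
    assert lineage == [founders]


def test_inbreeding_improves_and_fixes(pipe):
    founders = _founders(pipe, 60, 9)
    config = hs.SelectionConfig(
        population_size=60, selection_fraction=0.1, generations=15
    )
    lineage = hs.run_inbreeding(founders, config, np.random.default_rng(2))
    assert len(lineage) == 16
    assert lineage[-1].mean_biomass() >= lineage[1].mean_biomass() - 1e-9
    assert lineage[-1].mean_homozygosity() > lineage[0].mean_homozygosity()


def test_inbreeding_reproducible_bit_for_bit(pipe):
    config = hs.SelectionConfig(population_size=20, selection_fraction=0.2, generations=4)
    runs = []
    for _ in range(2):
        founders = _founders(pipe, 20, 10)
        lineage = hs.run_inbreeding(founders, config, np.random.default_rng(77))
        runs.append(
            [(ind.id, ind.genotype, ind.biomass_rate) for pop in lineage for ind in pop]
        )
    assert runs[0] == runs[1]


def test_selection_config_validation():
    with pytest.raises(hs.ConfigError):
        hs.SelectionConfig(selection_fraction=0.0)
    with pytest.raises(hs.ConfigError):
        hs.SelectionConfig(population_size=10, selection_fraction=0.05)  # 1 parent


# ---------------------------------------------------------------------------
# F1 / F2 production
# ---------------------------------------------------------------------------


def test_f1_from_identical_clonal_lines_rejected(pipe):
    line_a, _ = homozygous_distinct_lines(pipe, 10, np.random.default_rng(0))
    with pytest.raises(hs.ConfigError):
        hs.produce_f1(line_a, line_a, 10, 0.3, np.random.default_rng(0))


def test_f1_of_homozygous_distinct_lines(pipe):
    line_a, line_b = homozygous_distinct_lines(pipe, 20, np.random.default_rng(0))
    f1 = hs.produce_f1(line_a, line_b, 500, 0.3, np.random.default_rng(1))
    assert len(f1) == 500
    first = f1.individuals[0].genotype
    assert all(ind.genotype == first for ind in f1)
    assert f1.mean_homozygosity() == 0.0


def test_f1_parents_within_sampled_subsets(pipe):
    line_a = _founders(pipe, 20, 11, "lineA")
    line_b = _founders(pipe, 20, 12, "lineB")
    rng = np.random.default_rng(13)
    f1 = hs.produce_f1(line_a, line_b, 100, 0.3, rng)
    ids_a = {ind.id for ind in line_a}
    ids_b = {ind.id for ind in line_b}
    used_a = {ind.parent_ids[0] for ind in f1}
    used_b = {ind.parent_ids[1] for ind in f1}
    assert used_a <= ids_a and len(used_a) <= 6  # 30% of 20
    assert used_b <= ids_b and len(used_b) <= 6


def test_f2_sizes_and_empty(pipe):
    line_a, line_b = homozygous_distinct_lines(pipe, 20, np.random.default_rng(0))
    f1 = hs.produce_f1(line_a, line_b, 50, 0.3, np.random.default_rng(2))
    assert len(hs.produce_f2(f1, 0, np.random.default_rng(3))) == 0
    f2 = hs.produce_f2(f1, 40, np.random.default_rng(3))
    assert len(f2) == 40
    assert all(ind.parent_ids[0] != ind.parent_ids[1] for ind in f2)


def test_f2_mean_biomass_below_f1_on_bottleneck(pipe):
    drops = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        a, b = complementary_parents(pipe)
        pop_a = hs.Population([a] * 10, line_id="lineA")
        pop_b = hs.Population([b] * 10, line_id="lineB")
        f1 = hs.produce_f1(pop_a, pop_b, 60, 0.3, rng)
        f2 = hs.produce_f2(f1, 60, rng)
        drops.append(f1.mean_biomass() - f2.mean_biomass())
    assert all(d > 0 for d in drops)


# ---------------------------------------------------------------------------
# pairwise_cross_schedule
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n, expected", [(2, 1), (5, 10), (40, 780)])
def test_schedule_counts(n, expected):
    ids = [f"line{i:02d}" for i in range(n)]
    schedule = hs.pairwise_cross_schedule(ids)
    assert len(schedule) == expected
    assert len(set(schedule)) == expected
    assert all(a != b for a, b in schedule)


def test_schedule_rejects_duplicates():
    with pytest.raises(hs.StructuralError):
        hs.pairwise_cross_schedule(["a", "b", "a"])


# ---------------------------------------------------------------------------
# neutral-genetics properties (no selection, lazy phenotypes)
# ---------------------------------------------------------------------------


def test_allele_frequency_expectation_conserved_under_drift(pipe):
    # random mating, fraction 1.0: frequencies drift but their mean over
    # replicates stays at the founder frequency
    locus = next(iter(pipe.space))
    target = float(pipe.space[locus][-1])

    def freq(pop):
        values = [v for ind in pop for v in ind.genotype.alleles[locus]]
        return sum(1 for v in values if v == target) / len(values)

    initial, final = [], []
    for seed in range(60):
        rng = np.random.default_rng(1000 + seed)
        pop = hs.found_population(pipe.evaluator, pipe.space, 30, rng)
        initial.append(freq(pop))
        for _ in range(3):
            parents = hs.truncation_select(pop, 1.0)
            pop = hs.make_offspring_generation(parents, 30, False, rng)
        final.append(freq(pop))
    assert np.mean(final) == pytest.approx(np.mean(initial), abs=0.02)


def test_heterozygosity_halves_under_selfing(pipe):
    def het(pop):
        return 1.0 - pop.mean_homozygosity()

    levels = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        start = _het_individual(pipe, name=f"h{seed}")
        pop = hs.Population([start])
        per_gen = [het(pop)]
        for gen in range(1, 4):
            pop = _self_progeny(pop.individuals, 200, rng, "self", gen)
            per_gen.append(het(pop))
        levels.append(per_gen)
    mean_levels = np.mean(levels, axis=0)
    assert mean_levels[0] == 1.0
    for g in (1, 2, 3):
        assert mean_levels[g] == pytest.approx(0.5 ** g, abs=0.05)


# ---------------------------------------------------------------------------
# fixation experiment
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fixation_result(pipe):
    a, b = complementary_parents(pipe)
    f1 = hs.Individual(
        "f1", hs.cross(a, b, np.random.default_rng(0)), pipe.evaluator,
        parent_ids=("parentA", "parentB"), line_id="lineAxB",
    )
    config = hs.FixationConfig(
        n_f2=120, founders_per_arm=3, population_size=40,
        selection_fraction=0.05, last_generation=7, seed=5,
    )
    return hs.fixation_experiment(f1, config)


def test_fixation_generation_bookkeeping(fixation_result):
    assert fixation_result.generation_indices == list(range(2, 8))
    for arm in ("selected", "random"):
        assert len(fixation_result.arms[arm]) == 3
        for lineage in fixation_result.arms[arm]:
            assert [p.generation_index for p in lineage] == list(range(3, 8))


def test_fixation_allele_frequencies_sum_to_one(fixation_result):
    for arm in ("selected", "random"):
        table = fixation_result.allele_frequency_table(arm)
        sums = table["freq_parent_a"] + table["freq_parent_b"]
        assert np.allclose(sums, 1.0)


def test_fixation_selected_arm_recovers_f2_depression(pipe):
    # selection under selfing pushes biomass back to (at least) the F2 mean
    gains = []
    for seed in range(5):
        a, b = complementary_parents(pipe)
        f1 = hs.Individual(
            "f1", hs.cross(a, b, np.random.default_rng(seed)), pipe.evaluator
        )
        config = hs.FixationConfig(
            n_f2=80, founders_per_arm=2, population_size=40,
            selection_fraction=0.05, last_generation=7, seed=seed,
        )
        result = hs.fixation_experiment(f1, config)
        final = np.mean(
            [lineage[-1].mean_biomass() for lineage in result.arms["selected"]]
        )
        gains.append(final - result.f2.mean_biomass())
    assert all(g >= -1e-9 for g in gains)
    assert np.mean(gains) > 0


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def test_population_json_round_trip(pipe):
    pop = _founders(pipe, 5, 20)
    restored = population_from_dict(population_to_dict(pop), pipe.evaluator)
    assert [i.id for i in restored] == [i.id for i in pop]
    assert all(
        r.genotype == o.genotype for r, o in zip(restored, pop.individuals)
    )
    assert restored.line_id == pop.line_id
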
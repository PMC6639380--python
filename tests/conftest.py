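from dataclasses import dataclass

import numpy as np
import pytest

import heterosim as hs


@dataclass
class Pipeline:
    """Model plus everything derived from it that the genetics layer needs."""

    model: hs.MetabolicModel
    rfd: hs.FluxDistribution
    envelope: hs.FluxEnvelope
    space: dict
    evaluator: hs.GenotypeEvaluator


def build_pipeline(model, fraction=0.95, levels=101) -> Pipeline:
    rfd = hs.build_reference(model)
    envelope = hs.run_fva(model, fraction)
    space = hs.build_allele_space(model, envelope, rfd, levels)
    return Pipeline(model, rfd, envelope, space, hs.GenotypeEvaluator(model, rfd))


@pytest.fixture(scope="session")
def chain3():
    return hs.make_toy_model(hs.ToySpec("chain", n_internal=1, input_bound=10))


@pytest.fixture(scope="session")
def branched():
    return hs.make_toy_model(
        hs.ToySpec("branched", capacities=(3, 5), input_bound=10)
    )


@pytest.fixture(scope="session")
def parallel55():
    return hs.make_toy_model(
        hs.ToySpec("parallel_paths", capacities=(5, 5), input_bound=10)
    )


@pytest.fixture(scope="session")
def two_route():
    # equal-capacity short (2-step) and long (3-step) routes; input is limiting
    return hs.make_toy_model(
        hs.ToySpec(
            "parallel_paths",
            capacities=(5, 5),
            path_lengths=(2, 3),
            input_bound=5,
        )
    )


@pytest.fixture(scope="session")
def futile():
    return hs.make_toy_model(
        hs.ToySpec("futile_cycle", n_internal=1, input_bound=10)
    )


@pytest.fixture(scope="session")
def bottleneck():
    return hs.make_toy_model(
        hs.ToySpec("bottleneck_pair", n_internal=4, input_bound=10)
    )


@pytest.fixture(scope="session")
def bottleneck_pipeline(bottleneck):
    return build_pipeline(bottleneck, levels=11)


def complementary_parents(pipeline: Pipeline, lo_a="R1", lo_b="R2"):
    """Two fully homozygous individuals with complementary bottlenecks:
    parent A is lowest-capacity at ``lo_a``, parent B at ``lo_b``, both are
    highest-capacity everywhere else."""
    space = pipeline.space
    ga = {
        l: ((space[l][0],) * 2 if l == lo_a else (space[l][-1],) * 2)
        for l in space
    }
    gb = {
        l: ((space[l][0],) * 2 if l == lo_b else (space[l][-1],) * 2)
        for l in space
    }
    a = hs.Individual("parentA", hs.Genotype(ga), pipeline.evaluator, line_id="lineA")
    b = hs.Individual("parentB", hs.Genotype(gb), pipeline.evaluator, line_id="lineB")
    return a, b


def homozygous_distinct_lines(pipeline: Pipeline, size: int, rng):
    """Two fully homozygous populations carrying different allele values at
    every constrained locus (clones within each line)."""
    space = pipeline.space
    for values in space.values():
        assert len(values) >= 2, "need polymorphic loci"
    ga = {l: (float(v[0]),) * 2 for l, v in space.items()}
    gb = {l: (float(v[-1]),) * 2 for l, v in space.items()}
    pops = []
    for name, g in (("lineA", ga), ("lineB", gb)):
        inds = [
            hs.Individual(f"{name}-{i}", hs.Genotype(dict(g)), pipeline.evaluator, line_id=name)
            for i in range(size)
        ]
        pops.append(hs.Population(inds, line_id=name))
    return pops[0], pops[1]
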
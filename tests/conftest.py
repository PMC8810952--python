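from __future__ import annotations

import numpy as np

from peroclock.datamodel import BetaMatrix, MethylationDataset, SampleAnnotation
from peroclock.simulate import SpeciesSpec


def make_samples(n, species="Peromyscus maniculatus", tissue="tail", ages=None, **kwargs):
    ages = ages if ages is not None else np.linspace(0.1, 3.0, n)
    return [
        SampleAnnotation(
            sample_id=f"S{i + 1:03d}",
            species=species,
            tissue=tissue,
            sex="F" if i % 2 == 0 else "M",
            age_years=float(ages[i]),
            max_lifespan_years=8.3,
            **kwargs,
        )
        for i in range(n)
    ]


def make_dataset(values, samples=None, cpg_ids=None):
    values = np.asarray(values, dtype=float)
    n_cpg, n_sample = values.shape
    cpg_ids = cpg_ids or [f"cpg{i:05d}" for i in range(n_cpg)]
    samples = samples or make_samples(n_sample)
    beta = BetaMatrix(values, cpg_ids, [s.sample_id for s in samples])
    return MethylationDataset(beta=beta, samples=samples)


def two_tissue_specs(n_per_cell=10):
    """Two species x two tissues, the layout used for clustering benchmarks."""
    return (
        SpeciesSpec(
            "Peromyscus maniculatus", 8.3,
            {"tail": n_per_cell, "brain": n_per_cell}, mating_system="polygamous",
        ),
        SpeciesSpec(
            "Peromyscus leucopus", 7.9,
            {"tail": n_per_cell, "brain": n_per_cell}, mating_system="polygamous",
        ),
    )
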
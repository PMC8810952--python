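"""Synthetic multi-species methylation datasets with known planted structure.

The generator emulates the structure of a multi-species deer-mouse methylation
array study: five *Peromyscus* species plus one interspecific hybrid, three
tissues (tail, brain, liver), two *P. maniculatus* stocks from high- and
low-altitude founder populations, both sexes, and ages spanning roughly one
month to 3.6 years — with an optional human-like stratum on the same CpGs for
dual-species clock work.

Betas are drawn on the logit scale as

    logit(beta) = mu_cpg + tissue + species + stock + sex
                  + slope * F(age) + group effects + noise

and mapped through the inverse logit, so every value lies strictly in (0, 1)
and planted effects compose additively.  Hierarchy offsets are shared within
annotation cells, which makes expected between-tissue dissimilarity exceed
between-species, between-stock and between-sex dissimilarity in that order —
the structure a correlation dendrogram of real array data shows.

Age effects enter through the same transform family the clocks regress on
(log-linear by default, or relative age for dual-species designs), so clock
recovery on simulated data is exactly learnable and tests of the transform
and of the generator stay separate.

Every random draw comes from a named substream derived from the single
config seed, so adding a contrast or an extra stratum does not shift
unrelated draws, and the same config is bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .clock import AgeTransformSpec, transform_age
from .datamodel import (
    BetaMatrix,
    MethylationDataset,
    ProbeRecord,
    REGION_CLASSES,
    SampleAnnotation,
)

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_human_stratum",
    "plant_outliers",
    "generate_gene_annotation",
    "generate_manifest",
    "generate_gene_sets",
    "study_species_specs",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent substream keyed by name; stable across unrelated config edits."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SpeciesSpec:
    """Sampling plan for one species: per-tissue counts and group labels."""

    name: str
    max_lifespan: float
    n_per_tissue: Mapping[str, int]
    stocks: tuple[tuple[str, str | None], ...] = ()  # (stock name, altitude|None)
    mating_system: str | None = None

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_tissue.values())


def study_species_specs() -> tuple[SpeciesSpec, ...]:
    """Default sampling plan mirroring the study design this generator emulates:
    tail samples for all six groups, brain and liver additionally for
    *P. leucopus* and *P. maniculatus*, and two *P. maniculatus* stocks."""
    return (
        SpeciesSpec("Peromyscus californicus", 5.5, {"tail": 16}, mating_system="monogamous"),
        SpeciesSpec("Peromyscus eremicus", 7.4, {"tail": 17}, mating_system="monogamous"),
        SpeciesSpec("Peromyscus polionotus x maniculatus", 5.5, {"tail": 6}),
        SpeciesSpec(
            "Peromyscus leucopus", 7.9, {"brain": 7, "liver": 8, "tail": 16},
            mating_system="polygamous",
        ),
        SpeciesSpec(
            "Peromyscus maniculatus", 8.3, {"brain": 12, "liver": 13, "tail": 25},
            stocks=(("BW", "low"), ("SM2", "high")),
            mating_system="polygamous",
        ),
        SpeciesSpec("Peromyscus polionotus", 5.5, {"tail": 16}, mating_system="monogamous"),
    )


def balanced_species_specs() -> tuple[SpeciesSpec, ...]:
    """A 150-sample variant of the study plan with slightly larger groups and
    no hybrid (whose n = 6 cannot be spread over ten folds); convenient for
    clock benchmarks where every stratum should survive internal CV."""
    return (
        SpeciesSpec("Peromyscus californicus", 5.5, {"tail": 18}, mating_system="monogamous"),
        SpeciesSpec("Peromyscus eremicus", 7.4, {"tail": 19}, mating_system="monogamous"),
        SpeciesSpec(
            "Peromyscus leucopus", 7.9, {"brain": 8, "liver": 9, "tail": 18},
            mating_system="polygamous",
        ),
        SpeciesSpec(
            "Peromyscus maniculatus", 8.3, {"brain": 13, "liver": 14, "tail": 28},
            stocks=(("BW", "low"), ("SM2", "high")),
            mating_system="polygamous",
        ),
        SpeciesSpec("Peromyscus polionotus", 5.5, {"tail": 23}, mating_system="monogamous"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator.

    All standard deviations are on the logit scale.  ``hierarchy_sds`` orders
    (tissue, species, stock, sex); the default (0.8, 0.4, 0.2, 0.1) with
    noise 0.2 yields tissue as the dominant clustering split.  Planted age
    CpGs get slopes ~ N(0, age_effect_sd) per unit of transformed age;
    planted group CpGs get effects ~ N(0, group_effect_sd) added to the
    positive level (monogamous / high altitude).
    """

    n_cpg: int = 2000
    species_specs: tuple[SpeciesSpec, ...] = field(default_factory=study_species_specs)
    age_range: tuple[float, float] = (0.083, 3.6)
    n_age_cpgs: int = 200
    age_effect_sd: float = 1.0
    age_effect_scale: str = "log_linear"  # or "relative"
    group_contrasts: Mapping[str, int] = field(default_factory=dict)  # field -> n CpGs
    group_effect_sd: float = 1.0
    baseline_sd: float = 1.5
    hierarchy_sds: tuple[float, float, float, float] = (0.8, 0.4, 0.2, 0.1)
    noise_sd: float = 0.2
    n_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpg <= 0:
            raise ValueError("n_cpg must be positive")
        planted = self.n_age_cpgs + sum(self.group_contrasts.values())
        if planted > self.n_cpg:
            raise ValueError(
                f"{planted} planted CpGs exceed n_cpg={self.n_cpg} (infeasible config)"
            )
        if self.n_age_cpgs < 0 or any(v < 0 for v in self.group_contrasts.values()):
            raise ValueError("planted CpG counts must be >= 0")
        if any(sd < 0 for sd in self.hierarchy_sds) or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.age_effect_scale not in ("log_linear", "relative"):
            raise ValueError("age_effect_scale must be 'log_linear' or 'relative'")
        if self.age_range[0] < 0 or self.age_range[1] < self.age_range[0]:
            raise ValueError("invalid age_range")

    @property
    def n_samples(self) -> int:
        return sum(sp.n_samples for sp in self.species_specs)


@dataclass
class GroundTruth:
    """Planted-effect registry: the oracle every recovery test checks against."""

    age_cpgs: dict[str, float]  # cpg_id -> slope (per transformed-age unit)
    age_scale: str
    group_cpgs: dict[str, dict[str, float]]  # contrast -> cpg_id -> effect
    outlier_sample_ids: list[str]
    baseline_means: dict[str, list[float]]  # "tissue|species|stock|sex" -> logit means

    def to_json(self, path: str | Path, include_baselines: bool = True) -> None:
        payload = {
            "age_cpgs": self.age_cpgs,
            "age_scale": self.age_scale,
            "group_cpgs": self.group_cpgs,
            "outlier_sample_ids": self.outlier_sample_ids,
            "baseline_means": self.baseline_means if include_baselines else {},
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            age_cpgs=dict(data["age_cpgs"]),
            age_scale=data["age_scale"],
            group_cpgs={k: dict(v) for k, v in data["group_cpgs"].items()},
            outlier_sample_ids=list(data["outlier_sample_ids"]),
            baseline_means={k: list(v) for k, v in data.get("baseline_means", {}).items()},
        )


# -- internal building blocks --------------------------------------------------

def _cpg_ids(n_cpg: int) -> list[str]:
    return [f"cpg{i:05d}" for i in range(n_cpg)]


def _age_transform_value(ages: np.ndarray, lifespans: np.ndarray, scale: str) -> np.ndarray:
    if scale == "relative":
        return ages / lifespans
    spec = AgeTransformSpec(kind="log_linear")
    return np.asarray(transform_age(ages, spec, ["x"] * len(ages)))


def _planted_effects(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    """Signed effect sizes bounded away from zero: sign * (0.5 sd + |N(0, sd)|).

    A "planted" effect of essentially zero would make recovery metrics
    (sign agreement, relative bias) meaningless, so the magnitude floor keeps
    every registered CpG genuinely affected while sd still sets the scale.
    """
    raw = rng.normal(0.0, sd, size)
    return np.sign(raw) * (0.5 * sd + np.abs(raw))


def _structural_draws(config: SimulationConfig) -> dict:
    """Draws shared between the deer and the human strata (same substreams)."""
    n = config.n_cpg
    mu = _rng(config.seed, "baseline").normal(0.0, config.baseline_sd, n)
    tissue_sd = config.hierarchy_sds[0]
    tissues = ("tail", "brain", "liver", "other")
    tissue_off = {
        t: _rng(config.seed, f"tissue/{t}").normal(0.0, tissue_sd, n) for t in tissues
    }
    perm = _rng(config.seed, "planted").permutation(n)
    age_idx = np.sort(perm[: config.n_age_cpgs])
    slopes = _planted_effects(
        _rng(config.seed, "age_slopes"), config.age_effect_sd, len(age_idx)
    )
    group_idx: dict[str, np.ndarray] = {}
    offset = config.n_age_cpgs
    for contrast in sorted(config.group_contrasts):
        k = config.group_contrasts[contrast]
        group_idx[contrast] = np.sort(perm[offset : offset + k])
        offset += k
    group_eff = {
        contrast: _planted_effects(
            _rng(config.seed, f"group_effects/{contrast}"),
            config.group_effect_sd,
            len(idx),
        )
        for contrast, idx in group_idx.items()
    }
    return {
        "mu": mu,
        "tissue_off": tissue_off,
        "age_idx": age_idx,
        "slopes": slopes,
        "group_idx": group_idx,
        "group_eff": group_eff,
    }


def _build_samples(config: SimulationConfig) -> list[SampleAnnotation]:
    samples: list[SampleAnnotation] = []
    counter = 0
    for sp in config.species_specs:
        rng = _rng(config.seed, f"ages/{sp.name}")
        for tissue in sorted(sp.n_per_tissue):
            n = sp.n_per_tissue[tissue]
            lo, hi = config.age_range
            hi = min(hi, sp.max_lifespan)
            ages = rng.uniform(lo, hi, n)
            for j in range(n):
                counter += 1
                stock, altitude = (None, None)
                if sp.stocks:
                    # contiguous blocks per stock so the within-block F/M
                    # alternation leaves sex balanced across stocks
                    stock, altitude = sp.stocks[(j * len(sp.stocks)) // n]
                samples.append(
                    SampleAnnotation(
                        sample_id=f"S{counter:03d}",
                        species=sp.name,
                        tissue=tissue,
                        sex="F" if j % 2 == 0 else "M",
                        age_years=float(ages[j]),
                        stock=stock,
                        mating_system=sp.mating_system,
                        altitude=altitude,
                        max_lifespan_years=sp.max_lifespan,
                    )
                )
    return samples


def _assemble_logits(
    config: SimulationConfig,
    samples: Sequence[SampleAnnotation],
    draws: dict,
    noise_key: str,
) -> tuple[np.ndarray, dict[str, list[float]]]:
    n_cpg, n_sample = config.n_cpg, len(samples)
    _, species_sd, stock_sd, sex_sd = config.hierarchy_sds

    species_names = sorted({s.species for s in samples})
    species_off = {
        sp: _rng(config.seed, f"species/{sp}").normal(0.0, species_sd, n_cpg)
        for sp in species_names
    }
    stock_names = sorted({(s.species, s.stock) for s in samples if s.stock})
    stock_off = {
        key: _rng(config.seed, f"stock/{key[0]}/{key[1]}").normal(0.0, stock_sd, n_cpg)
        for key in stock_names
    }
    sex_off = {"F": np.zeros(n_cpg), "M": _rng(config.seed, "sex/M").normal(0.0, sex_sd, n_cpg)}

    ages = np.array([s.age_years for s in samples])
    lifespans = np.array([s.max_lifespan_years or np.nan for s in samples])
    f_age = _age_transform_value(ages, lifespans, config.age_effect_scale)

    logits = np.tile(draws["mu"][:, None], (1, n_sample))
    baseline_means: dict[str, list[float]] = {}
    for j, s in enumerate(samples):
        cell = (
            draws["mu"]
            + draws["tissue_off"][s.tissue]
            + species_off[s.species]
            + (stock_off[(s.species, s.stock)] if s.stock else 0.0)
            + sex_off[s.sex]
        )
        logits[:, j] = cell
        key = f"{s.tissue}|{s.species}|{s.stock or ''}|{s.sex}"
        if key not in baseline_means:
            baseline_means[key] = [float(v) for v in cell]
    # planted age effects
    logits[draws["age_idx"], :] += np.outer(draws["slopes"], f_age)
    # planted group effects on the positive level of each contrast
    for contrast, idx in draws["group_idx"].items():
        positive = {"mating_system": "monogamous", "altitude": "high"}.get(contrast)
        if positive is None:
            raise ValueError(f"unknown contrast field {contrast!r}")
        indicator = np.array(
            [1.0 if getattr(s, contrast) == positive else 0.0 for s in samples]
        )
        logits[idx, :] += np.outer(draws["group_eff"][contrast], indicator)
    logits += _rng(config.seed, noise_key).normal(0.0, config.noise_sd, (n_cpg, n_sample))
    return logits, baseline_means


def generate_dataset(config: SimulationConfig) -> tuple[MethylationDataset, GroundTruth]:
    """Simulate a deer-mouse style dataset and its planted-effect registry.

    The returned betas are strictly inside (0, 1); the seed fully determines
    the output.  If ``config.n_outliers`` > 0, that many samples are replaced
    by uniform noise (see :func:`plant_outliers`) and recorded in the truth.
    """
    draws = _structural_draws(config)
    samples = _build_samples(config)
    if config.n_outliers >= len(samples):
        raise ValueError("n_outliers must be smaller than the number of samples")
    logits, baseline_means = _assemble_logits(config, samples, draws, "noise")
    beta = BetaMatrix(expit(logits), _cpg_ids(config.n_cpg), [s.sample_id for s in samples])

    cpgs = _cpg_ids(config.n_cpg)
    truth = GroundTruth(
        age_cpgs={cpgs[i]: float(s) for i, s in zip(draws["age_idx"], draws["slopes"])},
        age_scale=config.age_effect_scale,
        group_cpgs={
            contrast: {cpgs[i]: float(e) for i, e in zip(idx, draws["group_eff"][contrast])}
            for contrast, idx in draws["group_idx"].items()
        },
        outlier_sample_ids=[],
        baseline_means=baseline_means,
    )
    manifest = generate_manifest(cpgs, generate_gene_annotation(
        n_genes=max(20, config.n_cpg // 5), seed=config.seed), seed=config.seed)
    dataset = MethylationDataset(beta=beta, samples=samples, manifest=manifest)
    if config.n_outliers > 0:
        dataset, outlier_ids = plant_outliers(dataset, config.n_outliers, config.seed)
        truth.outlier_sample_ids = list(outlier_ids)
    return dataset, truth


def plant_outliers(
    dataset: MethylationDataset, n_outliers: int, seed: int
) -> tuple[MethylationDataset, list[str]]:
    """Replace ``n_outliers`` random samples' betas by i.i.d. uniform(0, 1).

    This destroys their interarray correlation with every other sample —
    the signature of a technical failure — without touching annotations.
    Returns a new dataset; the input is not mutated.
    """
    if n_outliers >= dataset.n_samples:
        raise ValueError("n_outliers must be smaller than the number of samples")
    if n_outliers == 0:
        return dataset, []
    rng = _rng(seed, "outliers")
    chosen = sorted(rng.choice(dataset.n_samples, size=n_outliers, replace=False))
    values = dataset.beta.values.copy()
    for j in chosen:
        values[:, j] = rng.uniform(0.0, 1.0, dataset.n_cpgs)
    beta = BetaMatrix(values, list(dataset.beta.cpg_ids), list(dataset.beta.sample_ids),
                      validate=False)
    new = MethylationDataset(
        beta=beta, samples=list(dataset.samples), manifest=list(dataset.manifest),
        unmapped_cpgs=dataset.unmapped_cpgs,
    )
    return new, [dataset.beta.sample_ids[j] for j in chosen]


def generate_human_stratum(
    config: SimulationConfig,
    n_samples: int = 120,
    age_range: tuple[float, float] = (0.0, 93.0),
    max_lifespan: float = 122.5,
    tissues: Sequence[str] = ("other", "liver", "brain"),
) -> MethylationDataset:
    """A human-labelled stratum on the same CpGs as :func:`generate_dataset`.

    The per-CpG baselines, tissue offsets and planted age slopes are re-derived
    from the same named substreams of ``config.seed``, so the human stratum
    shares its planted age CpGs with the deer stratum generated from the same
    config.  Age effects are expressed per unit of relative age, which
    requires ``config.age_effect_scale == 'relative'`` — otherwise a dual
    clock would have nothing cross-species to learn.
    """
    if config.age_effect_scale != "relative":
        raise ValueError(
            "generate_human_stratum needs age_effect_scale='relative' so age "
            "effects are comparable across species"
        )
    draws = _structural_draws(config)
    rng = _rng(config.seed, "human/samples")
    ages = rng.uniform(age_range[0], age_range[1], n_samples)
    samples = [
        SampleAnnotation(
            sample_id=f"H{j + 1:04d}",
            species="Homo sapiens",
            tissue=tissues[j % len(tissues)],
            sex="F" if j % 2 == 0 else "M",
            age_years=float(ages[j]),
            max_lifespan_years=max_lifespan,
        )
        for j in range(n_samples)
    ]
    logits, _ = _assemble_logits(config, samples, draws, "human/noise")
    beta = BetaMatrix(expit(logits), _cpg_ids(config.n_cpg), [s.sample_id for s in samples])
    manifest = generate_manifest(_cpg_ids(config.n_cpg), generate_gene_annotation(
        n_genes=max(20, config.n_cpg // 5), seed=config.seed), seed=config.seed)
    return MethylationDataset(beta=beta, samples=samples, manifest=manifest)


# -- genome scaffolding for manifests and enrichment ---------------------------

def generate_gene_annotation(
    n_genes: int,
    seed: int,
    n_chrom: int = 20,
    spacing: int = 150_000,
) -> pd.DataFrame:
    """Synthetic gene table (gene, chrom, tss, strand): evenly spaced TSSs
    with jitter on ``n_chrom`` chromosomes, random strands."""
    rng = _rng(seed, "genes")
    genes = []
    for i in range(n_genes):
        chrom = f"chr{(i % n_chrom) + 1}"
        rank = i // n_chrom
        tss = (rank + 1) * spacing + int(rng.integers(-spacing // 4, spacing // 4))
        genes.append(
            {
                "gene": f"g{i + 1:04d}",
                "chrom": chrom,
                "tss": max(1, tss),
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    return pd.DataFrame(genes)


def generate_manifest(
    cpg_ids: Sequence[str], genes: pd.DataFrame, seed: int
) -> list[ProbeRecord]:
    """Place each CpG near a random gene and classify its region."""
    rng = _rng(seed, "manifest")
    gene_rows = genes.to_dict("records")
    records = []
    for cpg in cpg_ids:
        g = gene_rows[int(rng.integers(0, len(gene_rows)))]
        offset = int(rng.integers(-30_000, 30_000))
        pos = max(1, g["tss"] + offset)
        signed = pos - g["tss"] if g["strand"] == "+" else g["tss"] - pos
        records.append(
            ProbeRecord(
                cpg_id=str(cpg),
                chrom=g["chrom"],
                pos=pos,
                adjacent_gene=g["gene"],
                region_class=REGION_CLASSES[int(rng.integers(0, len(REGION_CLASSES)))],
                tss_distance=signed,
            )
        )
    return records


def generate_gene_sets(
    gene_names: Sequence[str],
    n_sets: int = 40,
    size_range: tuple[int, int] = (10, 200),
    seed: int = 0,
    planted: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, set[str]]:
    """Random gene sets for enrichment testing, plus optional planted sets
    (name -> exact member list) appended verbatim."""
    rng = _rng(seed, "gene_sets")
    genes = list(gene_names)
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        lo, hi = size_range
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"set{i + 1:03d}"] = {genes[j] for j in members}
    for name, members in (planted or {}).items():
        sets[name] = set(members)
    return sets
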
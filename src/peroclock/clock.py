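"""Elastic-net epigenetic clocks: age transforms, fitting, and cross-validation.

A clock is a penalized linear regression of (transformed) chronological age
on CpG beta values.  Fitting uses the elastic net at mixing parameter 0.5
(midway between ridge and lasso); the penalty strength is chosen by tenfold
internal cross-validation on the training set.  Accuracy is reported by
leave-one-sample-out cross-validation (LOOCV): the Pearson correlation R
between the held-out age estimate (DNAm age) and chronological age, and the
median absolute error in years.

Three age scales are supported for the dependent variable:

* ``identity`` — age in years, untransformed;
* ``log_linear`` — logarithmic below a maturity age m, linear above, joined
  continuously: F(x) = log(x + c) - log(m + c) for x < m and
  (x - m) / (m + c) for x >= m, with offset c > 0.  This compresses the
  fast-changing juvenile range, the standard move for clocks spanning
  development and adulthood;
* ``relative`` — age divided by the species maximum lifespan, a value in
  [0, 1] comparable between species with very different lifespans; this is
  what makes a single dual-species (deer mouse + human) clock meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV

from .datamodel import DEFAULT_MAX_LIFESPANS, MethylationDataset

__all__ = [
    "AgeTransformSpec",
    "ClockModel",
    "CVResult",
    "transform_age",
    "inverse_transform_age",
    "fit_clock",
    "loocv_evaluate",
    "fit_dual_species_clock",
]


@dataclass(frozen=True)
class AgeTransformSpec:
    """Specification of the transform applied to chronological age.

    kind: 'identity', 'log_linear' or 'relative'.
    maturity_years / offset_years parameterize the log-linear form; defaults
    are 0.5 y maturity (deer mouse) with a 0.1 y offset.
    lifespan_source maps species name -> maximum lifespan (years) for the
    'relative' kind and for species-specific maturities in dual fits.
    maturity_by_species optionally overrides maturity per species.
    """

    kind: str = "log_linear"
    maturity_years: float = 0.5
    offset_years: float = 0.1
    lifespan_source: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_LIFESPANS)
    )
    maturity_by_species: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "log_linear", "relative"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.maturity_years <= 0 or self.offset_years <= 0:
            raise ValueError("maturity_years and offset_years must be positive")

    def _maturity(self, species: str | None) -> float:
        if species is not None and species in self.maturity_by_species:
            return self.maturity_by_species[species]
        return self.maturity_years

    def _lifespan(self, species: str | None) -> float:
        if species is None or species not in self.lifespan_source:
            raise ValueError(
                f"relative age transform needs a maximum lifespan for species {species!r}"
            )
        return float(self.lifespan_source[species])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "maturity_years": self.maturity_years,
            "offset_years": self.offset_years,
            "lifespan_source": dict(self.lifespan_source),
            "maturity_by_species": dict(self.maturity_by_species),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "AgeTransformSpec":
        return cls(
            kind=data["kind"],
            maturity_years=data["maturity_years"],
            offset_years=data["offset_years"],
            lifespan_source=dict(data.get("lifespan_source", {})),
            maturity_by_species=dict(data.get("maturity_by_species", {})),
        )


def _log_linear(x: np.ndarray, m: float, c: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x < m, np.log(x + c) - np.log(m + c), (x - m) / (m + c))


def _log_linear_inv(y: np.ndarray, m: float, c: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return np.where(y < 0, np.exp(y + np.log(m + c)) - c, y * (m + c) + m)


def transform_age(
    age_years: float | np.ndarray,
    spec: AgeTransformSpec,
    species: str | Sequence[str] | None = None,
) -> float | np.ndarray:
    """Map chronological age (years) to the clock's regression scale.

    ``species`` is required per sample for 'relative' (to look up the
    lifespan) and consulted for species-specific maturities in 'log_linear'.
    """
    ages = np.atleast_1d(np.asarray(age_years, dtype=float))
    if np.any(ages < 0):
        raise ValueError("age_years must be non-negative")
    if isinstance(species, str) or species is None:
        species_arr = [species] * ages.size
    else:
        species_arr = list(species)
        if len(species_arr) != ages.size:
            raise ValueError("species list length must match ages")

    if spec.kind == "identity":
        out = ages.copy()
    elif spec.kind == "relative":
        lifespans = np.array([spec._lifespan(s) for s in species_arr])
        out = ages / lifespans
    else:
        out = np.empty_like(ages)
        for i, (a, s) in enumerate(zip(ages, species_arr)):
            m = spec._maturity(s)
            out[i] = _log_linear(a, m, spec.offset_years)
    return out[0] if np.isscalar(age_years) else out


def inverse_transform_age(
    value: float | np.ndarray,
    spec: AgeTransformSpec,
    species: str | Sequence[str] | None = None,
    clamp_relative: bool = False,
) -> float | np.ndarray:
    """Invert :func:`transform_age`, returning age in years.

    For the 'relative' kind, predictions may optionally be clamped to
    [0, 1] before conversion (used when reporting relative age itself).
    """
    vals = np.atleast_1d(np.asarray(value, dtype=float))
    if isinstance(species, str) or species is None:
        species_arr = [species] * vals.size
    else:
        species_arr = list(species)

    if spec.kind == "identity":
        out = vals.copy()
    elif spec.kind == "relative":
        rel = np.clip(vals, 0.0, 1.0) if clamp_relative else vals
        lifespans = np.array([spec._lifespan(s) for s in species_arr])
        out = rel * lifespans
    else:
        out = np.empty_like(vals)
        for i, (v, s) in enumerate(zip(vals, species_arr)):
            m = spec._maturity(s)
            out[i] = _log_linear_inv(v, m, spec.offset_years)
    return out[0] if np.isscalar(value) else out


@dataclass
class ClockModel:
    """A fitted sparse linear age estimator.

    ``coefficients`` maps CpG id -> coefficient on the raw beta scale
    (non-zero entries only); predictors were standardized inside the fit and
    coefficients back-transformed, so the model applies directly to beta
    values.  ``alpha`` is the elastic-net mixing parameter, ``lambda_`` the
    internally cross-validated penalty strength.
    """

    intercept: float
    coefficients: dict[str, float]
    transform: AgeTransformSpec
    alpha: float
    lambda_: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return len(self.coefficients)

    def predict_transformed(self, dataset: MethylationDataset) -> np.ndarray:
        """Linear predictor on the transformed-age scale."""
        beta = dataset.beta.to_frame()
        missing = [c for c in self.coefficients if c not in beta.index]
        if missing:
            raise KeyError(f"dataset lacks {len(missing)} clock CpGs, e.g. {missing[:3]}")
        if not self.coefficients:
            return np.full(dataset.n_samples, self.intercept)
        cpgs = list(self.coefficients)
        coef = np.array([self.coefficients[c] for c in cpgs])
        x = beta.loc[cpgs].to_numpy().T  # samples x cpgs
        if np.isnan(x).any():
            raise ValueError("clock prediction requires complete betas at clock CpGs")
        return self.intercept + x @ coef

    def predict_age_years(self, dataset: MethylationDataset) -> np.ndarray:
        """DNAm age in years (relative predictions clamped to [0, 1] first)."""
        species = [s.species for s in dataset.samples]
        raw = self.predict_transformed(dataset)
        return np.asarray(
            inverse_transform_age(raw, self.transform, species, clamp_relative=True)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "transform": self.transform.to_dict(),
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        data = json.loads(Path(path).read_text())
        return cls(
            intercept=data["intercept"],
            coefficients=dict(data["coefficients"]),
            transform=AgeTransformSpec.from_dict(data["transform"]),
            alpha=data["alpha"],
            lambda_=data["lambda"],
            metadata=dict(data.get("metadata", {})),
        )


@dataclass
class CVResult:
    """Cross-validated accuracy: one held-out prediction per sample."""

    predictions: pd.DataFrame  # sample_id, age_years, dnam_age_years [, rel columns]
    pearson_r: float
    median_abs_error_years: float

    @property
    def n(self) -> int:
        return len(self.predictions)


def _stratified_folds(
    strata: Sequence[tuple], n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment spreading every (species, tissue) stratum across folds."""
    n = len(strata)
    fold = np.empty(n, dtype=int)
    order = rng.permutation(n)
    by_stratum: dict[tuple, list[int]] = {}
    for i in order:
        by_stratum.setdefault(strata[i], []).append(i)
    counter = 0
    for members in by_stratum.values():
        for i in members:
            fold[i] = counter % n_folds
            counter += 1
    return fold


def _design(dataset: MethylationDataset, transform: AgeTransformSpec):
    x = dataset.beta.values.T.copy()  # samples x cpgs
    if np.isnan(x).any():
        raise ValueError("clock fitting requires complete beta values (no NaN)")
    species = [s.species for s in dataset.samples]
    y = np.asarray(transform_age(dataset.ages, transform, species))
    return x, y, species


def fit_clock(
    dataset: MethylationDataset,
    transform: AgeTransformSpec | None = None,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 16,
    lambda_min_ratio: float = 1e-2,
) -> ClockModel:
    """Fit an elastic-net clock with internally cross-validated penalty.

    ``alpha`` is the elastic-net mixing parameter (0.5 by default, midway
    between ridge and lasso); the penalty strength minimizing the internal
    ``n_folds``-fold CV mean squared error is selected from a ``n_lambdas``
    log-spaced path.  Folds are stratified by (species, tissue) so that no
    fold loses an entire stratum.  Predictors are standardized inside the
    fit; returned coefficients are on the raw beta scale.
    """
    transform = transform or AgeTransformSpec()
    x, y, species = _design(dataset, transform)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant (transformed) age response")

    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    xs = (x - mean) / sd_safe

    # every internal-CV fold must leave a usable training set; with very few
    # samples CV is impossible and a fixed penalty (5% of lambda_max) is used
    n_folds_eff = int(min(n_folds, n // 2))
    internal_cv_r2 = float("nan")
    if n_folds_eff >= 2:
        rng = np.random.default_rng(seed)
        strata = [(s.species, s.tissue) for s in dataset.samples]
        fold = _stratified_folds(strata, n_folds_eff, rng)
        splits = [
            (np.flatnonzero(fold != k), np.flatnonzero(fold == k))
            for k in range(n_folds_eff)
        ]
        enet = ElasticNetCV(
            l1_ratio=alpha,
            alphas=n_lambdas,  # path length; sklearn derives the log-spaced grid
            eps=lambda_min_ratio,
            cv=splits,
            fit_intercept=True,
            max_iter=1500,
            tol=2e-3,
            selection="random",  # faster coordinate descent; seeded, so deterministic
            random_state=seed % (2**31),
        )
        enet.fit(xs, y)
        cv_mse = float(enet.mse_path_.mean(axis=1).min())
        internal_cv_r2 = float(1.0 - cv_mse / np.var(y))
        chosen_lambda = float(enet.alpha_)
    else:
        from sklearn.linear_model import ElasticNet

        lambda_max = np.max(np.abs(xs.T @ (y - y.mean()))) / (n * max(alpha, 1e-12))
        chosen_lambda = 0.05 * float(lambda_max)
        enet = ElasticNet(
            alpha=chosen_lambda, l1_ratio=alpha, max_iter=1500, tol=2e-3,
        )
        enet.fit(xs, y)

    coef_std = enet.coef_
    nz = np.flatnonzero(coef_std != 0)
    coef_beta = coef_std[nz] / sd_safe[nz]
    intercept = float(enet.intercept_ - np.sum(coef_std[nz] * mean[nz] / sd_safe[nz]))
    coefficients = {
        dataset.beta.cpg_ids[i]: float(c) for i, c in zip(nz, coef_beta)
    }
    return ClockModel(
        intercept=intercept,
        coefficients=coefficients,
        transform=transform,
        alpha=alpha,
        lambda_=chosen_lambda,
        metadata={
            "n_samples": n,
            "n_cpgs": dataset.n_cpgs,
            "species": sorted({s.species for s in dataset.samples}),
            "tissues": sorted({s.tissue for s in dataset.samples}),
            "seed": seed,
            "n_folds": n_folds,
            "internal_cv_r2": internal_cv_r2,
        },
    )


def _score_predictions(
    dataset: MethylationDataset, dnam_age: np.ndarray, transform: AgeTransformSpec
) -> CVResult:
    ages = dataset.ages
    frame = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in dataset.samples],
            "species": [s.species for s in dataset.samples],
            "tissue": [s.tissue for s in dataset.samples],
            "age_years": ages,
            "dnam_age_years": dnam_age,
        }
    )
    if transform.kind == "relative":
        lifespans = np.array([transform._lifespan(s.species) for s in dataset.samples])
        frame["relative_age"] = ages / lifespans
        frame["dnam_relative_age"] = np.clip(dnam_age / lifespans, 0.0, 1.0)
    r = float(np.corrcoef(dnam_age, ages)[0, 1]) if np.ptp(dnam_age) > 0 else 0.0
    mae = float(np.median(np.abs(dnam_age - ages)))
    return CVResult(predictions=frame, pearson_r=r, median_abs_error_years=mae)


def loocv_evaluate(
    dataset: MethylationDataset,
    transform: AgeTransformSpec | None = None,
    alpha: float = 0.5,
    seed: int = 0,
    n_folds: int = 10,
    **fit_kwargs,
) -> CVResult:
    """Leave-one-sample-out accuracy of the clock.

    Each sample is predicted by a clock trained on the remaining n - 1
    samples (penalty re-selected by internal CV each time), giving one
    unbiased DNAm-age estimate per sample.  Reports the Pearson R between
    DNAm age and chronological age and the median absolute error in years.
    """
    transform = transform or AgeTransformSpec()
    n = dataset.n_samples
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    ids = dataset.beta.sample_ids
    preds = np.empty(n)
    for i in range(n):
        train_ids = ids[:i] + ids[i + 1 :]
        train = dataset.subset_samples(train_ids)
        try:
            model = fit_clock(
                train, transform, alpha=alpha, n_folds=min(n_folds, n - 1),
                seed=seed + i, **fit_kwargs,
            )
        except Exception as exc:
            raise RuntimeError(f"LOOCV fold for sample {ids[i]!r} failed: {exc}") from exc
        held = dataset.subset_samples([ids[i]])
        preds[i] = model.predict_age_years(held)[0]
    return _score_predictions(dataset, preds, transform)


def _merge_datasets(a: MethylationDataset, b: MethylationDataset) -> MethylationDataset:
    shared = sorted(set(a.beta.cpg_ids) & set(b.beta.cpg_ids))
    if not shared:
        raise ValueError("datasets share no CpG ids")
    fa = a.beta.to_frame().loc[shared]
    fb = b.beta.to_frame().loc[shared]
    from .datamodel import BetaMatrix  # local to avoid re-export confusion

    beta = BetaMatrix.from_frame(pd.concat([fa, fb], axis=1), validate=False)
    manifest = {p.cpg_id: p for p in list(a.manifest) + list(b.manifest)}
    kept = [manifest[c] for c in shared if c in manifest]
    unmapped = tuple(c for c in shared if c not in manifest) if kept else ()
    return MethylationDataset(
        beta=beta,
        samples=list(a.samples) + list(b.samples),
        manifest=kept,
        unmapped_cpgs=unmapped,
    )


def fit_dual_species_clock(
    deer_dataset: MethylationDataset,
    human_dataset: MethylationDataset,
    target: str = "chronological",
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    loocv: bool = True,
    human_maturity_years: float = 15.0,
    **fit_kwargs,
) -> tuple[ClockModel, CVResult | None, dict[str, CVResult]]:
    """One regression over pooled deer-mouse + human samples.

    ``target='chronological'`` fits log-linear transformed age with a
    species-specific maturity (human maturity defaults to 15 y);
    ``target='relative'`` fits age / maximum lifespan, which needs no
    per-species maturity and whose predictions are clamped to [0, 1].
    Accuracy is reported pooled and restricted to each species group —
    the pooled correlation is inflated by the lifespan gap between the
    species, so the restricted numbers are the honest per-species ones.
    """
    if target not in ("chronological", "relative"):
        raise ValueError("target must be 'chronological' or 'relative'")
    deer_species = {s.species for s in deer_dataset.samples}
    human_species = {s.species for s in human_dataset.samples}
    if not deer_species or deer_species & {"Homo sapiens"}:
        raise ValueError("deer_dataset must contain only non-human samples")
    if human_species != {"Homo sapiens"}:
        raise ValueError("human_dataset must contain only 'Homo sapiens' samples")

    pooled = _merge_datasets(deer_dataset, human_dataset)
    if target == "relative":
        transform = AgeTransformSpec(kind="relative")
    else:
        transform = AgeTransformSpec(
            kind="log_linear",
            maturity_by_species={"Homo sapiens": human_maturity_years},
        )
    model = fit_clock(
        pooled, transform, alpha=alpha, n_folds=n_folds, seed=seed, **fit_kwargs
    )
    model.metadata["target"] = target

    overall: CVResult | None = None
    per_group: dict[str, CVResult] = {}
    if loocv:
        overall = loocv_evaluate(
            pooled, transform, alpha=alpha, seed=seed, n_folds=n_folds, **fit_kwargs
        )
        overall.predictions["group"] = [
            "human" if sp == "Homo sapiens" else "peromyscus"
            for sp in overall.predictions["species"]
        ]
        for group in ("peromyscus", "human"):
            sub = overall.predictions[overall.predictions["group"] == group]
            if sub.empty:
                raise ValueError(f"no samples in restricted group {group!r}")
            r = (
                float(np.corrcoef(sub["dnam_age_years"], sub["age_years"])[0, 1])
                if sub["dnam_age_years"].std() > 0
                else 0.0
            )
            mae = float(np.median(np.abs(sub["dnam_age_years"] - sub["age_years"])))
            per_group[group] = CVResult(
                predictions=sub.reset_index(drop=True),
                pearson_r=r,
                median_abs_error_years=mae,
            )
    return model, overall, per_group
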
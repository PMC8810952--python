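"""Epigenome-wide association: per-CpG age correlations, Fisher Z statistics,
Stouffer meta-analysis across tissues, age-adjusted group contrasts, and
cross-stratum sector classification.

The age screen is a per-CpG Pearson correlation between beta value and
chronological age within a stratum (typically one tissue of one species),
with a two-sided p-value from the exact t reference t = r sqrt(n-2) /
sqrt(1-r^2) on n-2 degrees of freedom.  Correlations are variance-stabilized
as Fisher Z = atanh(r) sqrt(n-3) for sector plots and meta-analysis; strata
are combined by Stouffer's method, sum(w_i z_i) / sqrt(sum w_i^2), with
equal weights across tissues.  Group contrasts (altitude, mating system,
species pair) are per-CpG least-squares fits of beta ~ group + age, so the
group effect is the mean methylation difference adjusted for chronological
age.  Missing betas are handled pairwise-complete; per-CpG sample counts are
reported as ``n_used``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MethylationDataset

__all__ = [
    "EwasResult",
    "GroupEwasResult",
    "SectorClassification",
    "cpg_age_correlation",
    "fisher_z",
    "stouffer_meta",
    "ewas_age",
    "group_ewas",
    "sector_classify",
    "cross_result_correlation",
    "rank_hits",
]

SECTOR_CATEGORIES = ("shared_up", "shared_down", "unique_x", "unique_y", "divergent", "null")


# -- elementary statistics -----------------------------------------------------

def fisher_z(r: float | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    """Variance-stabilized correlation statistic z = atanh(r) * sqrt(n - 3).

    |r| = 1 yields a signed infinity sentinel (the caller sees the flag as a
    non-finite value); n must exceed 3 for the statistic to be defined.
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(np.abs(r_arr) > 1):
        raise ValueError("|r| must be <= 1")
    if np.any(n_arr <= 3):
        raise ValueError("fisher_z requires n > 3")
    with np.errstate(divide="ignore"):
        z = np.arctanh(r_arr) * np.sqrt(n_arr - 3.0)
    return float(z) if np.isscalar(r) and np.isscalar(n) else z


def stouffer_meta(
    z: Sequence[float] | np.ndarray, weights: Sequence[float] | None = None
) -> float:
    """Stouffer combination sum(w_i z_i) / sqrt(sum w_i^2), equal weights by default."""
    z_arr = np.asarray(z, dtype=float)
    if z_arr.ndim != 1 or z_arr.size == 0:
        raise ValueError("need at least one stratum Z-score")
    if weights is None:
        w = np.ones_like(z_arr)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != z_arr.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match z")
    return float(np.sum(w * z_arr) / np.sqrt(np.sum(w**2)))


def _corr_with_trait(values: np.ndarray, trait: np.ndarray):
    """Row-wise Pearson correlation of a CpG x sample matrix with a trait,
    pairwise-complete over missing betas.  Returns (r, n_used, constant_flag)."""
    valid = np.isfinite(values)
    n_used = valid.sum(axis=1)
    t = np.where(valid, trait[None, :], 0.0)
    v = np.where(valid, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_t = t.sum(axis=1)
        sum_v = v.sum(axis=1)
        mean_t = sum_t / n_used
        mean_v = sum_v / n_used
        sxy = (v * t).sum(axis=1) - n_used * mean_v * mean_t
        sxx = (v**2).sum(axis=1) - n_used * mean_v**2
        syy = (t**2).sum(axis=1) - n_used * mean_t**2
        denom = np.sqrt(np.clip(sxx, 0, None) * np.clip(syy, 0, None))
        r = np.where(denom > 0, sxy / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    constant = (sxx <= 1e-300) | (syy <= 0) | (n_used < 3)
    return r, n_used, constant


def cpg_age_correlation(
    dataset: MethylationDataset,
    stratum: Mapping[str, object] | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Per-CpG Pearson correlation of beta with chronological age in a stratum.

    ``stratum`` is a mapping of annotation field -> value (e.g.
    ``{"tissue": "tail", "species": "Peromyscus maniculatus"}``); None uses
    all samples.  Returns a DataFrame indexed by cpg_id with columns
    r, n_used, p, z and a ``constant`` flag; constant CpGs get r = 0, p = 1.
    """
    if stratum:
        mask = dataset.sample_mask(**stratum)
        sub = dataset.subset_samples(
            [s.sample_id for s, keep in zip(dataset.samples, mask) if keep]
        )
    else:
        sub = dataset
    ages = sub.ages
    if sub.n_samples < min_n:
        raise ValueError(
            f"stratum has {sub.n_samples} samples; need at least {min_n}"
        )
    if np.ptp(ages) == 0:
        raise ValueError("stratum has no age variance")
    r, n_used, constant = _corr_with_trait(sub.beta.values, ages)
    df_resid = np.maximum(n_used - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt(df_resid) / np.sqrt(np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df_resid)
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)
    p = np.where(constant, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    r = np.where(constant, 0.0, r)
    with np.errstate(divide="ignore"):
        z = np.where(
            n_used > 3, np.arctanh(np.clip(r, -1, 1)) * np.sqrt(np.maximum(n_used - 3, 0)), np.nan
        )
    return pd.DataFrame(
        {"r": r, "n_used": n_used.astype(int), "p": p, "z": z, "constant": constant},
        index=pd.Index(sub.beta.cpg_ids, name="cpg_id"),
    )


@dataclass
class EwasResult:
    """Per-stratum age-EWAS tables plus (optionally) their Stouffer meta-Z."""

    per_stratum: dict[str, pd.DataFrame]
    meta: pd.DataFrame | None = None

    @property
    def strata(self) -> list[str]:
        return list(self.per_stratum)

    def to_frame(self) -> pd.DataFrame:
        """Wide per-CpG table: r/n/p/z per stratum + meta columns."""
        pieces = []
        for name, frame in self.per_stratum.items():
            renamed = frame[["r", "n_used", "p", "z"]].add_prefix(f"{name}.")
            pieces.append(renamed)
        wide = pd.concat(pieces, axis=1)
        if self.meta is not None:
            wide = wide.join(self.meta.add_prefix("meta."))
        return wide


def ewas_age(
    dataset: MethylationDataset,
    stratify: str = "tissue",
    stratum_filter: Mapping[str, object] | None = None,
    min_n: int = 4,
    meta: bool = True,
) -> EwasResult:
    """Age EWAS per stratum with equal-weight Stouffer meta-analysis.

    Strata are the levels of ``stratify`` (default tissue, the scale the
    meta-analysis is meant for); ``stratum_filter`` restricts the sample set
    first (e.g. to one species).  Strata with fewer than ``min_n`` samples
    or no age variance are skipped.
    """
    if stratum_filter:
        mask = dataset.sample_mask(**stratum_filter)
        dataset = dataset.subset_samples(
            [s.sample_id for s, keep in zip(dataset.samples, mask) if keep]
        )
    levels = sorted({getattr(s, stratify) for s in dataset.samples if getattr(s, stratify)})
    per_stratum: dict[str, pd.DataFrame] = {}
    for level in levels:
        try:
            per_stratum[str(level)] = cpg_age_correlation(
                dataset, {stratify: level}, min_n=min_n
            )
        except ValueError:
            continue
    if not per_stratum:
        raise ValueError("no stratum had enough samples for the age EWAS")
    meta_frame = None
    if meta and len(per_stratum) >= 1:
        z_cols = pd.DataFrame({name: f["z"] for name, f in per_stratum.items()})
        usable = z_cols.notna()
        z_filled = z_cols.fillna(0.0).to_numpy()
        w = usable.to_numpy().astype(float)
        denom = np.sqrt((w**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            z_meta = (z_filled * w).sum(axis=1) / denom
        p_meta = 2.0 * stats.norm.sf(np.abs(z_meta))
        meta_frame = pd.DataFrame(
            {"z": z_meta, "p": np.clip(p_meta, np.finfo(float).tiny, 1.0),
             "n_strata": usable.sum(axis=1)},
            index=z_cols.index,
        )
    return EwasResult(per_stratum=per_stratum, meta=meta_frame)


@dataclass
class GroupEwasResult:
    """Age-adjusted two-group contrast: per-CpG effect, t, p and direction."""

    table: pd.DataFrame  # effect, t, p, direction, n_used
    group_field: str
    positive_level: str
    reference_level: str
    n_positive: int
    n_reference: int


def group_ewas(
    dataset: MethylationDataset,
    group_field: str,
    positive_level: str,
    covariate: str = "age_years",
    min_group_n: int = 3,
) -> GroupEwasResult:
    """Per-CpG least-squares fit beta ~ group + age (the age-adjusted contrast).

    ``effect`` is the coefficient of the group indicator (positive level = 1),
    i.e. the mean methylation difference between groups at equal age, with a
    two-sided t test on that coefficient.  Samples whose ``group_field`` is
    None are dropped.  Raises on a rank-deficient design (group confounded
    with age).
    """
    keep = [s for s in dataset.samples if getattr(s, group_field) is not None]
    if len(keep) < dataset.n_samples:
        dataset = dataset.subset_samples([s.sample_id for s in keep])
    labels = np.array([getattr(s, group_field) for s in dataset.samples], dtype=object)
    levels = sorted(set(labels))
    if positive_level not in levels:
        raise ValueError(f"{positive_level!r} not a level of {group_field!r}: {levels}")
    if len(levels) != 2:
        raise ValueError(f"{group_field!r} must be binary in this dataset, got {levels}")
    reference = next(l for l in levels if l != positive_level)
    indicator = (labels == positive_level).astype(float)
    n_pos = int(indicator.sum())
    n_ref = int(len(indicator) - n_pos)
    if min(n_pos, n_ref) < min_group_n:
        raise ValueError(
            f"both groups need >= {min_group_n} samples (got {n_pos} vs {n_ref})"
        )
    age = np.array([getattr(s, covariate) for s in dataset.samples], dtype=float)
    design = np.column_stack([np.ones_like(age), indicator, age])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design is rank deficient: group is confounded with age")

    values = dataset.beta.values  # cpg x sample
    if np.isnan(values).any():
        effects = np.empty(values.shape[0])
        t_stats = np.empty(values.shape[0])
        p_vals = np.empty(values.shape[0])
        n_used = np.empty(values.shape[0], dtype=int)
        for i in range(values.shape[0]):
            ok = np.isfinite(values[i])
            n_used[i] = int(ok.sum())
            effects[i], t_stats[i], p_vals[i] = _ols_group(
                design[ok], values[i, ok]
            )
    else:
        effects, t_stats, p_vals = _ols_group_matrix(design, values.T)
        n_used = np.full(values.shape[0], len(age), dtype=int)

    table = pd.DataFrame(
        {
            "effect": effects,
            "t": t_stats,
            "p": np.clip(p_vals, np.finfo(float).tiny, 1.0),
            "direction": np.sign(effects).astype(int),
            "n_used": n_used,
        },
        index=pd.Index(dataset.beta.cpg_ids, name="cpg_id"),
    )
    return GroupEwasResult(
        table=table,
        group_field=group_field,
        positive_level=positive_level,
        reference_level=reference,
        n_positive=n_pos,
        n_reference=n_ref,
    )


def _ols_group_matrix(design: np.ndarray, y: np.ndarray):
    """Vectorized OLS of many responses on one design; t test on column 1."""
    n, k = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = xtx_inv @ design.T @ y  # k x n_cpg
    resid = y - design @ coef
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.clip(sigma2 * xtx_inv[1, 1], 1e-300, None))
    t_stat = coef[1] / se
    p = 2.0 * stats.t.sf(np.abs(t_stat), dof)
    return coef[1], t_stat, p


def _ols_group(design: np.ndarray, y: np.ndarray):
    if len(y) <= design.shape[1] or np.linalg.matrix_rank(design) < design.shape[1]:
        return np.nan, np.nan, 1.0
    e, t, p = _ols_group_matrix(design, y[:, None])
    return float(e[0]), float(t[0]), float(p[0])


# -- cross-stratum comparison --------------------------------------------------

@dataclass
class SectorClassification:
    """Mutually exclusive, exhaustive sector labels for a Z-vs-Z comparison."""

    labels: pd.Series  # cpg_id -> category
    p_sig: float
    p_nonsig: float
    z_sig: float
    z_nonsig: float

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(SECTOR_CATEGORIES, fill_value=0)


def sector_classify(
    stats_x: pd.Series | pd.DataFrame,
    stats_y: pd.Series | pd.DataFrame,
    p_sig: float = 1e-4,
    p_nonsig: float = 0.05,
) -> SectorClassification:
    """Classify shared CpGs by their aging Z in two strata.

    shared_up / shared_down: both |Z| pass the significance threshold with
    the same sign; divergent: both pass with opposite signs; unique_x /
    unique_y: one passes while the other fails even the lenient
    ``p_nonsig`` threshold; everything else is null.  Thresholds are
    two-sided normal quantiles of the p cutoffs.
    """
    if not p_sig < p_nonsig:
        raise ValueError("p_sig must be smaller than p_nonsig")
    zx = stats_x["z"] if isinstance(stats_x, pd.DataFrame) else stats_x
    zy = stats_y["z"] if isinstance(stats_y, pd.DataFrame) else stats_y
    shared = zx.index.intersection(zy.index)
    if shared.empty:
        raise ValueError("no shared CpG ids")
    zx = zx.loc[shared].to_numpy(dtype=float)
    zy = zy.loc[shared].to_numpy(dtype=float)
    z_sig = float(stats.norm.isf(p_sig / 2))
    z_nonsig = float(stats.norm.isf(p_nonsig / 2))

    sig_x = np.abs(zx) >= z_sig
    sig_y = np.abs(zy) >= z_sig
    weak_x = np.abs(zx) < z_nonsig  # fails even the lenient threshold
    weak_y = np.abs(zy) < z_nonsig
    same_sign = np.sign(zx) == np.sign(zy)

    labels = np.full(len(shared), "null", dtype=object)
    labels[sig_x & sig_y & same_sign & (zx > 0)] = "shared_up"
    labels[sig_x & sig_y & same_sign & (zx < 0)] = "shared_down"
    labels[sig_x & sig_y & ~same_sign] = "divergent"
    labels[sig_x & ~sig_y & weak_y] = "unique_x"
    labels[~sig_x & sig_y & weak_x] = "unique_y"
    return SectorClassification(
        labels=pd.Series(labels, index=shared, name="sector"),
        p_sig=p_sig,
        p_nonsig=p_nonsig,
        z_sig=z_sig,
        z_nonsig=z_nonsig,
    )


def cross_result_correlation(
    stats_x: pd.Series | pd.DataFrame, stats_y: pd.Series | pd.DataFrame
) -> float:
    """Pearson correlation between two strata's Z vectors over shared CpGs."""
    zx = stats_x["z"] if isinstance(stats_x, pd.DataFrame) else stats_x
    zy = stats_y["z"] if isinstance(stats_y, pd.DataFrame) else stats_y
    shared = zx.index.intersection(zy.index)
    x = zx.loc[shared].to_numpy(dtype=float)
    y = zy.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 shared CpGs with finite Z")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def rank_hits(
    stats: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    p_threshold: float = 1e-4,
    top_k: int = 15,
    effect_col: str | None = None,
) -> dict:
    """Rank CpGs per direction by p (ties: |effect|, then cpg_id).

    ``stats`` needs columns ``p`` and either ``direction`` or a signed
    statistic (``effect``/``z``/``r``, controlled by ``effect_col``) whose
    sign defines the direction.  Returns per-direction top tables annotated
    with adjacent genes from the manifest, plus the count passing
    ``p_threshold``.
    """
    frame = stats.copy()
    if effect_col is None:
        effect_col = next(
            (c for c in ("effect", "z", "r") if c in frame.columns), None
        )
        if effect_col is None:
            raise ValueError("stats needs an effect/z/r column for direction")
    if "direction" not in frame.columns:
        frame["direction"] = np.sign(frame[effect_col]).astype(int)
    frame["_abs_effect"] = frame[effect_col].abs()
    frame["_cpg"] = frame.index.astype(str)
    out: dict[str, object] = {"p_threshold": p_threshold, "n_significant": {}}
    for direction, name in ((1, "increased"), (-1, "decreased")):
        sub = frame[frame["direction"] == direction]
        sub = sub.sort_values(
            ["p", "_abs_effect", "_cpg"], ascending=[True, False, True]
        )
        out["n_significant"][name] = int((sub["p"] < p_threshold).sum())
        top = sub.head(top_k).drop(columns=["_abs_effect", "_cpg"])
        if manifest is not None and not manifest.empty:
            cols = [
                c for c in ("adjacent_gene", "region_class", "chrom", "pos")
                if c in manifest.columns
            ]
            top = top.join(manifest[cols], how="left")
        out[name] = top
    return out
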
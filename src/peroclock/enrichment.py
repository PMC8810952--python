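"""Region/gene-set enrichment of top CpG sets, GREAT-style.

Each gene gets a regulatory domain: a basal interval of 50 kb upstream to
1 kb downstream of its TSS (strand-aware), extended in both directions to
the nearer of the neighboring gene's basal domain or 1000 kb.  A CpG is
associated with every gene whose extended domain contains its position.

Two complementary tests score a foreground CpG set (e.g. the top 500 per
direction from an EWAS) against a background set (all array CpGs):

* a hypergeometric test over genes — does the foreground hit more genes of
  the set than chance, given the gene universe actually reachable from the
  array background?  This conditions out array-design bias;
* a binomial test over genomic regions — are more foreground CpGs inside the
  set's domains than the background fraction p0 predicts?

Gene sets outside a configurable size window (10–3000 genes by default) are
dropped to limit multiple testing; nominal p-values are reported with both
Bonferroni and Benjamini–Hochberg adjustments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "RegulatoryDomain",
    "build_regulatory_domains",
    "map_cpgs_to_genes",
    "hypergeometric_gene_test",
    "binomial_region_test",
    "select_foreground",
    "enrich",
]


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal and extended regulatory interval of one gene (1-based inclusive)."""

    gene: str
    chrom: str
    basal_start: int
    basal_end: int
    ext_start: int
    ext_end: int

    def __post_init__(self) -> None:
        if not (self.ext_start <= self.basal_start <= self.basal_end <= self.ext_end):
            raise ValueError(f"domain of {self.gene!r}: basal must nest inside extended")


def build_regulatory_domains(
    genes: pd.DataFrame,
    basal_upstream: int = 50_000,
    basal_downstream: int = 1_000,
    max_extension: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """Regulatory domains from a gene table with columns gene, chrom, tss, strand.

    The basal domain runs ``basal_upstream`` bp upstream to
    ``basal_downstream`` bp downstream of the TSS (strand-aware).  Each side
    is then extended to the nearer of the neighboring gene's basal boundary
    or ``max_extension`` bp, never shrinking below the basal domain itself.
    A missing strand is treated as '+' with a warning.
    """
    import warnings

    required = {"gene", "chrom", "tss"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    frame = genes.copy()
    if "strand" not in frame.columns:
        frame["strand"] = "+"
    blank = ~frame["strand"].isin(["+", "-"])
    if blank.any():
        warnings.warn(
            f"{int(blank.sum())} gene(s) without strand treated as '+'", stacklevel=2
        )
        frame.loc[blank, "strand"] = "+"

    basal_start = np.where(
        frame["strand"] == "+",
        frame["tss"] - basal_upstream,
        frame["tss"] - basal_downstream,
    )
    basal_end = np.where(
        frame["strand"] == "+",
        frame["tss"] + basal_downstream,
        frame["tss"] + basal_upstream,
    )
    frame["basal_start"] = np.maximum(1, basal_start)
    frame["basal_end"] = np.maximum(1, basal_end)

    domains: list[RegulatoryDomain] = []
    for _, chrom_genes in frame.groupby("chrom", sort=False):
        ordered = chrom_genes.sort_values(["tss", "gene"]).reset_index(drop=True)
        for i, row in ordered.iterrows():
            ext_start = max(1, row["tss"] - max_extension, 1)
            ext_end = row["tss"] + max_extension
            # stop at the neighbors' basal domains, but never inside our own basal
            if i > 0:
                ext_start = max(ext_start, int(ordered.loc[i - 1, "basal_end"]) + 1)
            if i < len(ordered) - 1:
                ext_end = min(ext_end, int(ordered.loc[i + 1, "basal_start"]) - 1)
            ext_start = min(ext_start, int(row["basal_start"]))
            ext_end = max(ext_end, int(row["basal_end"]))
            domains.append(
                RegulatoryDomain(
                    gene=str(row["gene"]),
                    chrom=str(row["chrom"]),
                    basal_start=int(row["basal_start"]),
                    basal_end=int(row["basal_end"]),
                    ext_start=int(ext_start),
                    ext_end=int(ext_end),
                )
            )
    return domains


def map_cpgs_to_genes(
    cpgs: pd.DataFrame, domains: Sequence[RegulatoryDomain]
) -> dict[str, frozenset[str]]:
    """Associate each CpG with every gene whose extended domain contains it.

    ``cpgs`` needs columns cpg_id, chrom, pos (1-based).  A CpG may map to
    several genes (overlapping domains) or to none; CpGs on chromosomes
    absent from the domain list are unmapped.
    """
    required = {"cpg_id", "chrom", "pos"}
    if not required <= set(cpgs.columns):
        raise ValueError(f"cpg table needs columns {sorted(required)}")
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        # interval tree uses half-open [start, end); domains are inclusive
        trees.setdefault(d.chrom, IntervalTree()).addi(d.ext_start, d.ext_end + 1, d.gene)
    mapping: dict[str, frozenset[str]] = {}
    for row in cpgs.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is None:
            mapping[str(row.cpg_id)] = frozenset()
            continue
        mapping[str(row.cpg_id)] = frozenset(iv.data for iv in tree.at(int(row.pos)))
    return mapping


def _adjust(frame: pd.DataFrame, p_col: str) -> pd.DataFrame:
    """Bonferroni and Benjamini-Hochberg columns for one p-value family."""
    m = len(frame)
    frame = frame.copy()
    frame["p_bonferroni"] = np.minimum(frame[p_col] * m, 1.0)
    order = frame[p_col].to_numpy().argsort(kind="stable")
    ranked = frame[p_col].to_numpy()[order]
    q = ranked * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q_bh = np.empty(m)
    q_bh[order] = np.minimum(q, 1.0)
    frame["q_bh"] = q_bh
    return frame


def _filter_sets(
    gene_sets: Mapping[str, Iterable[str]],
    universe: frozenset[str],
    size_bounds: tuple[int, int],
) -> dict[str, frozenset[str]]:
    lo, hi = size_bounds
    out = {}
    for name, members in gene_sets.items():
        inter = frozenset(members) & universe
        if lo <= len(inter) <= hi:
            out[name] = inter
    return out


def hypergeometric_gene_test(
    foreground: Sequence[str],
    background: Sequence[str],
    mapping: Mapping[str, frozenset[str]],
    gene_sets: Mapping[str, Iterable[str]],
    size_bounds: tuple[int, int] = (10, 3000),
) -> pd.DataFrame:
    """Gene-level over-representation test conditioned on the array background.

    The gene universe is the set of genes hit by at least one background
    CpG; the foreground gene list is the genes hit by at least one
    foreground CpG (a CpG mapping to k genes contributes each once).  For a
    set with K universe genes, p = P(X >= k) with X hypergeometric
    (N universe genes, K set genes, n foreground genes).  Gene sets are
    size-filtered on their universe overlap.  Returns one row per set with
    Bonferroni and BH columns.
    """
    fg = set(map(str, foreground))
    bg = set(map(str, background))
    if not fg <= bg:
        raise ValueError("foreground CpGs must be a subset of the background")
    universe = frozenset().union(*(mapping.get(c, frozenset()) for c in bg)) if bg else frozenset()
    fg_genes = frozenset().union(*(mapping.get(c, frozenset()) for c in fg)) if fg else frozenset()
    fg_genes = fg_genes & universe
    sets = _filter_sets(gene_sets, universe, size_bounds)
    if not sets:
        raise ValueError("no gene set within size bounds after universe restriction")
    n_universe = len(universe)
    n_fg = len(fg_genes)
    rows = []
    for name in sorted(sets):
        members = sets[name]
        k = len(fg_genes & members)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(members), n_fg))
        rows.append(
            {
                "gene_set": name,
                "n_fg_hits": k,
                "n_fg": n_fg,
                "n_set": len(members),
                "n_universe": n_universe,
                "p_hypergeometric": min(max(p, 0.0), 1.0),
            }
        )
    return _adjust(pd.DataFrame(rows).set_index("gene_set"), "p_hypergeometric")


def binomial_region_test(
    foreground: Sequence[str],
    background: Sequence[str],
    mapping: Mapping[str, frozenset[str]],
    gene_sets: Mapping[str, Iterable[str]],
    size_bounds: tuple[int, int] = (10, 3000),
) -> pd.DataFrame:
    """Region-level binomial test.

    p0 is the fraction of background CpGs whose position falls in any of the
    set's regulatory domains; the test asks whether the count of foreground
    CpGs in those domains exceeds Binomial(n_fg, p0) expectations.  p0 = 0
    with foreground hits is degenerate and flagged (p reported as 0).
    """
    fg = list(dict.fromkeys(map(str, foreground)))
    bg = list(dict.fromkeys(map(str, background)))
    if not set(fg) <= set(bg):
        raise ValueError("foreground CpGs must be a subset of the background")
    universe = frozenset().union(*(mapping.get(c, frozenset()) for c in bg)) if bg else frozenset()
    sets = _filter_sets(gene_sets, universe, size_bounds)
    if not sets:
        raise ValueError("no gene set within size bounds after universe restriction")
    rows = []
    n_bg = len(bg)
    n_fg = len(fg)
    for name in sorted(sets):
        members = sets[name]
        bg_hits = sum(1 for c in bg if mapping.get(c, frozenset()) & members)
        k = sum(1 for c in fg if mapping.get(c, frozenset()) & members)
        p0 = bg_hits / n_bg if n_bg else 0.0
        degenerate = p0 == 0.0 and k > 0
        if degenerate:
            p = 0.0
        elif k == 0:
            p = 1.0
        else:
            p = float(stats.binom.sf(k - 1, n_fg, p0))
        rows.append(
            {
                "gene_set": name,
                "n_fg_hits": k,
                "n_fg": n_fg,
                "n_bg_hits": bg_hits,
                "n_bg": n_bg,
                "p0": p0,
                "p_binomial": min(max(p, 0.0), 1.0),
                "degenerate": degenerate,
            }
        )
    return _adjust(pd.DataFrame(rows).set_index("gene_set"), "p_binomial")


def select_foreground(
    stats_table: pd.DataFrame,
    n_per_direction: int = 500,
    effect_col: str | None = None,
) -> tuple[list[str], list[str]]:
    """Top-n CpG ids per direction (increased, decreased) by significance.

    Ranking is by p ascending, then |effect| descending, then cpg_id — the
    last key makes ties deterministic.
    """
    frame = stats_table.copy()
    if effect_col is None:
        effect_col = next((c for c in ("effect", "z", "r") if c in frame.columns), None)
        if effect_col is None:
            raise ValueError("stats table needs an effect/z/r column")
    if "direction" not in frame.columns:
        frame["direction"] = np.sign(frame[effect_col]).astype(int)
    frame["_abs"] = frame[effect_col].abs()
    frame["_cpg"] = frame.index.astype(str)
    result = []
    for direction in (1, -1):
        sub = frame[frame["direction"] == direction].sort_values(
            ["p", "_abs", "_cpg"], ascending=[True, False, True]
        )
        result.append(list(sub.index[:n_per_direction].astype(str)))
    return result[0], result[1]


def enrich(
    stats_table: pd.DataFrame,
    manifest: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: Mapping[str, Iterable[str]],
    n_per_direction: int = 500,
    size_bounds: tuple[int, int] = (10, 3000),
) -> dict[str, pd.DataFrame]:
    """End-to-end enrichment of an EWAS table: one result per direction.

    Builds domains from ``genes``, maps all manifest CpGs, selects the top
    ``n_per_direction`` foreground CpGs each way, and runs both tests; the
    multiplicity family is (direction x test) as the per-direction tables
    come out already adjusted.
    """
    domains = build_regulatory_domains(genes)
    cpg_table = manifest.reset_index(drop=True)[["cpg_id", "chrom", "pos"]]
    mapping = map_cpgs_to_genes(cpg_table, domains)
    background = [c for c in cpg_table["cpg_id"].astype(str) if c in stats_table.index]
    increased, decreased = select_foreground(stats_table, n_per_direction)
    out: dict[str, pd.DataFrame] = {}
    for name, fg in (("increased", increased), ("decreased", decreased)):
        fg = [c for c in fg if c in set(background)]
        hyper = hypergeometric_gene_test(fg, background, mapping, gene_sets, size_bounds)
        binom = binomial_region_test(fg, background, mapping, gene_sets, size_bounds)
        binom = binom.rename(
            columns={
                "n_fg_hits": "n_fg_region_hits",
                "p_bonferroni": "p_bonferroni_binomial",
                "q_bh": "q_bh_binomial",
            }
        )[["n_fg_region_hits", "n_bg_hits", "n_bg", "p0", "p_binomial",
           "p_bonferroni_binomial", "q_bh_binomial", "degenerate"]]
        out[name] = hyper.join(binom, how="outer")
    return out
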
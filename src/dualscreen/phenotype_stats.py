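"""Per-screen scoring chain for pooled dual-guide screens.

Pipeline, per screen: drop guides with fewer than ``min_count`` reads in
either member of the compared sample pair; compute the log2
relative-frequency enrichment of each surviving guide between the two
samples (pseudocount-guarded); center on the median of the passing
negative-control guides; average guide phenotypes across replicates;
score each gene as the signed mean of its strongest-``k`` guides; test
each gene's guides against the negative controls with a two-sided
Mann-Whitney U; combine phenotype and significance into a discriminant
score; and rank genes from lowest to highest discriminant.

Growth screens run the same chain on (day18, day0) columns and divide by
the number of doublings to give a per-doubling gamma.
"""

from __future__ import annotations

import itertools
import json
import math
import sys
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from dualscreen.counts_io import CountTable, SampleKey
from dualscreen.library_design import GuideRecord

__all__ = [
    "StatsConfig",
    "filter_low_counts",
    "guide_phenotype",
    "normalize_to_controls",
    "average_replicates",
    "gene_phenotype",
    "mw_pvalue",
    "discriminant",
    "rank_genes",
    "growth_gamma",
    "screen_guide_phenotypes",
    "gene_statistics",
    "analyze_screen",
    "write_gene_stats",
    "read_gene_stats",
]


@dataclass
class StatsConfig:
    min_count: int = 50
    k_strongest: int = 3
    pseudocount: float = 1.0
    discriminant_mode: str = "neglog_product"  # or "literal_product"
    mw_exact_max: int = 100
    alpha: float = 0.05
    min_abs_phenotype: float = 0.1

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.k_strongest < 1:
            raise ValueError("k_strongest must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.discriminant_mode not in (
            "neglog_product",
            "literal_product",
        ):
            raise ValueError(
                "discriminant_mode must be 'neglog_product' or "
                "'literal_product'"
            )


def filter_low_counts(
    table: CountTable, pair: tuple[str, str], min_count: int
) -> np.ndarray:
    """Boolean pass mask: count >= ``min_count`` in BOTH columns of the
    compared pair ("fewer than ``min_count``" excludes strictly-below)."""
    a = table.column(pair[0])
    b = table.column(pair[1])
    return (a >= min_count) & (b >= min_count)


def guide_phenotype(high, low, t_high, t_low, pseudocount: float = 1.0):
    """Raw log2 enrichment of a guide between two samples.

    ``log2(((high + pc) / t_high) / ((low + pc) / t_low))`` where the
    totals are pseudocount-adjusted column totals. Accepts scalars or
    arrays.
    """
    if np.any(np.asarray(t_high) <= 0) or np.any(np.asarray(t_low) <= 0):
        raise ValueError("column totals must be positive")
    num = (np.asarray(high, dtype=float) + pseudocount) / t_high
    den = (np.asarray(low, dtype=float) + pseudocount) / t_low
    out = np.log2(num / den)
    return float(out) if np.isscalar(high) else out


def normalize_to_controls(
    raw: np.ndarray, nt_flags: np.ndarray
) -> np.ndarray:
    """Center phenotypes on the median of the (passing) negative controls.

    ``raw`` may contain NaN for filtered-out guides; those stay NaN and
    are ignored when computing the control median. After centering, the
    control median is driven to exactly zero (tiny floating residuals are
    re-subtracted).
    """
    raw = np.asarray(raw, dtype=float)
    nt_flags = np.asarray(nt_flags, dtype=bool)
    nt_values = raw[nt_flags & ~np.isnan(raw)]
    if nt_values.size == 0:
        raise ValueError("no passing negative-control guides to normalize to")
    out = raw - np.median(nt_values)
    for _ in range(3):  # polish away even-count median rounding
        residual = np.median(out[nt_flags & ~np.isnan(out)])
        if residual == 0.0:
            break
        out = out - residual
    return out


def average_replicates(per_replicate: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean over replicates in which the element passed
    (non-NaN); elements failing every replicate stay NaN."""
    if not per_replicate:
        raise ValueError("no replicates supplied")
    stacked = np.vstack([np.asarray(r, dtype=float) for r in per_replicate])
    if not (~np.isnan(stacked)).any():
        raise ValueError("no element passes in any replicate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(stacked, axis=0)


def gene_phenotype(
    phenotypes: Sequence[float],
    k_strongest: int,
    element_ids: Optional[Sequence[str]] = None,
) -> float:
    """Signed mean of the ``k`` guides with largest \\|phenotype\\|.

    ``k`` is capped at the number of available guides; ties at the k-th
    slot are broken by element_id order for determinism.
    """
    values = [float(v) for v in phenotypes if not math.isnan(v)]
    if element_ids is None:
        ids = [f"{i:06d}" for i in range(len(values))]
    else:
        ids = [
            str(e)
            for e, v in zip(element_ids, phenotypes)
            if not math.isnan(float(v))
        ]
    if not values:
        raise ValueError("gene has no passing guides")
    order = sorted(
        range(len(values)), key=lambda i: (-abs(values[i]), ids[i])
    )
    chosen = order[: min(k_strongest, len(values))]
    return float(np.mean([values[i] for i in chosen]))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with half-credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _mw_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) label assignments.

    p = fraction of assignments whose U deviates from nm/2 at least as far
    as the observed U (ties handled by half-credit, so the enumeration is
    valid under ties as well).
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    center = n * m / 2.0
    observed = abs(_u_statistic(x, y) - center)
    total = 0
    at_least = 0
    indices = range(n + m)
    for combo in itertools.combinations(indices, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(combo)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= observed - 1e-12:
            at_least += 1
    return at_least / total


def mw_pvalue(
    gene_values: Sequence[float],
    control_values: Sequence[float],
    exact_max: int = 100,
) -> float:
    """Two-sided Mann-Whitney p of a gene's guides vs negative controls.

    Exact by full enumeration when ``n*m <= exact_max``; otherwise the
    normal approximation with tie and continuity corrections. Clamped to
    (0, 1].
    """
    x = np.asarray(list(gene_values), dtype=float)
    y = np.asarray(list(control_values), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return 1.0  # fully tied: no evidence either way
    if x.size * y.size <= exact_max:
        p = _mw_exact(x, y)
    else:
        result = _scipy_stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        p = float(result.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return min(max(p, sys.float_info.min), 1.0)


def discriminant(
    phenotype_score: float, p_value: float, mode: str = "neglog_product"
) -> float:
    """Combine phenotype and significance into one ranking score.

    ``neglog_product``: phenotype x (-log10 p) — strong, significant hits
    get large-magnitude scores. ``literal_product``: phenotype x p.
    """
    if p_value <= 0.0:
        warnings.warn(
            "p-value <= 0 clamped to machine minimum before log",
            RuntimeWarning,
            stacklevel=2,
        )
        p_value = sys.float_info.min
    if p_value > 1.0:
        raise ValueError("p-value must be in (0, 1]")
    if mode == "neglog_product":
        return phenotype_score * (-math.log10(p_value))
    if mode == "literal_product":
        return phenotype_score * p_value
    raise ValueError(f"unknown discriminant mode {mode!r}")


def rank_genes(gene_table: pd.DataFrame) -> pd.Series:
    """Rank 1 = lowest (most negative) discriminant.

    Ties are broken by \\|phenotype_score\\| descending, then gene name
    ascending, giving a deterministic total order.
    """
    df = gene_table[["gene", "discriminant", "phenotype_score"]].copy()
    df["_abs"] = -df["phenotype_score"].abs()
    order = df.sort_values(
        ["discriminant", "_abs", "gene"], kind="stable"
    ).index
    ranks = pd.Series(0, index=gene_table.index, dtype=int)
    ranks.loc[order] = np.arange(1, len(df) + 1)
    return ranks


def growth_gamma(
    enrichment: np.ndarray, doublings: float
) -> np.ndarray:
    """Per-doubling growth phenotype from a centered log2 enrichment."""
    if doublings <= 0:
        raise ValueError("doublings must be positive")
    return np.asarray(enrichment, dtype=float) / doublings


# ---------------------------------------------------------------------------
# Full-screen drivers


def _replicate_pairs(
    table: CountTable, library_label: str, mode: str
) -> list[tuple[str, str, str]]:
    """(replicate, numerator sample, denominator sample) for one screen."""
    if mode == "facs":
        num_bin, den_bin = "high", "low"
    elif mode == "growth":
        num_bin, den_bin = "day18", "day0"
    else:
        raise ValueError("mode must be 'facs' or 'growth'")
    keys = [SampleKey.parse(s) for s in table.samples]
    reps = sorted(
        {k.replicate for k in keys if k.library == library_label}
    )
    if not reps:
        raise ValueError(
            f"no samples for library {library_label!r} in table "
            f"(samples: {table.samples})"
        )
    pairs = []
    for rep in reps:
        num = f"{library_label}.{rep}.{num_bin}"
        den = f"{library_label}.{rep}.{den_bin}"
        if num not in table.samples or den not in table.samples:
            raise ValueError(
                f"replicate {rep} of {library_label!r} is missing its "
                f"{num_bin}/{den_bin} pair"
            )
        pairs.append((rep, num, den))
    return pairs


def screen_guide_phenotypes(
    table: CountTable,
    library_records: Sequence[GuideRecord],
    library_label: str,
    config: StatsConfig = StatsConfig(),
    mode: str = "facs",
    doublings: float = 10.0,
) -> pd.DataFrame:
    """Replicate-averaged, control-centered guide phenotypes for one screen.

    Returns a frame with element_id, gene, is_negative_control,
    phenotype (NaN when failing every replicate), and
    n_replicates_passing.
    """
    by_id = {rec.element_id: rec for rec in library_records}
    missing = [e for e in table.elements if e not in by_id]
    if missing:
        raise KeyError(
            f"count-table elements absent from library: {missing[:10]}"
        )
    nt_flags = np.array(
        [by_id[e].is_negative_control for e in table.elements]
    )

    per_replicate: list[np.ndarray] = []
    for _rep, num, den in _replicate_pairs(table, library_label, mode):
        passed = filter_low_counts(table, (num, den), config.min_count)
        if not (passed & nt_flags).any():
            raise ValueError(
                f"no negative-control guide passes the {config.min_count}-"
                f"count filter in pair ({num}, {den})"
            )
        high = table.column(num).astype(float)
        low = table.column(den).astype(float)
        n_passing = int(passed.sum())
        t_high = high[passed].sum() + config.pseudocount * n_passing
        t_low = low[passed].sum() + config.pseudocount * n_passing
        raw = np.full(len(table.elements), np.nan)
        raw[passed] = guide_phenotype(
            high[passed], low[passed], t_high, t_low, config.pseudocount
        )
        per_replicate.append(normalize_to_controls(raw, nt_flags))

    averaged = average_replicates(per_replicate)
    if mode == "growth":
        averaged = growth_gamma(averaged, doublings)
    n_passing_reps = np.sum(
        ~np.isnan(np.vstack(per_replicate)), axis=0
    )
    return pd.DataFrame(
        {
            "element_id": table.elements,
            "gene": [by_id[e].gene for e in table.elements],
            "is_negative_control": nt_flags,
            "phenotype": averaged,
            "n_replicates_passing": n_passing_reps,
        }
    )


def gene_statistics(
    guide_table: pd.DataFrame, config: StatsConfig = StatsConfig()
) -> pd.DataFrame:
    """Gene-level scores from a replicate-averaged guide table.

    Genes with zero passing guides are excluded from the output (and thus
    from ranking); genes with fewer than ``k_strongest`` passing guides
    are scored on what is available and flagged via n_guides_passing.
    """
    passing = guide_table.dropna(subset=["phenotype"])
    controls = passing.loc[
        passing["is_negative_control"], "phenotype"
    ].to_numpy()
    if controls.size == 0:
        raise ValueError("no passing negative-control guides")

    rows = []
    targeting = passing[~passing["is_negative_control"]]
    for gene, group in targeting.groupby("gene", sort=True):
        values = group["phenotype"].to_numpy()
        score = gene_phenotype(
            values, config.k_strongest, group["element_id"].tolist()
        )
        p = mw_pvalue(values, controls, exact_max=config.mw_exact_max)
        rows.append(
            {
                "gene": gene,
                "phenotype_score": score,
                "p_value": p,
                "discriminant": discriminant(
                    score, p, config.discriminant_mode
                ),
                "n_guides_passing": len(values),
            }
        )
    if not rows:
        raise ValueError("no scorable genes")
    out = pd.DataFrame(rows)
    out["rank"] = rank_genes(out)
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def analyze_screen(
    table: CountTable,
    library_records: Sequence[GuideRecord],
    library_label: str,
    config: StatsConfig = StatsConfig(),
    mode: str = "facs",
    doublings: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain for one screen: guide phenotypes then gene statistics."""
    guides = screen_guide_phenotypes(
        table, library_records, library_label, config, mode, doublings
    )
    genes = gene_statistics(guides, config)
    return guides, genes


def write_gene_stats(
    genes: pd.DataFrame,
    path: str | Path,
    config: Optional[StatsConfig] = None,
    metadata_path: str | Path | None = None,
    **metadata,
) -> None:
    genes.to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        payload = dict(metadata)
        if config is not None:
            payload["config"] = asdict(config)
        with open(metadata_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_gene_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "phenotype_score", "p_value", "discriminant", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene-stats TSV missing columns: {sorted(missing)}")
    return df
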
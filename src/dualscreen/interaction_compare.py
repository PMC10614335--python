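"""Anchored-vs-control screen comparison and interaction classification.

Genes scored in both a non-targeting-anchored screen and a gene-anchored
screen are compared by phenotype, significance, and discriminant rank.
Enhanced phenotypes in the anchored screen indicate synthetic
(parallel-pathway) interactions; diminished phenotypes indicate
same-pathway membership; unchanged significant phenotypes indicate
orthogonal factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CompareConfig",
    "CATEGORIES",
    "rank_delta",
    "classify",
    "compare_report",
    "expected_category",
]

CATEGORIES = ("synthetic", "same_pathway", "orthogonal", "null")

#: Ground-truth category -> expected interaction call under a pathway-A
#: anchor (used for the truth-vs-call confusion matrix).
_TRUTH_TO_CALL = {
    "pathway_A_member": "same_pathway",
    "pathway_B_member": "synthetic",
    "stabilizer": "orthogonal",
    "expression_only": "null",
    "null": "null",
}


@dataclass
class CompareConfig:
    alpha: float = 0.05
    min_abs_phenotype: float = 0.2
    enhancement_factor: float = 0.3  # tau

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.enhancement_factor <= 0:
            raise ValueError("enhancement_factor must be positive")


def expected_category(truth_category: str) -> str:
    """Expected interaction call for a ground-truth gene category."""
    return _TRUTH_TO_CALL[truth_category]


def rank_delta(nt: pd.DataFrame, anchor: pd.DataFrame) -> pd.DataFrame:
    """Per-gene discriminant-rank change between the two screens.

    delta = rank_nt - rank_anchor over the gene intersection; genes
    scored in only one screen are returned separately in the
    ``only_nt`` / ``only_anchor`` frame attributes of the result.
    """
    merged = nt.merge(
        anchor, on="gene", how="inner", suffixes=("_nt", "_anchor")
    )
    if merged.empty:
        raise ValueError("no genes scored in both screens")
    merged["rank_delta"] = (
        merged["rank_nt"].astype(int) - merged["rank_anchor"].astype(int)
    )
    merged.attrs["only_nt"] = sorted(
        set(nt["gene"]) - set(anchor["gene"])
    )
    merged.attrs["only_anchor"] = sorted(
        set(anchor["gene"]) - set(nt["gene"])
    )
    return merged


def _significant(
    phenotype: float, p: float, config: CompareConfig
) -> bool:
    return p <= config.alpha and abs(phenotype) >= config.min_abs_phenotype


def classify(
    phenotype_nt: float,
    p_nt: float,
    phenotype_anchor: float,
    p_anchor: float,
    config: CompareConfig = CompareConfig(),
) -> str:
    """Interaction category for one gene scored in both screens.

    Rules (first match wins), with sig(s) = p <= alpha and \\|phenotype\\|
    >= min_abs_phenotype, tau = enhancement_factor:

    1. synthetic — anchored hit at least (1+tau)-fold stronger than the
       control-screen phenotype, same sign (or no control-screen hit);
    2. same_pathway — control-screen hit that shrinks below (1-tau)-fold
       (or loses significance) in the anchored screen;
    3. orthogonal — hits in both screens with phenotypes closer than
       tau x max(\\|phenotype_nt\\|, min_abs_phenotype);
    4. null — everything else.
    """
    tau = config.enhancement_factor
    sig_nt = _significant(phenotype_nt, p_nt, config)
    sig_anchor = _significant(phenotype_anchor, p_anchor, config)
    same_sign = phenotype_nt * phenotype_anchor >= 0

    if (
        sig_anchor
        and abs(phenotype_anchor) >= (1 + tau) * abs(phenotype_nt)
        and (same_sign or not sig_nt)
    ):
        return "synthetic"
    if sig_nt and (
        not sig_anchor
        or abs(phenotype_anchor) <= (1 - tau) * abs(phenotype_nt)
    ):
        return "same_pathway"
    if (
        sig_nt
        and sig_anchor
        and abs(phenotype_anchor - phenotype_nt)
        < tau * max(abs(phenotype_nt), config.min_abs_phenotype)
    ):
        return "orthogonal"
    return "null"


def compare_report(
    nt: pd.DataFrame,
    anchor: pd.DataFrame,
    config: CompareConfig = CompareConfig(),
    anchor_gene: Optional[str] = None,
    truth: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, dict]:
    """Full per-gene interaction table plus a summary.

    The table is ordered by anchored-screen rank and contains phenotypes,
    p-values, ranks, rank_delta, the category, and an ``is_anchor`` flag.
    The anchor gene's own row (self-combination: double knockdown) is
    annotated and excluded from the summary counts and from the
    truth-vs-call confusion matrix (supplied via ``truth`` with columns
    gene, category).
    """
    merged = rank_delta(nt, anchor)
    merged["category"] = [
        classify(
            row.phenotype_score_nt,
            row.p_value_nt,
            row.phenotype_score_anchor,
            row.p_value_anchor,
            config,
        )
        for row in merged.itertuples()
    ]
    merged["is_anchor"] = (
        merged["gene"] == anchor_gene if anchor_gene else False
    )
    columns = [
        "gene",
        "phenotype_score_nt",
        "p_value_nt",
        "rank_nt",
        "phenotype_score_anchor",
        "p_value_anchor",
        "rank_anchor",
        "rank_delta",
        "category",
        "is_anchor",
    ]
    table = (
        merged[columns]
        .sort_values("rank_anchor", kind="stable")
        .reset_index(drop=True)
    )

    body = table[~table["is_anchor"]]
    summary: dict = {
        "n_genes": int(len(table)),
        "category_counts": {
            c: int((body["category"] == c).sum()) for c in CATEGORIES
        },
        "only_nt": merged.attrs["only_nt"],
        "only_anchor": merged.attrs["only_anchor"],
    }
    if anchor_gene is not None:
        anchor_rows = table[table["is_anchor"]]
        summary["anchor_gene"] = anchor_gene
        summary["anchor_row"] = (
            anchor_rows.iloc[0].to_dict() if len(anchor_rows) else None
        )
    if truth is not None:
        summary["confusion"] = _confusion(body, truth)
    return table, summary


def _confusion(table: pd.DataFrame, truth: pd.DataFrame) -> dict:
    merged = table.merge(
        truth[["gene", "category"]].rename(
            columns={"category": "truth_category"}
        ),
        on="gene",
        how="inner",
    )
    matrix: dict[str, dict[str, int]] = {}
    for truth_cat, group in merged.groupby("truth_category"):
        matrix[str(truth_cat)] = {
            c: int((group["category"] == c).sum()) for c in CATEGORIES
        }
    agreement = (
        merged["category"]
        == merged["truth_category"].map(_TRUTH_TO_CALL)
    )
    matrix["_agreement"] = {
        "n": int(len(merged)),
        "n_agree": int(agreement.sum()),
    }
    return matrix


def write_compare_outputs(
    table: pd.DataFrame,
    summary: dict,
    out_dir: str | Path,
) -> None:
    """InteractionCall TSV, summary JSON, and rank-vs-rank scatter TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "interactions.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    table[["gene", "rank_nt", "rank_anchor", "category"]].to_csv(
        out_dir / "rank_scatter.tsv", sep="\t", index=False
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
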
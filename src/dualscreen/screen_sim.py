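"""Synthetic dual-guide FACS reporter-screen generator.

The reporter model has two partially redundant pathways (A and B) plus a
background route. Each pathway's residual activity under a set of
knockdowns is the product of ``1 - strength * efficacy`` over the
knockdowns targeting it, and the reporter log2 ratio is the log of the
summed residual flux. Within a pathway an already-ablated route masks
further knockdowns; across pathways knockdowns synergize, collapsing the
ratio toward the background flux. Stabilizer knockdowns raise the ratio
(``+log2(1 + strength * efficacy)``); expression-only knockdowns cancel in
the ratio and contribute nothing.

A simulated screen draws per-guide efficacies, computes each element's
expected ratio (with the anchored library's fixed guide attenuated by an
interference factor), adds Gaussian cell noise, sorts cells into
high/low tail gates at a global quantile, and samples sequencing reads
multinomially per bin at a fixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from dualscreen.counts_io import CountTable, ReadLayout, merge_tables
from dualscreen.library_design import DualLibrary, GuideRecord

__all__ = [
    "CATEGORIES",
    "PathwayModel",
    "TrueEffect",
    "SimConfig",
    "Scenario",
    "SimulatedScreen",
    "expected_log_ratio",
    "element_expected_ratios",
    "simulate_cells",
    "simulate_sort",
    "simulate_counts",
    "simulate_growth",
    "generate_dataset",
    "default_scenario",
    "make_guide_library",
    "write_synthetic_fastq",
]

CATEGORIES = (
    "pathway_A_member",
    "pathway_B_member",
    "stabilizer",
    "expression_only",
    "null",
)

#: Gene label used for non-targeting control guides.
NT_GENE = "negative_control"


@dataclass(frozen=True)
class PathwayModel:
    """Relative flux carried by pathways A, B and the background route."""

    flux_a: float = 0.475
    flux_b: float = 0.475
    flux_bg: float = 0.05

    def __post_init__(self) -> None:
        if self.flux_a < 0 or self.flux_b < 0 or self.flux_bg < 0:
            raise ValueError("fluxes must be non-negative")
        if self.flux_a + self.flux_b + self.flux_bg <= 0:
            raise ValueError("total flux must be positive")


@dataclass(frozen=True)
class TrueEffect:
    """Ground-truth role of one gene."""

    gene: str
    category: str
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        if self.category == "null" and self.strength != 0.0:
            raise ValueError("null genes must have strength 0")


@dataclass
class SimConfig:
    """Knobs for one simulated screen."""

    n_genes: int = 300
    guides_per_gene: int = 5
    n_negative_control_guides: int = 250
    anchor_gene: Optional[str] = None
    anchor_efficacy: float = 0.95
    interference_rho: float = 0.8
    efficacy_distribution: str = "beta"  # "beta" or "ladder"
    efficacy_params: tuple = (8.0, 2.0)
    efficacy_ladder: tuple = (0.9, 0.8, 0.7, 0.5, 0.3)
    cell_noise_sd: float = 1.0
    cells_per_element: int = 1000
    gate_fraction: float = 0.30
    read_depth_per_bin: int = 5_000_000
    n_replicates: int = 2
    doublings: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gate_fraction < 0.5:
            raise ValueError("gate_fraction must be in (0, 0.5)")
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        if not 0.0 < self.interference_rho <= 1.0:
            raise ValueError("interference_rho must be in (0, 1]")
        for name in (
            "n_genes",
            "n_negative_control_guides",
            "cells_per_element",
            "read_depth_per_bin",
            "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Scenario:
    """How many genes of each ground-truth category to plant."""

    n_pathway_a: int = 8
    n_pathway_b: int = 10
    n_stabilizers: int = 5
    n_expression_only: int = 5
    pathway_strength: float = 0.9
    stabilizer_strength: float = 0.5
    expression_strength: float = 0.5
    growth_fitness: dict = field(default_factory=dict)

    @property
    def n_special(self) -> int:
        return (
            self.n_pathway_a
            + self.n_pathway_b
            + self.n_stabilizers
            + self.n_expression_only
        )


def default_scenario() -> Scenario:
    return Scenario()


@dataclass
class SimulatedScreen:
    """Simulator output bundle: counts, ground truth, per-guide efficacy."""

    counts: CountTable
    truth: pd.DataFrame
    efficacies: pd.DataFrame
    library: DualLibrary
    config: SimConfig
    anchor_gene: Optional[str] = None

    def write_outputs(self, out_dir: str | Path) -> None:
        from dualscreen.counts_io import write_count_table
        from dualscreen.library_design import write_library_tsv

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_count_table(self.counts, out_dir / "counts.tsv")
        self.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        self.efficacies.to_csv(
            out_dir / "efficacies.tsv", sep="\t", index=False
        )
        write_library_tsv(self.library.elements, out_dir / "library.tsv")
        cfg = asdict(self.config)
        cfg["anchor_gene"] = self.anchor_gene
        for key, value in cfg.items():
            if isinstance(value, tuple):
                cfg[key] = list(value)
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Expected-ratio model


def expected_log_ratio(
    effects: Sequence[tuple[TrueEffect, float]],
    anchor: Optional[tuple[TrueEffect, float, float]] = None,
    model: PathwayModel = PathwayModel(),
) -> float:
    """Expected reporter log2 ratio under a set of knockdowns.

    ``effects`` pairs each knocked-down gene's :class:`TrueEffect` with the
    guide efficacy achieved. ``anchor``, if given, is ``(effect, efficacy,
    interference_rho)`` for the fixed guide; its efficacy is attenuated by
    ``rho``. Two knockdowns of the same gene enter the pathway product
    independently, so they compose as
    ``1 - (1 - s*e1) * (1 - s*e2*rho)``.
    """
    instances: list[tuple[TrueEffect, float]] = []
    for effect, efficacy in effects:
        _check_unit("efficacy", efficacy)
        instances.append((effect, efficacy))
    if anchor is not None:
        effect, efficacy, rho = anchor
        _check_unit("anchor efficacy", efficacy)
        if not 0.0 < rho <= 1.0:
            raise ValueError("interference rho must be in (0, 1]")
        instances.append((effect, efficacy * rho))

    act_a = 1.0
    act_b = 1.0
    stabilizer_term = 0.0
    for effect, efficacy in instances:
        knockdown = effect.strength * efficacy
        if effect.category == "pathway_A_member":
            act_a *= 1.0 - knockdown
        elif effect.category == "pathway_B_member":
            act_b *= 1.0 - knockdown
        elif effect.category == "stabilizer":
            stabilizer_term += np.log2(1.0 + knockdown)
        # expression_only and null contribute nothing: the reporter is a
        # ratio, so global expression effects cancel.
    flux = model.flux_a * act_a + model.flux_b * act_b + model.flux_bg
    with np.errstate(divide="ignore"):
        return float(np.log2(flux) + stabilizer_term)


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def element_expected_ratios(
    library: DualLibrary | Sequence[GuideRecord],
    truth: Mapping[str, TrueEffect],
    efficacies: Mapping[str, float],
    model: PathwayModel = PathwayModel(),
    anchor: Optional[tuple[TrueEffect, float, float]] = None,
) -> np.ndarray:
    """Expected log2 ratio for every library element, in element order."""
    elements = (
        library.elements if isinstance(library, DualLibrary) else list(library)
    )
    unknown = sorted(
        {
            rec.gene
            for rec in elements
            if not rec.is_negative_control and rec.gene not in truth
        }
    )
    if unknown:
        raise KeyError(f"genes missing from truth table: {unknown[:10]}")
    out = np.empty(len(elements))
    for i, rec in enumerate(elements):
        effects = (
            []
            if rec.is_negative_control
            else [(truth[rec.gene], efficacies[rec.element_id])]
        )
        out[i] = expected_log_ratio(effects, anchor=anchor, model=model)
    return out


# ---------------------------------------------------------------------------
# Cell-level simulation


def simulate_cells(
    expected: np.ndarray,
    cells_per_element: int,
    cell_noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell log2 ratios: ``expected[element] + Normal(0, sd)``.

    Returns ``(element_index, ratio)`` arrays of length
    ``n_elements * cells_per_element``.
    """
    n_elements = len(expected)
    element_index = np.repeat(
        np.arange(n_elements, dtype=np.int32), cells_per_element
    )
    ratios = np.repeat(np.asarray(expected, dtype=float), cells_per_element)
    if cell_noise_sd > 0:
        ratios = ratios + rng.normal(0.0, cell_noise_sd, size=ratios.size)
    return element_index, ratios


def simulate_sort(
    ratios: np.ndarray, gate_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Global tail gates: indices of the top and bottom ``gate_fraction``.

    Gates are quantiles over the pooled population. Both gates contain
    exactly ``round(gate_fraction * n_cells)`` cells; ties are broken by
    stable (input-order) sorting.
    """
    if not 0.0 < gate_fraction < 0.5:
        raise ValueError("gate_fraction must be in (0, 0.5)")
    ratios = np.asarray(ratios)
    n = ratios.size
    if n < 4:
        raise ValueError("need at least 4 cells to sort")
    n_gate = int(round(gate_fraction * n))
    order = np.argsort(ratios, kind="stable")
    low = order[:n_gate]
    high = order[n - n_gate :]
    return high, low


def simulate_counts(
    bin_cell_counts: np.ndarray,
    read_depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial sequencing draw over one sorted bin.

    Probabilities are proportional to each element's cell count in the
    bin; the returned column sums to ``read_depth`` exactly.
    """
    if read_depth <= 0:
        raise ValueError("read depth must be positive")
    bin_cell_counts = np.asarray(bin_cell_counts, dtype=float)
    total = bin_cell_counts.sum()
    if total <= 0:
        raise ValueError("bin contains no cells")
    return rng.multinomial(read_depth, bin_cell_counts / total)


def simulate_growth(
    library: DualLibrary | Sequence[GuideRecord],
    fitness: Mapping[str, float] | np.ndarray,
    doublings: float,
    read_depth: int,
    rng: np.random.Generator,
    library_label: str = "lib",
    replicate: str = "1",
    day0_weights: Optional[np.ndarray] = None,
) -> CountTable:
    """Two-timepoint growth screen: day18 abundance scales as
    ``day0 * 2 ** (doublings * fitness)``; both timepoints are sampled
    multinomially at ``read_depth``."""
    if doublings <= 0:
        raise ValueError("doublings must be positive")
    elements = (
        library.elements if isinstance(library, DualLibrary) else list(library)
    )
    ids = [rec.element_id for rec in elements]
    if isinstance(fitness, Mapping):
        fit = np.array([fitness[i] for i in ids], dtype=float)
    else:
        fit = np.asarray(fitness, dtype=float)
        if fit.shape != (len(ids),):
            raise ValueError("fitness vector length mismatch")
    if not np.isfinite(fit).all():
        raise ValueError("fitness values must be finite")
    if day0_weights is None:
        day0_weights = np.ones(len(ids))
    day0_weights = np.asarray(day0_weights, dtype=float)
    if day0_weights.sum() <= 0:
        raise ValueError("day0 abundances are all zero")
    day18_weights = day0_weights * np.exp2(doublings * fit)
    counts = np.column_stack(
        [
            simulate_counts(day0_weights, read_depth, rng),
            simulate_counts(day18_weights, read_depth, rng),
        ]
    )
    return CountTable(
        elements=ids,
        samples=[
            f"{library_label}.{replicate}.day0",
            f"{library_label}.{replicate}.day18",
        ],
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Dataset assembly

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_protospacers(
    n: int, rng: np.random.Generator, length: int = 20
) -> list[str]:
    """``n`` unique random ACGT ``length``-mers."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            seq = b"".join(_BASES[row]).decode()
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
    return out


def make_guide_library(
    config: SimConfig, rng: np.random.Generator
) -> list[GuideRecord]:
    """Synthetic parent library: ``guides_per_gene`` guides per gene plus
    non-targeting controls, with random unique protospacers."""
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    n_total = (
        config.n_genes * config.guides_per_gene
        + config.n_negative_control_guides
    )
    spacers = iter(_random_protospacers(n_total, rng))
    records: list[GuideRecord] = []
    for gene in genes:
        for g in range(config.guides_per_gene):
            records.append(
                GuideRecord(
                    element_id=f"{gene}_sg{g + 1}",
                    gene=gene,
                    protospacer=next(spacers),
                )
            )
    for j in range(config.n_negative_control_guides):
        records.append(
            GuideRecord(
                element_id=f"NTC_sg{j + 1}",
                gene=NT_GENE,
                protospacer=next(spacers),
                is_negative_control=True,
            )
        )
    return records


def make_truth(
    config: SimConfig, scenario: Scenario
) -> tuple[list[TrueEffect], str]:
    """Assign ground-truth categories to genes; returns the effects and the
    anchor gene (first pathway-A gene unless overridden in config)."""
    if scenario.n_special > config.n_genes:
        raise ValueError(
            f"scenario plants {scenario.n_special} special genes but only "
            f"{config.n_genes} genes are simulated"
        )
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    effects: list[TrueEffect] = []
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        chunk = genes[cursor : cursor + n]
        cursor += n
        return chunk

    pathway_a = take(scenario.n_pathway_a)
    for g in pathway_a:
        effects.append(TrueEffect(g, "pathway_A_member",
                                  scenario.pathway_strength))
    for g in take(scenario.n_pathway_b):
        effects.append(TrueEffect(g, "pathway_B_member",
                                  scenario.pathway_strength))
    for g in take(scenario.n_stabilizers):
        effects.append(TrueEffect(g, "stabilizer",
                                  scenario.stabilizer_strength))
    for g in take(scenario.n_expression_only):
        effects.append(TrueEffect(g, "expression_only",
                                  scenario.expression_strength))
    for g in genes[cursor:]:
        effects.append(TrueEffect(g, "null", 0.0))

    anchor = config.anchor_gene
    if anchor is None:
        anchor = pathway_a[0] if pathway_a else NT_GENE
    elif anchor not in genes and anchor != NT_GENE:
        raise ValueError(f"anchor gene {anchor!r} not among simulated genes")
    return effects, anchor


def _draw_efficacies(
    config: SimConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    if config.efficacy_distribution == "beta":
        a, b = config.efficacy_params
        return rng.beta(a, b, size=n)
    if config.efficacy_distribution == "ladder":
        ladder = np.asarray(config.efficacy_ladder, dtype=float)
        return ladder[np.arange(n) % ladder.size]
    raise ValueError(
        f"unknown efficacy distribution {config.efficacy_distribution!r}"
    )


def _facs_columns(
    expected: np.ndarray,
    config: SimConfig,
    library_label: str,
    rng: np.random.Generator,
) -> tuple[list[str], list[np.ndarray]]:
    names: list[str] = []
    columns: list[np.ndarray] = []
    n_elements = len(expected)
    for rep in range(1, config.n_replicates + 1):
        element_index, ratios = simulate_cells(
            expected, config.cells_per_element, config.cell_noise_sd, rng
        )
        high, low = simulate_sort(ratios, config.gate_fraction)
        for bin_name, idx in (("high", high), ("low", low)):
            cell_counts = np.bincount(
                element_index[idx], minlength=n_elements
            )
            columns.append(
                simulate_counts(cell_counts, config.read_depth_per_bin, rng)
            )
            names.append(f"{library_label}.{rep}.{bin_name}")
    return names, columns


def generate_dataset(
    config: SimConfig,
    scenario: Optional[Scenario] = None,
    model: PathwayModel = PathwayModel(),
    mode: str = "facs",
) -> SimulatedScreen:
    """Paired NT-anchored and gene-anchored screens over one library.

    Both screens share the library, ground truth, and per-guide
    efficacies; only the fixed guide differs. The anchor gene is also
    present as a variable-position gene, so the anchor+self double
    knockdown occurs in the anchored screen. Sample columns are named
    ``NT.<rep>.<bin>`` and ``anchor.<rep>.<bin>`` (FACS mode) or
    ``<library>.<rep>.day0/day18`` (growth mode).
    """
    if scenario is None:
        scenario = default_scenario()
    if mode not in ("facs", "growth"):
        raise ValueError("mode must be 'facs' or 'growth'")
    rng = np.random.default_rng(config.seed)

    records = make_guide_library(config, rng)
    effects, anchor_gene = make_truth(config, scenario)
    truth_map = {e.gene: e for e in effects}
    truth_map[NT_GENE] = TrueEffect(NT_GENE, "null", 0.0)

    efficacy_values = _draw_efficacies(config, len(records), rng)
    efficacies = {
        rec.element_id: float(v)
        for rec, v in zip(records, efficacy_values)
    }

    anchor_effect = truth_map[anchor_gene]
    anchored_kd = (
        anchor_effect,
        config.anchor_efficacy,
        config.interference_rho,
    )

    expected_nt = element_expected_ratios(
        records, truth_map, efficacies, model=model, anchor=None
    )
    expected_anchor = element_expected_ratios(
        records, truth_map, efficacies, model=model, anchor=anchored_kd
    )

    element_ids = [rec.element_id for rec in records]
    if mode == "facs":
        names: list[str] = []
        columns: list[np.ndarray] = []
        for label, expected in (
            ("NT", expected_nt),
            ("anchor", expected_anchor),
        ):
            lib_names, lib_cols = _facs_columns(expected, config, label, rng)
            names.extend(lib_names)
            columns.extend(lib_cols)
        counts = CountTable(
            elements=element_ids,
            samples=names,
            counts=np.column_stack(columns),
        )
    else:
        per_unit = scenario.growth_fitness
        fit = np.array(
            [
                0.0
                if rec.is_negative_control
                else per_unit.get(truth_map[rec.gene].category, 0.0)
                * truth_map[rec.gene].strength
                * efficacies[rec.element_id]
                for rec in records
            ]
        )
        tables = []
        for label in ("NT", "anchor"):
            for rep in range(1, config.n_replicates + 1):
                tables.append(
                    simulate_growth(
                        records,
                        fit,
                        config.doublings,
                        config.read_depth_per_bin,
                        rng,
                        library_label=label,
                        replicate=str(rep),
                    )
                )
        counts = merge_tables(tables)

    truth_df = pd.DataFrame(
        {
            "gene": [e.gene for e in effects],
            "category": [e.category for e in effects],
            "strength": [e.strength for e in effects],
        }
    )
    efficacy_df = pd.DataFrame(
        {
            "element_id": element_ids,
            "efficacy": [efficacies[i] for i in element_ids],
        }
    )
    library = DualLibrary(fixed_guide="G" * 20, elements=records)
    return SimulatedScreen(
        counts=counts,
        truth=truth_df,
        efficacies=efficacy_df,
        library=library,
        config=config,
        anchor_gene=anchor_gene,
    )


def write_synthetic_fastq(
    table: CountTable,
    sample: str,
    library: DualLibrary | Sequence[GuideRecord],
    layout: ReadLayout,
    path: str | Path,
    tail: str = "GTTTAAGAGCTAAGCTG",
    max_reads: Optional[int] = None,
) -> int:
    """Emit one FASTQ of constant-anchor + protospacer + tail reads whose
    multiset matches a count column. Returns the number of reads written."""
    elements = (
        library.elements if isinstance(library, DualLibrary) else list(library)
    )
    by_id = {rec.element_id: rec for rec in elements}
    column = table.column(sample)
    written = 0
    with open(path, "w") as fh:
        for element_id, n in zip(table.elements, column):
            rec = by_id[element_id]
            seq = layout.anchor + rec.protospacer + tail
            qual = "I" * len(seq)
            for k in range(int(n)):
                if max_reads is not None and written >= max_reads:
                    return written
                fh.write(
                    f"@{element_id}:{k}\n{seq}\n+\n{qual}\n"
                )
                written += 1
    return written
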
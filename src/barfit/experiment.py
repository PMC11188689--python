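"""End-to-end synthetic selection studies.

Reproduces the structure of the lake-water experiment: a barcoded library
incubated in three independent water samples, each under two conditions
(filtered / non-filtered, i.e. with the resident microbiota removed or
intact), sampled on days 2, 4 and 8 against a Day-0 control, in three
technical replicates. Selection acts through per-gene log2 effects;
sequencing noise is multinomial at the configured depth. The pipeline runs
counts → strain fitness → normalized gene fitness → replicate averaging →
per-water-sample PCA selection → cross-replicate consensus, and the known
truth lets sensitivity and false-positive rates be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fitness, select, simulate
from .barseq import assemble_count_matrix
from .errors import ConfigurationError


@dataclass
class StudyDesign:
    """The sampling design of one selection study."""

    n_water_samples: int = 3
    conditions: tuple = (select.FILTERED, select.NON_FILTERED)
    days: tuple = (2, 4, 8)
    n_tech_reps: int = 3
    depth: int = 2_000_000

    def schedule(self) -> list[tuple[str, int]]:
        return [("control", 0)] + [(c, d) for c in self.conditions for d in self.days]


def make_effect_map(
    gene_ids,
    rng,
    n_depleted: int = 40,
    depleted_effect: float = -2.0,
    n_enriched: int = 40,
    enriched_effect: float = 1.5,
    conditions: tuple = (select.FILTERED, select.NON_FILTERED),
    days: tuple = (2, 4, 8),
) -> tuple[dict, dict[str, list[str]]]:
    """Plant ground-truth effects on a random subset of genes.

    ``n_depleted`` genes get ``depleted_effect`` in both conditions at every
    sampled day; ``n_enriched`` genes get ``enriched_effect`` in filtered
    water only. Everything else is neutral. Returns the effect map plus the
    planted gene lists.
    """
    gene_ids = list(gene_ids)
    if n_depleted + n_enriched > len(gene_ids):
        raise ConfigurationError("more planted genes than genes available")
    chosen = rng.choice(len(gene_ids), size=n_depleted + n_enriched, replace=False)
    depleted = sorted(gene_ids[i] for i in chosen[:n_depleted])
    enriched = sorted(gene_ids[i] for i in chosen[n_depleted:])
    effect_map: dict = {}
    for g in depleted:
        effect_map[g] = {(c, d): depleted_effect for c in conditions for d in days}
    for g in enriched:
        effect_map[g] = {(select.FILTERED, d): enriched_effect for d in days}
    return effect_map, {"depleted": depleted, "enriched": enriched}


def simulate_study_counts(
    pool: pd.DataFrame,
    abundances: pd.Series,
    effect_map: dict,
    design: StudyDesign,
    rng,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial count matrix + sample sheet for the full design.

    Technical replicates are independent multinomial draws from the same
    expected proportions; each lineage has its own Day-0 control drawn from
    the initial abundances.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    full_schedule = design.schedule()
    expected = simulate.simulate_selection(abundances, effect_map, full_schedule, pool)
    schedule = [(c, d) for c, d in full_schedule if d != 0]

    sheet_rows = []
    columns: dict[str, pd.Series] = {}
    for ws in range(1, design.n_water_samples + 1):
        for rep in range(1, design.n_tech_reps + 1):
            sid = f"ws{ws}_d0_r{rep}"
            sheet_rows.append((sid, ws, "control", 0, rep))
            columns[sid] = pd.Series(
                simulate.draw_counts(expected[("control", 0)].to_numpy(), design.depth, rng),
                index=abundances.index,
            )
            for c, d in schedule:
                sid = f"ws{ws}_{c[0]}{d}_r{rep}"
                sheet_rows.append((sid, ws, c, d, rep))
                columns[sid] = pd.Series(
                    simulate.draw_counts(expected[(c, d)].to_numpy(), design.depth, rng),
                    index=abundances.index,
                )
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "water_sample", "condition", "day", "tech_rep"]
    )
    counts = assemble_count_matrix(columns, sheet, pool)
    return counts, sheet


@dataclass
class StudyResult:
    pool: pd.DataFrame
    abundances: pd.Series
    effect_map: dict
    planted: dict
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    gene_fitness: pd.DataFrame  # replicate-averaged
    selections: list = field(default_factory=list)
    consensus: select.ConsensusResult | None = None

    def metrics(self) -> dict:
        """Recovery metrics against the planted truth."""
        dep = set(self.planted["depleted"])
        enr = set(self.planted["enriched"])
        blue = set(self.consensus.blue)
        red = set(self.consensus.red)
        return {
            "blue_sensitivity": len(blue & dep) / len(dep) if dep else float("nan"),
            "red_sensitivity": len(red & enr) / len(enr) if enr else float("nan"),
            "false_positives": len((blue | red) - dep - enr),
        }


def run_study(
    seed: int,
    genome_length: int = 3_000_000,
    n_genes: int = 3000,
    n_insertions: int = 60_000,
    coding_fraction: float = 0.9,
    abundance_sigma: float = 1.0,
    design: StudyDesign | None = None,
    effect_map: dict | None = None,
    planted: dict | None = None,
    pseudocount: float = fitness.DEFAULT_PSEUDOCOUNT,
    min_strains: int = 1,
    window: int = fitness.DEFAULT_WINDOW,
) -> StudyResult:
    """Simulate and analyse one full study from a single seed."""
    rng = np.random.default_rng(seed)
    design = design or StudyDesign()
    annotation, _seq = simulate.simulate_genome(genome_length, n_genes, rng)
    pool, abundances = simulate.simulate_library(
        annotation,
        n_insertions,
        coding_fraction=coding_fraction,
        seed=rng,
        abundance_sigma=abundance_sigma,
    )
    if effect_map is None:
        effect_map, planted = make_effect_map(
            annotation.genes["gene_id"], rng, conditions=design.conditions, days=design.days
        )
    elif planted is None:
        planted = {"depleted": [], "enriched": []}
    simulate.validate_effect_map(effect_map, annotation)
    counts, sheet = simulate_study_counts(pool, abundances, effect_map, design, rng)
    _sf, _per_rep, averaged = fitness.fitness_pipeline(
        counts, sheet, pool, annotation,
        pseudocount=pseudocount, min_strains=min_strains, window=window,
    )
    selections = [
        select.select_replicate(averaged, water_sample=ws)
        for ws in sorted(averaged["water_sample"].unique())
    ]
    cons = select.consensus(selections) if len(selections) >= 2 else None
    return StudyResult(
        pool=pool,
        abundances=abundances,
        effect_map=effect_map,
        planted=planted,
        counts=counts,
        sample_sheet=sheet,
        gene_fitness=averaged,
        selections=selections,
        consensus=cons,
    )
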
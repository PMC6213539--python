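"""End-to-end pipeline: fixtures -> compile -> intakes -> analysis.

Glue used by the CLI, the examples and the determinism checks.  Every
stage is the public function of its module; this file only wires them
together and serializes the outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from bcaadb import io as bio
from bcaadb.compiler import compile_table, report_summary
from bcaadb.recall import group_columns, summarize_survey
from bcaadb.simulate import SimConfig, make_food_tables, make_survey
from bcaadb.survey import (
    compute_breaks,
    categorize_items,
    contribution_table,
    exclude_misreporters,
    fit_quartile_association,
    quartile_assign,
)


def run_pipeline(cfg: SimConfig) -> dict:
    """Run the full synthetic study once; return all intermediate objects.

    Stages: generate fixtures, compile the target table, summarize the
    recall survey, exclude misreporters, categorize items, assign intake
    quartiles (computed cuts), fit the obesity association adjusted for
    age and energy, and attribute intake to food groups.
    """
    target, references, recipes, literature, explicit_map, raw_map, item_truth = (
        make_food_tables(cfg)
    )
    compiled, report = compile_table(
        target, references, recipes, literature, explicit_map, raw_map
    )
    recalls, profiles, subject_truth = make_survey(cfg, compiled)

    intakes = summarize_survey(recalls, compiled)
    kept, excluded = exclude_misreporters(profiles, intakes)
    kept_ids = [p.subject_id for p in kept]
    kept_intakes = intakes.loc[kept_ids]

    usable = [it for it in compiled if it.bcaa is not None]
    breaks = compute_breaks([it.bcaa.total() for it in usable])
    categories, composition = categorize_items(usable, breaks)

    quartile = quartile_assign(kept_intakes["total_bcaa_g"].to_numpy())
    prof_by_id = {p.subject_id: p for p in kept}
    outcome = np.array([prof_by_id[s].obesity_flag for s in kept_ids], dtype=float)
    age = np.array([prof_by_id[s].age for s in kept_ids])
    energy = kept_intakes["energy_kcal"].to_numpy()
    association = fit_quartile_association(quartile, outcome, age, energy)

    contribution = contribution_table(kept_intakes)

    return {
        "config": cfg,
        "target": target,
        "compiled": compiled,
        "report": report,
        "report_summary": report_summary(report),
        "item_truth": item_truth,
        "recalls": recalls,
        "profiles": profiles,
        "subject_truth": subject_truth,
        "intakes": intakes,
        "kept": kept,
        "excluded": excluded,
        "categories": categories,
        "composition": composition,
        "breaks": breaks,
        "quartile": pd.Series(quartile, index=kept_intakes.index, name="quartile"),
        "association": association,
        "contribution": contribution,
    }


def write_outputs(result: dict, outdir) -> list[Path]:
    """Serialize a pipeline run as deterministic CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        p = outdir / name
        bio.write_csv(frame, p, index=index)
        paths.append(p)

    _write(bio.food_table_frame(result["compiled"]), "compiled.csv")
    _write(result["report"].counts.rename_axis("group10"), "report.csv", index=True)
    _write(result["intakes"].round(9), "intakes.csv", index=True)
    _write(result["categories"].rename_axis("item_id").to_frame(), "categories.csv", index=True)
    _write(result["composition"].rename_axis("group18"), "composition.csv", index=True)
    _write(result["quartile"].rename_axis("subject_id").to_frame(), "quartiles.csv", index=True)
    assoc = result["association"]
    assoc_frame = pd.DataFrame({
        "quartile": sorted(assoc.odds_ratios),
        "odds_ratio": [assoc.odds_ratios[q] for q in sorted(assoc.odds_ratios)],
        "ci_low": [assoc.ci_low[q] for q in sorted(assoc.odds_ratios)],
        "ci_high": [assoc.ci_high[q] for q in sorted(assoc.odds_ratios)],
        "p_overall": assoc.p_overall,
    })
    _write(assoc_frame, "association.csv")
    _write(result["contribution"].rename_axis("group18"), "contribution.csv", index=True)
    excl = pd.DataFrame(
        sorted(result["excluded"].items()), columns=["subject_id", "reason"]
    )
    _write(excl, "excluded.csv")
    return paths
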
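"""Materialize a complete synthetic study on disk.

Writes everything the pipeline consumes — exposure and per-outcome summary
statistics, the generative LD table, a secondary-trait annotation table,
a score-weights file, an individual-level cohort, and a ready-to-run YAML
config — mirroring the reference design: one binary exposure screened
against seven outcomes (a lacunar-stroke-like binary outcome, three
ICH-like binary outcomes, and three continuous imaging-like outcomes),
with a subset of instruments annotated as secondarily associated with
lipids/kidney function or BMI for sensitivity reruns.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from . import simulate, summary_io
from .grs import WeightEntry, write_weights
from .pipeline import OutcomeSpec, StudyConfig

#: (label, binary, causal effect on the outcome) for the seven-outcome design
DEFAULT_OUTCOMES: tuple[tuple[str, bool, float], ...] = (
    ("lacunar_stroke", True, 0.14),
    ("ICH", True, 0.07),
    ("deep_ICH", True, 0.15),
    ("lobar_ICH", True, 0.07),
    ("WMH", False, 0.01),
    ("FA", False, -0.25),
    ("MD", False, 0.04),
)


def generate_study_files(
    out_dir: str | Path,
    seed: int,
    scenario: simulate.Scenario | None = None,
    outcomes: tuple[tuple[str, bool, float], ...] = DEFAULT_OUTCOMES,
    *,
    n_annotated_lipids_kidney: int = 8,
    n_annotated_bmi: int = 8,
) -> StudyConfig:
    """Generate and write a full synthetic study; returns its config.

    The exposure sample is drawn once; each outcome gets its own disjoint
    sample sharing the true instrument effects, with the causal effect set
    per outcome. Instrument annotations mark the first
    ``n_annotated_lipids_kidney`` variants as lipids/kidney-associated and
    the next ``n_annotated_bmi`` as BMI-associated, defining the two
    sensitivity exclusion sets.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = scenario or simulate.Scenario(binary_exposure=True)
    rng = np.random.default_rng(seed)
    panel = simulate.draw_variant_panel(base, rng)
    effects = simulate.draw_effects(base, panel, rng)

    gx = simulate.simulate_genotypes(panel, base.n_exposure_sample, rng)
    sx = simulate.simulate_traits(gx, effects, base, rng)
    exposure_stats = simulate.derive_summary_stats(
        gx, sx.exposure, panel, binary=base.binary_exposure
    )
    exposure_path = out / "exposure.tsv"
    summary_io.write_summary_stats(exposure_stats, exposure_path)

    outcome_specs = []
    for label, binary, beta in outcomes:
        sc = dataclasses.replace(
            base, beta_causal=beta, binary_outcome=binary
        )
        gy = simulate.simulate_genotypes(panel, sc.n_outcome_sample, rng)
        sy = simulate.simulate_traits(gy, effects, sc, rng)
        stats = simulate.derive_summary_stats(gy, sy.outcome, panel, binary=binary)
        path = out / f"outcome_{label}.tsv"
        summary_io.write_summary_stats(stats, path)
        outcome_specs.append(OutcomeSpec(label=label, path=str(path), binary=binary))

    ld_path = out / "ld.tsv"
    summary_io.write_ld_table(simulate.ld_pairs_from_panel(panel), ld_path)

    annotations: dict[str, frozenset[str]] = {}
    ids = list(panel.ids)
    for vid in ids[:n_annotated_lipids_kidney]:
        annotations[vid] = frozenset({"lipids", "kidney_function"})
    for vid in ids[n_annotated_lipids_kidney : n_annotated_lipids_kidney + n_annotated_bmi]:
        annotations[vid] = frozenset({"BMI"})
    for vid in ids[n_annotated_lipids_kidney + n_annotated_bmi :]:
        annotations[vid] = frozenset()
    annotation_path = out / "annotations.tsv"
    summary_io.write_annotations(annotations, annotation_path)

    weights = [
        WeightEntry(
            variant_id=r.variant_id,
            odds_ratio=math.exp(r.beta),
            effect_allele=r.effect_allele,
            eaf=r.eaf,
        )
        for r in exposure_stats
        if np.isfinite(r.beta)
    ]
    write_weights(weights, out / "weights.tsv")

    cohort = simulate.simulate_cohort(
        base, panel, effects, rng, score_effect=-0.5, phenotypes=("FA_pc1",)
    )
    summary_io.write_cohort(cohort, out / "cohort_dosages.tsv", out / "cohort_pheno.tsv")

    config = StudyConfig(
        exposure_label="exposure",
        exposure_path=str(exposure_path),
        outcomes=outcome_specs,
        ld_path=str(ld_path),
        annotation_path=str(annotation_path),
        exclusion_sets={
            "pleiotropic": ["lipids", "kidney_function"],
            "bmi": ["BMI"],
        },
        seed=seed,
        out_dir=str(out / "results"),
    )
    config.to_yaml(out / "config.yaml")
    return config


__all__ = ["generate_study_files", "DEFAULT_OUTCOMES"]
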
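"""Config-driven study orchestration.

Reproduces the shape of the study design: one exposure screened against
several outcomes (the reference design uses seven: lacunar stroke, ICH,
deep ICH, lobar ICH, WMH, FA and MD), each with the primary IVW estimate,
weighted-median secondaries, and the MR-Egger pleiotropy diagnostic;
family-wise significance is flagged at a Bonferroni-corrected threshold
(0.05/7 = 0.0071 for the seven-outcome family). Sensitivity reruns drop
instruments annotated with secondary traits (a local stand-in for a
Phenoscanner lookup) and report the resulting change in every estimate.

Significance flags are reported but never suppress output rows —
nonsignificant estimates are part of the result.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import estimators, harmonize, summary_io

logger = logging.getLogger("mrkit")


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n."""
    if not (0.0 < alpha_family < 1.0):
        raise ValueError("alpha_family must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_family / n_tests


def display_threshold(threshold: float) -> str:
    """Threshold rounded to 2 significant figures for reporting
    (0.05/7 -> '0.0071')."""
    return f"{threshold:.2g}"


@dataclass(frozen=True)
class OutcomeSpec:
    label: str
    path: str
    binary: bool = False


@dataclass
class StudyConfig:
    """Everything needed to rerun a study from files + seed."""

    exposure_label: str
    exposure_path: str
    outcomes: list[OutcomeSpec]
    ld_path: str
    annotation_path: str | None = None
    clump_r2: float = 0.1
    clump_window_bp: int = 100_000
    proxy_r2: float = 0.7
    alpha_family: float = 0.05
    n_tests: int = 7
    exclusion_sets: dict[str, list[str]] = field(default_factory=dict)
    n_boot: int = 1000
    seed: int = 0
    random_effects: bool = False
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = raw.get("thresholds", {})
        estimators_cfg = raw.get("estimators", {})
        return cls(
            exposure_label=raw["exposure"]["label"],
            exposure_path=raw["exposure"]["path"],
            outcomes=[
                OutcomeSpec(o["label"], o["path"], bool(o.get("binary", False)))
                for o in raw["outcomes"]
            ],
            ld_path=raw["ld_path"],
            annotation_path=raw.get("annotation_path"),
            clump_r2=thresholds.get("clump_r2", 0.1),
            clump_window_bp=thresholds.get("clump_window_bp", 100_000),
            proxy_r2=thresholds.get("proxy_r2", 0.7),
            alpha_family=thresholds.get("alpha_family", 0.05),
            n_tests=thresholds.get("n_tests", 7),
            exclusion_sets={k: list(v) for k, v in raw.get("exclusion_sets", {}).items()},
            n_boot=estimators_cfg.get("n_boot", 1000),
            seed=estimators_cfg.get("seed", 0),
            random_effects=bool(estimators_cfg.get("random_effects", False)),
            out_dir=raw.get("out_dir", "results"),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "exposure": {"label": self.exposure_label, "path": self.exposure_path},
            "outcomes": [dataclasses.asdict(o) for o in self.outcomes],
            "ld_path": self.ld_path,
            "annotation_path": self.annotation_path,
            "thresholds": {
                "clump_r2": self.clump_r2,
                "clump_window_bp": self.clump_window_bp,
                "proxy_r2": self.proxy_r2,
                "alpha_family": self.alpha_family,
                "n_tests": self.n_tests,
            },
            "exclusion_sets": self.exclusion_sets,
            "estimators": {
                "n_boot": self.n_boot,
                "seed": self.seed,
                "random_effects": self.random_effects,
            },
            "out_dir": self.out_dir,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class OutcomeResult:
    label: str
    pairs: list[harmonize.HarmonizedPair]
    table: estimators.EstimateTable | None
    error: str | None = None
    excluded_variants: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return sum(1 for p in self.pairs if p.status != harmonize.DROPPED)


@dataclass
class StudyResult:
    config: StudyConfig
    outcomes: dict[str, OutcomeResult]
    per_test_threshold: float

    def estimates_frame(self) -> pd.DataFrame:
        frames = []
        for label, res in self.outcomes.items():
            if res.table is None:
                frames.append(
                    pd.DataFrame(
                        [{"outcome": label, "method": "", "status": f"failed: {res.error}"}]
                    )
                )
                continue
            df = res.table.to_frame(outcome=label)
            if "pvalue" in df.columns:
                df["significant"] = df["pvalue"] < self.per_test_threshold
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def egger_frame(self) -> pd.DataFrame:
        rows = []
        for label, res in self.outcomes.items():
            if res.table is None or res.table.egger is None:
                rows.append({"outcome": label, "status": "not_estimable"})
                continue
            e = res.table.egger
            rows.append(
                {
                    "outcome": label,
                    "status": "ok",
                    "intercept": e.intercept,
                    "intercept_se": e.intercept_se,
                    "intercept_p": e.intercept_p,
                    "slope": e.slope.beta_hat,
                    "slope_se": e.slope.se,
                    "slope_p": e.slope.pvalue,
                }
            )
        return pd.DataFrame(rows)

    def counts_frame(self) -> pd.DataFrame:
        """Machine-readable per-stage instrument accounting.

        Invariant: selected = retained + dropped for every outcome.
        """
        rows = []
        for label, res in self.outcomes.items():
            n_dropped = sum(1 for p in res.pairs if p.status == harmonize.DROPPED)
            rows.append(
                {
                    "outcome": label,
                    "n_selected": len(res.pairs),
                    "n_retained": res.n_retained,
                    "n_dropped": n_dropped,
                    "n_proxy": sum(1 for p in res.pairs if p.status == harmonize.PROXY),
                    "n_excluded_by_annotation": len(res.excluded_variants),
                }
            )
        return pd.DataFrame(rows)

    def forest_frame(self) -> pd.DataFrame:
        """Plot-ready forest data: one IVW point per outcome, OR scale."""
        rows = []
        for label, res in self.outcomes.items():
            if res.table is None:
                continue
            est = res.table.estimates.get(estimators.IVW)
            if est is None:
                continue
            orv, lo, hi = est.or_scale
            rows.append(
                {"label": label, "point": orv, "ci_low": lo, "ci_high": hi}
            )
        return pd.DataFrame(rows)


def _load_inputs(config: StudyConfig):
    exposure = summary_io.read_summary_stats(config.exposure_path)
    ld = summary_io.read_ld_table(config.ld_path)
    annotations = (
        summary_io.read_annotations(config.annotation_path)
        if config.annotation_path
        else {}
    )
    return exposure, ld, annotations


def run_study(
    config: StudyConfig,
    *,
    exclusion_set: str | None = None,
    write: bool = True,
) -> StudyResult:
    """Run the full summary-statistic arm of a study.

    For each outcome: clump + harmonize the instruments, run every
    estimator, flag per-outcome significance at alpha/n_tests. An outcome
    whose harmonization or estimation fails entirely is reported as failed
    and the run continues. With ``exclusion_set``, instruments annotated
    with any trait in the named set are removed before estimation.
    """
    exposure, ld, annotations = _load_inputs(config)
    excluded_ids: set[str] = set()
    if exclusion_set is not None:
        if exclusion_set not in config.exclusion_sets:
            raise summary_io.ConfigurationError(
                f"exclusion set {exclusion_set!r} not defined in config"
            )
        traits = set(config.exclusion_sets[exclusion_set])
        excluded_ids = {
            vid for vid, tags in annotations.items() if tags & traits
        }
        exposure = [r for r in exposure if r.variant_id not in excluded_ids]
        if not exposure:
            raise summary_io.ValidationError(
                f"exclusion set {exclusion_set!r} removes every instrument"
            )
        logger.info(
            "exclusion set %r removed %d instruments", exclusion_set, len(excluded_ids)
        )
    threshold = bonferroni_threshold(config.alpha_family, config.n_tests)
    results: dict[str, OutcomeResult] = {}
    for spec in config.outcomes:
        try:
            outcome_stats = summary_io.read_summary_stats(spec.path)
            pairs = harmonize.build_instruments(
                exposure,
                outcome_stats,
                ld,
                clump_r2=config.clump_r2,
                clump_window_bp=config.clump_window_bp,
                proxy_r2=config.proxy_r2,
            )
            table = estimators.estimate_all(
                pairs,
                n_boot=config.n_boot,
                seed=config.seed,
                random_effects=config.random_effects,
            )
            results[spec.label] = OutcomeResult(
                label=spec.label,
                pairs=pairs,
                table=table,
                excluded_variants=sorted(excluded_ids),
            )
        except (summary_io.ValidationError, summary_io.ConfigurationError,
                estimators.EstimationError, OSError) as exc:
            logger.error("outcome %s failed: %s", spec.label, exc)
            results[spec.label] = OutcomeResult(
                label=spec.label, pairs=[], table=None, error=str(exc)
            )
    study = StudyResult(config=config, outcomes=results, per_test_threshold=threshold)
    if write:
        _write_bundle(study, exclusion_set)
    return study


def _write_bundle(study: StudyResult, exclusion_set: str | None) -> None:
    out = Path(study.config.out_dir)
    if exclusion_set:
        out = out / f"sensitivity_{exclusion_set}"
    out.mkdir(parents=True, exist_ok=True)
    study.estimates_frame().to_csv(out / "estimates.tsv", sep="\t", index=False)
    study.egger_frame().to_csv(out / "egger.tsv", sep="\t", index=False)
    study.counts_frame().to_csv(out / "counts.tsv", sep="\t", index=False)
    study.forest_frame().to_csv(out / "forest.tsv", sep="\t", index=False)
    harm_frames = []
    for label, res in study.outcomes.items():
        df = harmonize.harmonization_report(res.pairs)
        df.insert(0, "outcome", label)
        harm_frames.append(df)
    pd.concat(harm_frames, ignore_index=True).to_csv(
        out / "harmonization.tsv", sep="\t", index=False
    )
    lines = [
        f"exposure: {study.config.exposure_label}",
        f"outcomes: {', '.join(study.outcomes)}",
        f"per-test threshold: {display_threshold(study.per_test_threshold)} "
        f"({study.config.alpha_family}/{study.config.n_tests})",
        f"seed: {study.config.seed}",
    ]
    for label, res in study.outcomes.items():
        if res.table is None:
            lines.append(f"{label}: FAILED ({res.error})")
        else:
            lines.append(
                f"{label}: {res.n_retained} instruments retained of {len(res.pairs)}"
            )
    (out / "run.log").write_text("\n".join(lines) + "\n")


def sensitivity_rerun(
    config: StudyConfig,
    exclusion_set: str,
    primary: StudyResult | None = None,
    *,
    write: bool = True,
) -> tuple[StudyResult, pd.DataFrame]:
    """Rerun after removing instruments annotated with the named traits.

    Returns the rerun result and a delta table comparing each estimate
    with the primary run (rerun minus primary, log scale).
    """
    if primary is None:
        primary = run_study(config, write=False)
    rerun = run_study(config, exclusion_set=exclusion_set, write=write)
    rows = []
    for label in rerun.outcomes:
        prim, sens = primary.outcomes.get(label), rerun.outcomes[label]
        if prim is None or prim.table is None or sens.table is None:
            continue
        for method in estimators.METHODS:
            a = prim.table.estimates.get(method)
            b = sens.table.estimates.get(method)
            if a is None or b is None:
                continue
            rows.append(
                {
                    "outcome": label,
                    "method": method,
                    "primary_beta": a.beta_hat,
                    "sensitivity_beta": b.beta_hat,
                    "delta": b.beta_hat - a.beta_hat,
                    "removed_variants": ",".join(sens.excluded_variants),
                }
            )
    deltas = pd.DataFrame(rows)
    if write:
        out = Path(config.out_dir) / f"sensitivity_{exclusion_set}"
        deltas.to_csv(out / "deltas.tsv", sep="\t", index=False)
    return rerun, deltas


__all__ = [
    "StudyConfig",
    "OutcomeSpec",
    "OutcomeResult",
    "StudyResult",
    "bonferroni_threshold",
    "display_threshold",
    "run_study",
    "sensitivity_rerun",
]
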
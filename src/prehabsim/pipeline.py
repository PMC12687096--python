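"""End-to-end orchestration: generate, score, analyze, design, evaluate.

One pipeline configuration (YAML) drives the whole desk-scale experiment:
synthetic cohort generation, morbidity scoring, effect estimation,
progression-criteria evaluation, design power calculations, and the
cost-utility model.  A single global seed deterministically derives
per-stage substreams, so identical (config, seed) pairs yield
byte-identical outputs and individual stages remain reproducible in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import stats as sps

from . import complication_scoring, feasibility_design, health_econ, trial_analysis
from .synthetic_cohort import GeneratorConfig, generate_cohort, write_cohort
from .trial_analysis import EffectEstimate, ProgressionCriterion

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "default_config_path",
    "default_econ_model_path",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid pipeline config:\n  - " + "\n  - ".join(self.errors))


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    generator: GeneratorConfig
    criteria: list[ProgressionCriterion] = field(default_factory=list)
    criterion_denominators: dict = field(default_factory=dict)
    bootstrap_samples: int = 2000
    alpha: float = 0.05
    rounding: int = 1
    econ_model_path: Optional[str] = None  # None -> bundled illustrative model
    psa_samples: Optional[int] = None
    output_dir: str = "outputs"
    seed: int = 0


def default_config_path() -> Path:
    return Path(resources.files("prehabsim") / "data" / "default_config.yaml")


def default_econ_model_path() -> Path:
    return Path(resources.files("prehabsim") / "data" / "default_econ_model.yaml")


def load_config(path) -> PipelineConfig:
    """Parse and validate a pipeline YAML; every violation is reported."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"malformed YAML in {path}: {exc}"]) from exc
    if not isinstance(doc, dict):
        raise ConfigError([f"{path} does not contain a mapping"])

    errors: list[str] = []
    generator = None
    if "generator" not in doc:
        errors.append("missing required block 'generator'")
    else:
        try:
            generator = GeneratorConfig.from_dict(doc["generator"])
        except TypeError as exc:
            errors.append(f"generator block: {exc}")
        except ValueError as exc:
            errors.append(str(exc))

    criteria: list[ProgressionCriterion] = []
    for entry in doc.get("progression_criteria", []):
        try:
            criteria.append(
                ProgressionCriterion(
                    name=entry["name"],
                    red_limit=float(entry["red_limit"]),
                    green_limit=float(entry["green_limit"]),
                    observed=(None if entry.get("observed") is None else float(entry["observed"])),
                    unit=entry.get("unit", "proportion"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"progression criterion {entry!r}: {exc}")

    analysis = doc.get("analysis", {})
    bootstrap_samples = int(analysis.get("bootstrap_samples", 2000))
    alpha = float(analysis.get("alpha", 0.05))
    if bootstrap_samples < 1:
        errors.append("analysis.bootstrap_samples must be >= 1")
    if not 0 < alpha < 1:
        errors.append("analysis.alpha must be in (0, 1)")

    econ_path = doc.get("econ_model")
    if econ_path is not None and not Path(econ_path).exists():
        errors.append(f"econ_model path {econ_path!r} does not exist")

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        generator=generator,
        criteria=criteria,
        criterion_denominators=dict(doc.get("criterion_denominators", {})),
        bootstrap_samples=bootstrap_samples,
        alpha=alpha,
        rounding=int(analysis.get("rounding", 1)),
        econ_model_path=econ_path,
        psa_samples=(None if doc.get("psa_samples") is None else int(doc["psa_samples"])),
        output_dir=str(doc.get("output_dir", "outputs")),
        seed=int(doc.get("seed", 0)),
    )


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("cohort", "bootstrap", "psa")
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def _effect_to_dict(e: EffectEstimate) -> dict:
    return {
        "estimate": e.estimate,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "scale": e.scale,
        "n_used": e.n_used,
    }


class _Encoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, EffectEstimate):
            return _effect_to_dict(obj)
        return super().default(obj)


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_Encoder) + "\n")


def _analyze(cohort, config: PipelineConfig, rng: np.random.Generator) -> dict:
    itt = trial_analysis.itt_set(cohort)
    pp = trial_analysis.per_protocol_set(cohort)
    table = trial_analysis.adherence_table(itt)
    int_mask = itt["arm"] == "intervention"
    classes = itt.loc[int_mask, "pct_weight_change"].map(trial_analysis.classify_adherence)
    n_int = int(int_mask.sum())

    result = {
        "n_itt": len(itt),
        "n_per_protocol": len(pp),
        "adherence": {
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "prop_adherent_intervention": table.a / (table.a + table.b),
            "prop_adherent_usual_care": table.c / (table.c + table.d),
            "prop_nonadherent_intervention": float((classes == "nonadherent").sum() / n_int),
            "odds_ratio": trial_analysis.odds_ratio_2x2(table, correction=True),
        },
        "weight_change_surgery": {
            "itt": trial_analysis.adjusted_mean_difference(
                itt["weight_change_surgery"], itt["arm"], itt["baseline_weight"]
            ),
            "per_protocol": trial_analysis.adjusted_mean_difference(
                pp["weight_change_surgery"], pp["arm"], pp["baseline_weight"]
            ),
        },
        "weight_change_30d": {
            "itt": trial_analysis.adjusted_mean_difference(
                itt["weight_change_30d"], itt["arm"], itt["baseline_weight"]
            ),
        },
        "fat_free_mass_change": {
            "itt": trial_analysis.adjusted_mean_difference(
                itt["fat_free_mass_change"], itt["arm"], itt["baseline_weight"]
            ),
        },
    }
    days = itt.loc[int_mask, "days_rand_to_surgery"]
    loss = -itt.loc[int_mask, "pct_weight_change"]
    if days.nunique() > 1 and loss.nunique() > 1:
        r, p = sps.pearsonr(loss, days)
        result["loss_days_correlation"] = {"r": float(r), "p": float(p), "n": int(len(days))}
    try:
        split = trial_analysis.median_split_cci_ratio(
            itt, n_boot=config.bootstrap_samples, rng=rng
        )
        result["median_split_cci"] = {
            "median_loss_pct": split["median_loss_pct"],
            "ratio": split["ratio"],
            "relative_reduction": split["relative_reduction"],
            "n_high_loss": split["n_high_loss"],
            "n_low_loss": split["n_low_loss"],
        }
    except (ZeroDivisionError, ValueError) as exc:
        result["median_split_cci"] = {"error": str(exc)}
    return result


def _progression(cohort, config: PipelineConfig) -> dict:
    itt = trial_analysis.itt_set(cohort)
    int_mask = itt["arm"] == "intervention"
    observed_from_cohort = {
        "adherence": float(
            (itt.loc[int_mask, "pct_weight_change"].map(trial_analysis.classify_adherence)
             == "adherent").mean()
        ),
        "retention": float(cohort["retained_30d"].mean()),
    }
    denominators = dict(config.criterion_denominators)
    denominators.setdefault("adherence", int(int_mask.sum()))
    denominators.setdefault("retention", len(cohort))
    criteria = []
    for crit in config.criteria:
        observed = crit.observed
        if crit.name in observed_from_cohort:
            observed = observed_from_cohort[crit.name]
        criteria.append(
            ProgressionCriterion(
                name=crit.name, red_limit=crit.red_limit, green_limit=crit.green_limit,
                observed=observed, unit=crit.unit,
            )
        )
    proportion_names = {c.name for c in criteria if c.unit == "proportion"}
    denominators = {k: v for k, v in denominators.items() if k in proportion_names}
    return trial_analysis.evaluate_progression_criteria(criteria, denominators)


def _design(config: PipelineConfig) -> dict:
    targets = config.generator.arm_targets()
    default_n = {"adherence": targets["intervention"], "engagement": targets["intervention"],
                 "retention": config.generator.n_total}
    rows = {}
    powers = []
    for crit in config.criteria:
        if crit.unit != "proportion":
            continue
        n = int(config.criterion_denominators.get(crit.name, default_n.get(crit.name,
                                                                           config.generator.n_total)))
        q = feasibility_design.PowerQuery(
            n=n, p_null=crit.red_limit, p_alt=crit.green_limit, alpha=config.alpha
        )
        res = feasibility_design.exact_binomial_power(q)
        rows[crit.name] = {
            "n": n, "p_null": crit.red_limit, "p_alt": crit.green_limit,
            "alpha": config.alpha, "k_star": res.k_star,
            "attained_size": res.attained_size, "power": res.power,
        }
        powers.append(res.power)
    report = {"criteria": rows}
    if powers:
        report["collective_power"] = feasibility_design.collective_power(powers)
    return report


def _econ(config: PipelineConfig, seed: int) -> dict:
    model_path = config.econ_model_path or default_econ_model_path()
    doc = health_econ.load_econ_model(model_path)
    res_i = doc.model.evaluate_arm("intervention")
    res_u = doc.model.evaluate_arm("usual_care")
    dc, dq = doc.model.incremental()
    report = {
        "model_path": str(model_path),
        "deterministic": {
            "intervention": {"cost": res_i.cost, "qalys": res_i.qalys},
            "usual_care": {"cost": res_u.cost, "qalys": res_u.qalys},
            "incremental_cost": dc,
            "incremental_qalys": dq,
            "icer": health_econ.compute_icer(res_i.cost, res_i.qalys, res_u.cost, res_u.qalys),
        },
    }
    n_psa = config.psa_samples if config.psa_samples is not None else doc.psa_n_samples
    if doc.psa_distributions and n_psa > 0:
        psa = health_econ.run_psa(doc.model, doc.psa_distributions, n_psa, seed=seed)
        ceac = health_econ.compute_ceac(psa)
        at_20k = float(
            ceac.loc[(ceac["wtp"] - 20_000.0).abs().idxmin(), "prob_cost_effective"]
        )
        report["psa"] = {
            "n_samples": n_psa,
            "seed": seed,
            "mean_incremental_cost": float(psa.samples["incremental_cost"].mean()),
            "mean_incremental_qalys": float(psa.samples["incremental_qaly"].mean()),
            "prob_cost_effective_at_20000": at_20k,
            "ceac": {
                "wtp": ceac["wtp"].tolist(),
                "prob_cost_effective": ceac["prob_cost_effective"].tolist(),
            },
        }
    if doc.one_way_ranges:
        tornado = health_econ.one_way_sensitivity(doc.model, doc.one_way_ranges)
        report["one_way"] = tornado.to_dict(orient="records")
    return report


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Execute every stage in order, writing all outputs; returns the report."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": config.generator.content_hash(),
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    cohort = stage("generate", lambda: generate_cohort(config.generator, seeds["cohort"]))
    write_cohort(cohort, out / "cohort.csv", config=config.generator, seed=seeds["cohort"])
    report["n_generated"] = len(cohort)
    report["arm_sizes"] = cohort["arm"].value_counts().to_dict()

    morbidity = stage("score", lambda: complication_scoring.summarize_morbidity(cohort))
    _write_json(morbidity, out / "morbidity.json")

    analysis = stage(
        "analyze",
        lambda: _analyze(cohort, config, np.random.default_rng(seeds["bootstrap"])),
    )
    analysis["seed"] = config.seed
    analysis["config_hash"] = report["config_hash"]
    _write_json(analysis, out / "analysis.json")

    if config.criteria:
        progression = stage("progression", lambda: _progression(cohort, config))
        _write_json(progression, out / "progression.json")
        report["progression_zones"] = {k: v["zone"] for k, v in progression.items()}

        design = stage("design", lambda: _design(config))
        _write_json(design, out / "design.json")

    econ = stage("econ", lambda: _econ(config, seeds["psa"]))
    _write_json(econ, out / "econ.json")
    report["icer"] = econ["deterministic"]["icer"]

    report["itt_difference_kg"] = analysis["weight_change_surgery"]["itt"].estimate
    report["prop_adherent_intervention"] = analysis["adherence"]["prop_adherent_intervention"]
    _write_json(report, out / "run_report.json")
    return report
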
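"""End-to-end experiment runner.

Three phases, mirroring the study pipeline: (1) score the cohort and
derive the short forms by fold-consistency selection; (2) estimate each
short form's detection performance by repeated nested cross-validation;
(3) propagate its diagnostic accuracy into 2-year prognostic accuracy by
Monte Carlo, then run the misclassification, severity and fairness
post-hoc analyses.  All randomness flows from a single root seed split
into named substreams, so an identical config reproduces an identical
report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import __version__
from .instrument import CohortDataset, Instrument, drop_zero_variance
from .simulate import GeneratorConfig, generate_cohort
from .selection import FoldPlan, stability_select
from .evaluation import repeated_nested_cv_evaluate
from .prognosis import (
    META_PRIOR_PRESETS,
    PriorError,
    fixed_prior,
    prior_from_estimate,
    simulate_prognostic,
)
from .posthoc import misclassification_analysis, severity_comparison, subgroup_audit


@dataclass
class ExperimentConfig:
    """Configuration of one full pipeline run."""

    generator: Optional[GeneratorConfig] = None
    data_csv: Optional[Union[str, Path]] = None
    instrument: Optional[Instrument] = None
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    consistency_threshold: int = 4
    n_repeats: int = 5
    n_lambda: int = 100
    meta_prior_preset: str = "metapooled"
    n_sim: int = 10_000
    n_boot: int = 1000
    seed: int = 0
    output_dir: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        if self.generator is None and self.data_csv is None:
            self.generator = GeneratorConfig(seed=self.seed)
        if self.meta_prior_preset not in META_PRIOR_PRESETS:
            raise PriorError(f"unknown meta prior preset {self.meta_prior_preset!r}")


def _substreams(seed: int) -> dict[str, int]:
    names = ("generation", "splitting", "evaluation", "simulation", "audit")
    states = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return {n: int(s) for n, s in zip(names, states)}


def _subset_se_prior(pooled):
    """Diagnostic-sensitivity prior for the prognostic stage, taken from
    the pooled cross-validated estimate (fixed if degenerate)."""
    m = pooled.mean["sensitivity"]
    lo, hi = pooled.ci_low["sensitivity"], pooled.ci_high["sensitivity"]
    return prior_from_estimate(m, max(lo, 1e-6), min(hi, 1 - 1e-9))


def run_full_pipeline(config: ExperimentConfig) -> dict:
    """Run scoring, selection, evaluation, prognosis and post-hoc stages.

    Returns the report as a JSON-serializable dict; if ``output_dir`` is
    set, also writes ``report.json`` and ``report.md`` there.
    """
    seeds = _substreams(config.seed)
    stage = "load"
    try:
        if config.generator is not None:
            stage = "generate"
            gen = config.generator
            dataset = generate_cohort(gen)
        else:
            from .instrument import dichotomize_cohort

            instrument = config.instrument or Instrument.default()
            dataset = CohortDataset.from_csv(config.data_csv, instrument)
            dichotomize_cohort(dataset)

        stage = "score"
        X, y = dataset.analysis_set()
        _reduced, removed = drop_zero_variance(X)
        label_counts = {
            lab: sum(1 for v in dataset.risk_labels.values() if v == lab)
            for lab in ("not_at_risk", "chr_p", "psychosis")
        }

        stage = "select"
        plan = FoldPlan(
            n_outer_folds=config.n_outer_folds,
            n_inner_folds=config.n_inner_folds,
            seed=seeds["splitting"],
        )
        selection = stability_select(
            dataset,
            plan=plan,
            consistency_threshold=config.consistency_threshold,
            n_lambda=config.n_lambda,
        )

        report: dict = {
            "schema_version": 1,
            "package_version": __version__,
            "seed": config.seed,
            "substream_seeds": seeds,
            "cohort": {
                "n_participants": len(dataset.records),
                "label_counts": label_counts,
                "zero_variance_items": removed,
                "synthetic": bool(dataset.provenance),
            },
            "selection": selection.as_dict(),
            "subsets": {},
        }

        eval_plan = FoldPlan(
            n_outer_folds=config.n_outer_folds,
            n_inner_folds=config.n_inner_folds,
            seed=seeds["evaluation"],
        )
        audit_plan = FoldPlan(
            n_outer_folds=config.n_outer_folds,
            n_inner_folds=config.n_inner_folds,
            seed=seeds["audit"],
        )
        meta = META_PRIOR_PRESETS[config.meta_prior_preset]
        for name, items in (("mini", selection.mini_set), ("ultra", selection.ultra_set)):
            if not items:
                report["subsets"][name] = None
                continue
            stage = f"evaluate[{name}]"
            pooled = repeated_nested_cv_evaluate(
                dataset, items, plan=eval_plan, n_repeats=config.n_repeats,
                n_lambda=config.n_lambda,
            )
            stage = f"prognose[{name}]"
            est = simulate_prognostic(
                meta["se_meta"], meta["sp_meta"],
                _subset_se_prior(pooled), fixed_prior(1.0),
                n_sim=config.n_sim, n_boot=config.n_boot, seed=seeds["simulation"],
            )
            stage = f"posthoc[{name}]"
            miscls = misclassification_analysis(dataset, items)
            severity = severity_comparison(dataset, items)
            audits = {
                gf: _audit_dict(subgroup_audit(
                    dataset, items, group_field=gf, plan=audit_plan,
                    n_repeats=config.n_repeats, n_lambda=config.n_lambda,
                ))
                for gf in ("sex", "ethnicity_white")
            }
            report["subsets"][name] = {
                "items": items,
                "detection": pooled.as_dict(),
                "prognosis": {
                    "meta_prior_preset": config.meta_prior_preset,
                    **est.as_dict(),
                },
                "misclassification": miscls.as_dict(),
                "severity_comparison": severity.as_dict(),
                "subgroup_audit": audits,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "report.md", "w") as fh:
            fh.write(render_markdown(report))
    return report


def _audit_dict(audit: dict) -> dict:
    return {
        "group_field": audit["group_field"],
        "strata": {
            str(k): (v.as_dict() if v is not None else None)
            for k, v in audit["strata"].items()
        },
        "difference": audit["difference"],
    }


def render_markdown(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = [
        "# Short-form derivation report",
        "",
        f"- package version: {report['package_version']}",
        f"- root seed: {report['seed']}",
        f"- participants: {report['cohort']['n_participants']} "
        f"({report['cohort']['label_counts']})",
        f"- zero-variance items removed: {len(report['cohort']['zero_variance_items'])}",
        "",
    ]
    for name, sub in report["subsets"].items():
        if sub is None:
            lines += [f"## {name} set", "", "_empty selection_", ""]
            continue
        det = sub["detection"]["mean"]
        prog = sub["prognosis"]
        lines += [
            f"## {name} set ({len(sub['items'])} items)",
            "",
            f"- items: {', '.join(sub['items'])}",
            f"- detection (pooled means): kappa={det['kappa']:.3f}, "
            f"C={det['c_index']:.3f}, Se={det['sensitivity']:.3f}, "
            f"Sp={det['specificity']:.3f}, BA={det['balanced_accuracy']:.3f}, "
            f"PPV={det['ppv']:.3f}, NPV={det['npv']:.3f}, F1={det['f1']:.3f}",
            f"- prognostic accuracy ({prog['meta_prior_preset']} priors): "
            f"Se={prog['se_mean']:.3f} "
            f"[{prog['se_ci'][0]:.3f}, {prog['se_ci'][1]:.3f}], "
            f"Sp={prog['sp_mean']:.3f} "
            f"[{prog['sp_ci'][0]:.3f}, {prog['sp_ci'][1]:.3f}]",
            f"- false negatives: {sub['misclassification']['n_false_negatives']}",
            "",
        ]
    return "\n".join(lines)
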
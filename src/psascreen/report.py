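"""One-shot pipeline: cohort -> diagnostics -> grid search -> comparison -> ROC.

:func:`run_report` loads or simulates a cohort and writes every
table-shaped output of the analysis to a directory: the descriptive
cohort summary, per-rule diagnostic metrics, tumor-recognition tables,
the full scenario grid, the selected cut-offs, the old-vs-new comparison
and per-stratum ROC point lists, plus a manifest recording the package
version, seed and configuration hash. Given the same configuration and
seed the outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from ._util import pct, round_half_away
from .cohort import GROUP_LABELS, PatientRecord, read_cohort, summarize_cohort, write_cohort
from .comparison import compare_rules
from .diagnostics import metrics_by_group, recognition_table
from .gridsearch import ScenarioGrid, SelectionCriterion, evaluate_scenarios, select_cutoffs
from .roc import roc_by_group
from .rules import BiopsyRule, new_rule, old_rule
from .synthetic import default_spec, generate_cohort

__all__ = ["RunConfig", "run_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one cohort source: a CSV path, or synthetic generation
    (``cohort_path=None``) with ``n_per_group`` optionally overriding the
    calibrated default group sizes.
    """

    out_dir: str
    cohort_path: str | None = None
    seed: int = 0
    n_per_group: int | None = None
    old_policy: str = "mirror_new"
    sensitivity_floor: float = 0.88
    ci_level: float = 0.95
    ci_method: str = "wald"
    fpsa_splits: tuple[float, ...] = (18.0, 21.0)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_cohort(config: RunConfig) -> list[PatientRecord]:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    spec = default_spec(seed=config.seed)
    if config.n_per_group is not None:
        groups = {
            label: _replace_n(gp, config.n_per_group) for label, gp in spec.groups.items()
        }
        spec = type(spec)(groups=groups, seed=spec.seed, rp_fraction=spec.rp_fraction,
                          rp_params=spec.rp_params)
    return generate_cohort(spec)


def _replace_n(gp, n):
    from dataclasses import replace

    return replace(gp, n=int(n))


def _metrics_frame(by_group) -> pd.DataFrame:
    rows = []
    for label, summ in by_group.items():
        row: dict[str, object] = {"group": label}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            est = getattr(summ, name)
            if est is None:
                row[f"{name}_pct"] = row[f"{name}_ci_low_pct"] = row[f"{name}_ci_high_pct"] = None
            else:
                p, lo, hi = est.as_pct()
                row[f"{name}_pct"] = p
                row[f"{name}_ci_low_pct"] = lo
                row[f"{name}_ci_high_pct"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def _recognition_frame(table: pd.DataFrame) -> pd.DataFrame:
    out = table.map(lambda v: "No data" if pd.isna(v) else pct(v))
    out.insert(0, "category", out.index)
    return out.reset_index(drop=True)


def _scenario_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        sens = r.summary.sensitivity
        spec = r.summary.specificity
        rows.append(
            {
                "group": r.group_label,
                "fpsa_threshold": r.fpsa_threshold,
                "psa_low": r.psa_low,
                "psa_high": "inf" if math.isinf(r.psa_high) else r.psa_high,
                "n_flagged": r.n_flagged,
                "sensitivity_pct": None if sens is None else pct(sens.point),
                "specificity_pct": None if spec is None else pct(spec.point),
                "ppv_pct": None if r.summary.ppv is None else pct(r.summary.ppv.point),
                "npv_pct": None if r.summary.npv is None else pct(r.summary.npv.point),
            }
        )
    return pd.DataFrame(rows)


def _comparison_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group_label,
                "n": r.n,
                "biopsy_frac_old_pct": pct(r.frac_old),
                "biopsy_frac_new_pct": pct(r.frac_new),
                "difference_pct": pct(r.difference),
                "diff_ci_low_pct": pct(r.diff_ci[0]),
                "diff_ci_high_pct": pct(r.diff_ci[1]),
                "nns": "inf" if r.nns is None else r.nns,
                "nns_ci_low": None if r.nns_ci is None else r.nns_ci[0],
                "nns_ci_high": None
                if r.nns_ci is None
                else ("inf" if math.isinf(r.nns_ci[1]) else r.nns_ci[1]),
                "fisher_p": r.fisher_p,
            }
        )
    return pd.DataFrame(rows)


def _rule_to_dict(rule: BiopsyRule) -> dict:
    return {
        "name": rule.name,
        "groups": {
            label: {
                "fpsa_threshold": gr.fpsa_threshold,
                "psa_low": gr.psa_cutoff_low_fpsa,
                "psa_high": "inf" if math.isinf(gr.psa_cutoff_high_fpsa) else gr.psa_cutoff_high_fpsa,
            }
            for label, gr in rule.groups.items()
        },
    }


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns a name -> path map of the outputs."""
    out_dir = Path(config.out_dir)
    if not out_dir.parent.exists():
        raise FileNotFoundError(f"output location {out_dir.parent} does not exist")
    out_dir.mkdir(exist_ok=True)

    records = _load_cohort(config)
    rule_old = old_rule(config.old_policy)
    rule_new = new_rule()
    outputs: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False)
        outputs[name] = path

    write_cohort(records, out_dir / "cohort.csv")
    outputs["cohort.csv"] = out_dir / "cohort.csv"

    summary = summarize_cohort(records)
    save("cohort_counts.csv", summary.counts.reset_index(names="group"))
    save("cohort_numeric.csv", summary.numeric.reset_index())
    save("cohort_outcome.csv", summary.outcome.reset_index(names="group"))
    save("cohort_gleason.csv", summary.gleason.reset_index(names="group"))
    (out_dir / "cohort_summary.txt").write_text(summary.to_text())
    outputs["cohort_summary.txt"] = out_dir / "cohort_summary.txt"

    for tag, rule in [("old", rule_old), ("new", rule_new)]:
        save(f"metrics_{tag}.csv", _metrics_frame(metrics_by_group(records, rule, config.ci_level)))
        save(f"recognition_{tag}.csv", _recognition_frame(recognition_table(records, rule)))

    scenarios = evaluate_scenarios(records, ScenarioGrid(), config.ci_level)
    save("scenarios.csv", _scenario_frame(scenarios))

    criterion = SelectionCriterion(sensitivity_floor=config.sensitivity_floor)
    outcome = select_cutoffs(scenarios, criterion)
    selected = {
        "criterion": {"sensitivity_floor": criterion.sensitivity_floor,
                      "tie_break": list(criterion.tie_break)},
        "groups": {
            label: (
                "infeasible"
                if sel.infeasible
                else {
                    "fpsa_threshold": sel.chosen.fpsa_threshold,
                    "psa_low": sel.chosen.psa_low,
                    "psa_high": "inf" if math.isinf(sel.chosen.psa_high) else sel.chosen.psa_high,
                    "feasible_scenarios": sel.feasible_count,
                    "specificity_margin": sel.specificity_margin,
                }
            )
            for label, sel in outcome.per_group.items()
        },
    }
    (out_dir / "selected_rule.yaml").write_text(yaml.safe_dump(selected, sort_keys=True))
    outputs["selected_rule.yaml"] = out_dir / "selected_rule.yaml"

    save(
        "comparison.csv",
        _comparison_frame(
            compare_rules(records, rule_old, rule_new, config.ci_level, config.ci_method)
        ),
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate strata
        for split in config.fpsa_splits:
            rows = []
            for label, strat in roc_by_group(records, split).items():
                for side, curve in [("low", strat.low), ("high", strat.high)]:
                    if curve is None:
                        continue
                    for fpr, tpr in curve.points:
                        rows.append(
                            {"group": label, "stratum": side, "split": split,
                             "fpr": fpr, "tpr": tpr, "auc": curve.auc}
                        )
            save(f"roc_split{split:g}.csv", pd.DataFrame(rows))

    manifest = {
        "package": "psascreen",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "rules": {"old": _rule_to_dict(rule_old), "new": _rule_to_dict(rule_new)},
        "outputs": sorted(outputs),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    outputs["manifest.json"] = out_dir / "manifest.json"
    return outputs
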
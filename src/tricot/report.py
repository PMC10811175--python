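"""Automated analysis reports for tricot trials.

``build_report`` runs the full analysis pipeline (design diagnostics, worth
estimation with quasi-variances, probability of outperforming the check,
bootstrap risk assessment, optional covariate tree and cost-effectiveness
comparison) and emits a markdown report together with a JSON bundle whose
tables mirror the markdown bit-exactly.  A failure in any stage aborts the
whole report with the stage name; partial reports are never emitted.

Printing conventions: worths at 4 decimals, currency at 2, percentages as
integers (half away from zero).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from . import design as design_mod
from .exceptions import TricotError, ValidationError
from .plackett_luce import PlackettLuce, risk_assessment
from .tree import fit_pl_tree

__all__ = ["ReportConfig", "percent", "build_report"]

logger = logging.getLogger(__name__)


def percent(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator (full precision).

    Display rounding is half away from zero: ``round_half_away(percent(146,
    739))`` prints 20.
    """
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    return 100.0 * numerator / denominator


def round_half_away(x: float) -> int:
    """Round half away from zero (19.5 -> 20, -19.5 -> -20)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class ReportConfig:
    trait: str = "overall"
    check: str | None = None
    n_draws: int = 200
    alpha: float = 0.05
    seed: int = 0
    tree_minsize: int = 30
    tree_maxdepth: int = 3
    tree_n_perm: int = 199


def _fmt_table(df: pd.DataFrame) -> str:
    """Markdown table from a DataFrame."""
    df = df.reset_index()
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = [
        "| " + " | ".join(str(v) for v in rec) + " |"
        for rec in df.itertuples(index=False)
    ]
    return "\n".join([header, sep] + rows)


class _Stage:
    """Context naming the pipeline stage so failures abort with it."""

    def __init__(self, name):
        self.name = name

    def __enter__(self):
        logger.info("report stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, TricotError):
            raise TricotError(f"report stage {self.name!r} failed: {exc}") from exc
        return False


def build_report(
    config: ReportConfig,
    rankings,
    design: design_mod.Design | None = None,
    covariates: pd.DataFrame | None = None,
    cost_sheets: dict | None = None,
) -> tuple[str, dict]:
    """Assemble the automated trial report.

    ``cost_sheets`` maps arm name -> (CostSheet, n_units, t, k); with two
    arms, a saving percentage of the first versus the second is included.
    Returns (markdown, json_bundle).
    """
    md = [f"# Tricot trial report", "", f"Trait: {config.trait}  |  seed: {config.seed}", ""]
    bundle: dict = {"trait": config.trait, "seed": config.seed}

    if design is not None:
        with _Stage("design"):
            r = design.replication()
            eff = design_mod.canonical_efficiency(design)
            closed = design_mod.relative_efficiency(design.t, design.k)
            d = {
                "t": design.t,
                "b": design.b,
                "k": design.k,
                "replication_min": int(r.min()),
                "replication_max": int(r.max()),
                "canonical_efficiency": round(eff, 4),
                "closed_form_efficiency": round(closed, 4),
            }
            bundle["design"] = d
            md += [
                "## Design",
                "",
                f"t = {d['t']} items, b = {d['b']} blocks of k = {d['k']};"
                f" replication {d['replication_min']}..{d['replication_max']}.",
                f"Canonical efficiency {d['canonical_efficiency']} "
                f"(closed form {d['closed_form_efficiency']}).",
                "",
            ]

    with _Stage("worth model"):
        model = PlackettLuce(rankings)
        model.check_connected()
        res = model.fit()
        qv = res.quasi_variances()
        worth_tab = pd.DataFrame(
            {
                "log_worth": res.params.round(4),
                "worth": res.worth.to_numpy().round(4),
                "quasi_se": (qv.q**0.5).round(4),
            },
            index=res.items,
        ).rename_axis("item")
        bundle["worth"] = {
            it: {
                "log_worth": float(worth_tab.loc[it, "log_worth"]),
                "worth": float(worth_tab.loc[it, "worth"]),
                "quasi_se": float(worth_tab.loc[it, "quasi_se"]),
            }
            for it in res.items
        }
        bundle["loglik"] = round(res.llf, 4)
        bundle["n_rankings"] = res.n_rankings
        md += ["## Worth estimates", "", _fmt_table(worth_tab), ""]

    if config.check is not None:
        if config.check not in res.items:
            raise ValidationError(f"check {config.check!r} not among trial items")
        with _Stage("check comparison"):
            rows = {
                it: round(res.prob_outperform(it, config.check), 4)
                for it in res.items
                if it != config.check
            }
            tab = pd.DataFrame.from_dict(
                rows, orient="index", columns=["p_outperform_check"]
            ).rename_axis("item")
            bundle["prob_outperform"] = {k: float(v) for k, v in rows.items()}
            md += [f"## Probability of outperforming {config.check}", "",
                   _fmt_table(tab), ""]
        with _Stage("risk assessment"):
            draws = res.bayesian_bootstrap(n_draws=config.n_draws, seed=config.seed)
            risk = risk_assessment(draws, config.check).round(4)
            bundle["reliability"] = {
                it: {c: float(risk.loc[it, c]) for c in risk.columns}
                for it in risk.index
            }
            bundle["bootstrap"] = {
                "n_draws": config.n_draws,
                "n_excluded": draws.n_excluded,
                "seed": config.seed,
            }
            md += [f"## Risk assessment vs {config.check} "
                   f"({config.n_draws} Bayesian-bootstrap draws)", "",
                   _fmt_table(risk), ""]

    if covariates is not None:
        with _Stage("covariate tree"):
            tree = fit_pl_tree(
                rankings,
                covariates,
                alpha=config.alpha,
                minsize=config.tree_minsize,
                maxdepth=config.tree_maxdepth,
                n_perm=config.tree_n_perm,
                seed=config.seed,
            )
            bundle["tree"] = tree.to_dict()
            md += ["## Covariate tree", "", "```", tree.summary(), "```", ""]

    if cost_sheets:
        with _Stage("cost-effectiveness"):
            arms = {}
            for name, (sheet, n_units, t, k) in cost_sheets.items():
                rep = design_mod.EfficiencyReport(t, k, n_units, sheet.total)
                arms[name] = rep.to_dict()
            bundle["costs"] = arms
            tab = pd.DataFrame(arms).T.rename_axis("arm")
            md += ["## Cost-effectiveness", "", _fmt_table(tab), ""]
            if len(arms) == 2:
                (name_a, a), (name_b, b) = arms.items()
                saving = design_mod.cost_saving_percent(
                    a["cost_per_EEU"], b["cost_per_EEU"]
                )
                bundle["costs"]["saving_percent"] = saving
                md += [f"{name_a} costs {saving}% less per EEU than {name_b}.", ""]

    return "\n".join(md), bundle


def write_report(markdown: str, bundle: dict, md_path, json_path) -> None:
    with open(md_path, "w", encoding="utf-8") as fh:
        fh.write(markdown)
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=1)
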
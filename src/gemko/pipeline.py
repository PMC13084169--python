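"""End-to-end knockout analysis: load, simulate, sweep, report.

:func:`run_full_analysis` chains every stage — model loading, knockout
simulation at the primary optimality fraction, capacity sweep of the
disabled reactions, threshold-robustness sweep and reporter-metabolite
analysis — and writes five TSV tables plus a JSON run manifest:

=========================  =================================================
``table1_growth.tsv``      WT/KO biomass optima and relative change
``table2_capacity.tsv``    fraction x disabled-reaction max-capacity matrix
``table3_ranges.tsv``      per-reaction WT/KO ranges, Δrange, classification
``table4_robustness.tsv``  affected counts and set identity per fraction
``table5_accumulation.tsv``  accumulating metabolites with categories
``manifest.json``          config, model checksum, solver, versions
=========================  =================================================

Every aggregate in the summary tables is recomputable from the
per-reaction detail in ``table3_ranges.tsv``; reruns with identical
config and model produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import gemko

from .lp import FEASIBILITY_TOLERANCE, fba, fva
from .model import MetabolicModel, read_json_model
from .perturbation import (
    NOISE_RETEST_TOLERANCE,
    SIGNIFICANCE_THRESHOLD,
    KnockoutResult,
    simulate_knockout,
    subsystem_distribution,
)
from .reporters import (
    BLOCKED_TOLERANCE,
    AccumulationReport,
    compartment_summary,
    find_accumulating,
)
from .sensitivity import DEFAULT_FRACTIONS, RobustnessResult, capacity_curve, threshold_robustness

__all__ = ["AnalysisConfig", "ReportBundle", "load_model", "run_full_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything a reproducible knockout analysis run needs."""

    model_path: str
    gene: str
    output_dir: str
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    report_fraction: float = 0.9
    significance_threshold: float = SIGNIFICANCE_THRESHOLD
    feasibility_tolerance: float = FEASIBILITY_TOLERANCE
    blocked_tolerance: float = BLOCKED_TOLERANCE
    noise_retest_tolerance: float = NOISE_RETEST_TOLERANCE
    scope: str = "affected_universe"  # or "all_metabolites"

    def validate(self) -> None:
        problems = []
        if not all(0.0 <= f <= 1.0 for f in self.fractions):
            problems.append("fractions must lie in [0, 1]")
        if not 0.0 <= self.report_fraction <= 1.0:
            problems.append("report_fraction must lie in [0, 1]")
        if self.significance_threshold <= 0:
            problems.append("significance_threshold must be > 0")
        for name in (
            "feasibility_tolerance",
            "blocked_tolerance",
            "noise_retest_tolerance",
        ):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.scope not in ("affected_universe", "all_metabolites"):
            problems.append(
                "scope must be 'affected_universe' or 'all_metabolites'"
            )
        if problems:
            raise ValueError("invalid config:\n  - " + "\n  - ".join(problems))

    def to_dict(self) -> dict:
        return {
            "model_path": str(self.model_path),
            "gene": self.gene,
            "output_dir": str(self.output_dir),
            "fractions": list(self.fractions),
            "report_fraction": self.report_fraction,
            "significance_threshold": self.significance_threshold,
            "feasibility_tolerance": self.feasibility_tolerance,
            "blocked_tolerance": self.blocked_tolerance,
            "noise_retest_tolerance": self.noise_retest_tolerance,
            "scope": self.scope,
        }


@dataclass
class ReportBundle:
    """In-memory results plus the paths of everything written."""

    config: AnalysisConfig
    knockout: KnockoutResult
    robustness: RobustnessResult
    accumulation: AccumulationReport
    tables: dict[str, Path] = field(default_factory=dict)
    manifest_path: Path | None = None


def load_model(path: str | Path) -> MetabolicModel:
    """Load a model, dispatching on extension: ``.json`` for the package
    dialect, ``.xml``/``.sbml`` for SBML Level 3 + FBC."""
    path = Path(path)
    if path.suffix == ".json":
        return read_json_model(path)
    if path.suffix in (".xml", ".sbml"):
        from .sbml import read_sbml

        return read_sbml(path)
    raise ValueError(
        f"cannot infer model format from extension {path.suffix!r} "
        "(expected .json, .xml or .sbml)"
    )


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run every stage of the knockout analysis and write the report bundle.

    On a stage failure the exception propagates after a ``FAILED`` marker
    file is written to the output directory, so partial outputs are
    identifiable as such.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.perf_counter()
    try:
        bundle = _run(config, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    logger.info(
        "analysis finished in %.2f s (%d reactions evaluated)",
        time.perf_counter() - started,
        len(bundle.knockout.records),
    )
    return bundle


def _run(config: AnalysisConfig, outdir: Path) -> ReportBundle:
    model = load_model(config.model_path)
    if not model.reactions_for_gene(config.gene):
        logger.warning(
            "gene %s is not referenced by any GPR in %s",
            config.gene,
            config.model_path,
        )

    ko = simulate_knockout(
        model,
        config.gene,
        config.report_fraction,
        threshold=config.significance_threshold,
        tolerance=config.feasibility_tolerance,
        retest_tolerance=config.noise_retest_tolerance,
    )

    tables: dict[str, Path] = {}

    growth = pd.DataFrame(
        {
            "model": ["wild-type", f"{config.gene} knockout"],
            "max_biomass_flux": [_fmt(ko.wt_biomass), _fmt(ko.ko_biomass)],
            "relative_change": [
                "-",
                f"{100 * ko.relative_growth_change:.0f}%",
            ],
        }
    )
    tables["growth"] = outdir / "table1_growth.tsv"
    growth.to_csv(tables["growth"], sep="\t", index=False)

    disabled = sorted(ko.disabled_reactions)
    sweep_rows = []
    curves = {
        rid: capacity_curve(
            model, rid, config.fractions, tolerance=config.feasibility_tolerance
        )
        for rid in disabled
    }
    for f in sorted(set(config.fractions), reverse=True):
        row = {"optimality_percent": f"{100 * f:.0f}"}
        for rid in disabled:
            row[rid] = _fmt(curves[rid].capacity_at(f))
        sweep_rows.append(row)
    tables["capacity"] = outdir / "table2_capacity.tsv"
    pd.DataFrame(sweep_rows).to_csv(tables["capacity"], sep="\t", index=False)

    detail = pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "subsystem": r.subsystem,
                "wt_min": repr(r.wt_range.min_flux),
                "wt_max": repr(r.wt_range.max_flux),
                "ko_min": repr(r.ko_range.min_flux),
                "ko_max": repr(r.ko_range.max_flux),
                "delta_range": repr(r.delta_range),
                "classification": r.classification,
            }
            for r in sorted(ko.records, key=lambda r: (-r.delta_range, r.reaction_id))
        ]
    )
    tables["ranges"] = outdir / "table3_ranges.tsv"
    detail.to_csv(tables["ranges"], sep="\t", index=False)

    sweep_fractions = [f for f in config.fractions if f < 1.0]
    robustness = threshold_robustness(
        model,
        config.gene,
        sweep_fractions,
        config.significance_threshold,
        tolerance=config.feasibility_tolerance,
    )
    rob_rows = [
        {
            "optimality_percent": f"{100 * f:.0f}",
            "affected_reactions": s.affected_count,
            "subsystem_distribution": "; ".join(
                f"{sub}: {n}" for sub, n in s.subsystems.items()
            ),
        }
        for f, s in robustness.per_fraction.items()
    ]
    tables["robustness"] = outdir / "table4_robustness.tsv"
    pd.DataFrame(rob_rows).to_csv(tables["robustness"], sep="\t", index=False)

    report_summary = robustness.per_fraction.get(config.report_fraction)
    if report_summary is not None:
        ko_at_report = report_summary.result
    else:
        ko_at_report = ko
    wt_ranges = {r.reaction_id: r.wt_range for r in ko_at_report.records}
    ko_ranges = {r.reaction_id: r.ko_range for r in ko_at_report.records}
    if config.scope == "affected_universe":
        universe = list(
            dict.fromkeys(
                met_id
                for rec in ko_at_report.affected
                for met_id in model.get_reaction(rec.reaction_id).stoichiometry
            )
        )
    else:
        universe = None
    accumulation = find_accumulating(
        model,
        wt_ranges,
        ko_ranges,
        universe,
        gene=config.gene,
        tol=config.blocked_tolerance,
    )
    acc_rows = [
        {
            "metabolite_id": c.metabolite_id,
            "compartment": c.compartment,
            "category": c.category,
            "consuming_reactions": "; ".join(c.consuming_reactions),
        }
        for c in accumulation.candidates
    ]
    tables["accumulation"] = outdir / "table5_accumulation.tsv"
    pd.DataFrame(
        acc_rows,
        columns=[
            "metabolite_id",
            "compartment",
            "category",
            "consuming_reactions",
        ],
    ).to_csv(tables["accumulation"], sep="\t", index=False)

    manifest = {
        "config": config.to_dict(),
        "model_sha256": hashlib.sha256(
            Path(config.model_path).read_bytes()
        ).hexdigest(),
        "solver": "scipy.optimize.linprog (HiGHS)",
        "package_version": gemko.__version__,
        "model_size": {
            "reactions": len(model.reactions),
            "metabolites": len(model.metabolites),
            "genes": len(model.genes),
        },
        "disabled_reactions": disabled,
        "classification_counts": ko.counts(),
        "affected_sets_identical_across_fractions": robustness.sets_identical,
        "accumulating_candidates": accumulation.count,
        "compartment_summary": {
            comp: {"count": n, "percent": p}
            for comp, (n, p) in compartment_summary(accumulation).items()
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return ReportBundle(
        config=config,
        knockout=ko,
        robustness=robustness,
        accumulation=accumulation,
        tables=tables,
        manifest_path=manifest_path,
    )
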
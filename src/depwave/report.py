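"""Advisor report rendering: machine-readable JSON + human-readable text.

The JSON schema is versioned so downstream parsers can detect layout
changes; all numeric fields round-trip through ``json`` at full double
precision (``repr``-faithful floats).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .config import RunConfig
from .force_analysis import BenefitReport, advise

__all__ = ["REPORT_SCHEMA_VERSION", "ReportBundle", "report_to_dict", "render_text", "run_report"]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ReportBundle:
    report: BenefitReport
    as_dict: dict
    text: str

    @property
    def json(self) -> str:
        return json.dumps(self.as_dict, indent=2, sort_keys=True)


def report_to_dict(report: BenefitReport) -> dict:
    dec = report.decomposition
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "f0_hz": report.f0,
        "fco_hz": report.fco,
        "boundary_frequency_hz": report.boundary_frequency,
        "energy_rule": report.beneficial_energy_rule.value,
        "beneficial_exact": report.beneficial_exact,
        "gain_ratio": report.gain_ratio,
        "rules_disagree": report.rules_disagree,
        "force": {
            "fundamental_n": dec.fundamental,
            "positive_sum_a_n": dec.positive_sum,
            "negative_sum_b_n": dec.negative_sum,
            "total_n": dec.total,
            "sine_baseline_n": dec.sine_baseline,
        },
        "contributions": [
            {
                "order": c.order,
                "frequency_hz": c.frequency,
                "re_cm": c.re_cm,
                "force_n": c.force,
            }
            for c in dec.contributions
            if c.force != 0.0 or c.order == 1
        ],
    }


def render_text(report: BenefitReport) -> str:
    dec = report.decomposition
    lines = [
        "DEP waveform advisor",
        "====================",
        f"fundamental frequency f0 : {report.f0:.6g} Hz",
        f"cross-over frequency fco : "
        + (f"{report.fco:.6g} Hz" if report.fco is not None else "none (no sign change)"),
        f"energy-rule boundary fco/5 : "
        + (f"{report.boundary_frequency:.6g} Hz" if report.boundary_frequency is not None else "n/a"),
        f"energy rule verdict      : {report.beneficial_energy_rule.value}",
        f"exact decomposition      : "
        + ("beneficial" if report.beneficial_exact else "not beneficial")
        + f" (gain ratio {report.gain_ratio:.4f} vs equal-amplitude sine)",
        "",
        "force budget (N):",
        f"  fundamental : {dec.fundamental: .4e}",
        f"  harmonics A : {dec.positive_sum: .4e}  (same-sign)",
        f"  harmonics B : {dec.negative_sum: .4e}  (opposing)",
        f"  total       : {dec.total: .4e}",
        f"  sine basis  : {dec.sine_baseline: .4e}",
    ]
    if report.rules_disagree:
        lines.append("")
        lines.append(
            "note: the conservative energy rule and the exact decomposition disagree; "
            "the energy rule is sufficient, not necessary — trust the decomposition."
        )
    return "\n".join(lines)


def run_report(config: RunConfig) -> ReportBundle:
    """Run the advisor from a validated configuration."""
    system = config.system.build()
    report = advise(
        system,
        config.waveform.f0,
        v0=config.waveform.v0,
        max_order=config.waveform.max_order,
        bandwidth_limit=config.waveform.bandwidth_limit,
        rolloff=config.waveform.rolloff,
        field_gradient=config.analysis.field_gradient,
        comparison=config.analysis.comparison,
    )
    return ReportBundle(report=report, as_dict=report_to_dict(report), text=render_text(report))
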
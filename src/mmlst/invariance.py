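"""Measurement-invariance sequences and decision criteria.

The sequence fits the same model at increasingly restrictive invariance
levels across a facet (methods or situations): the time-invariant default
model as the least restrictive member, then metric (equal loadings), scalar
(equal intercepts) and residual (equal error variances) invariance. Steps
are compared with change-in-fit criteria for large samples: non-invariance
at a step is indicated by a CFI drop of at least .010 together with either
an RMSEA increase of at least .015 or an SRMR increase of at least .030
(metric) or .010 (scalar, residual). The CFI condition alone is additionally
flagged without flipping the conjunctive decision, so both readings of the
rule are recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .builder import build_model
from .design import (
    INVARIANCE_ORDER,
    DesignSpec,
    InvarianceLevel,
    ModelOptions,
)
from .estimation import (
    ConvergenceError,
    FitResult,
    chisq_difference_test,
    fit_model,
)

__all__ = ["ChenDecision", "InvarianceReport", "chen_decision",
           "invariance_sequence", "CHEN_THRESHOLDS"]

#: Decision thresholds: (CFI drop, RMSEA increase, SRMR increase) per step.
CHEN_THRESHOLDS = {
    "metric": {"dcfi": -0.010, "drmsea": 0.015, "dsrmr": 0.030},
    "scalar": {"dcfi": -0.010, "drmsea": 0.015, "dsrmr": 0.010},
    "residual": {"dcfi": -0.010, "drmsea": 0.015, "dsrmr": 0.010},
}


@dataclass
class ChenDecision:
    """Outcome of the change-in-fit rule at one invariance step."""

    step: str
    invariant: bool
    cfi_criterion_exceeded: bool
    trace: str
    thresholds: dict


def chen_decision(
    dcfi: float,
    drmsea: float,
    dsrmr: float,
    step: str | InvarianceLevel,
    n: int = 1000,
) -> ChenDecision:
    """Apply the large-sample change-in-fit rule to one step's deltas.

    Sign convention: ``dcfi`` is (more restrictive - less restrictive), so a
    deterioration is negative; ``drmsea`` and ``dsrmr`` deteriorations are
    positive. Thresholds are inclusive. The rule is calibrated for n > 300;
    smaller samples get the same rule and a warning note in the trace.
    """
    step = InvarianceLevel(step).value if not isinstance(step, str) else step
    if step not in CHEN_THRESHOLDS:
        raise ValueError(
            f"step must be metric, scalar or residual; got {step!r}"
        )
    thr = CHEN_THRESHOLDS[step]
    cfi_hit = dcfi <= thr["dcfi"]
    rmsea_hit = drmsea >= thr["drmsea"]
    srmr_hit = dsrmr >= thr["dsrmr"]
    noninvariant = cfi_hit and (rmsea_hit or srmr_hit)
    parts = [
        f"dCFI={dcfi:+.4f} ({'<=' if cfi_hit else '>'} {thr['dcfi']:+.3f})",
        f"dRMSEA={drmsea:+.4f} ({'>=' if rmsea_hit else '<'} "
        f"{thr['drmsea']:.3f})",
        f"dSRMR={dsrmr:+.4f} ({'>=' if srmr_hit else '<'} {thr['dsrmr']:.3f})",
    ]
    if n <= 300:
        parts.append(f"warning: rule calibrated for n > 300 (n={n})")
    return ChenDecision(
        step=step,
        invariant=not noninvariant,
        cfi_criterion_exceeded=cfi_hit,
        trace="; ".join(parts),
        thresholds=dict(thr),
    )


@dataclass
class InvarianceReport:
    """Ordered fits with per-step index changes and decisions."""

    facet: str
    levels: list[str]
    fits: list[FitResult]
    steps: list[dict] = field(default_factory=list)
    truncated_at: str | None = None
    status: str = "complete"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def invariance_sequence(
    data,
    design: DesignSpec,
    options: ModelOptions,
    facet: str,
    thresholds: dict | None = None,
    seed: int = 0,
) -> InvarianceReport:
    """Fit the configural-to-residual sequence across a facet and decide
    each step.

    The base (time-invariance) model is the least restrictive member. A mean
    structure is required for the scalar step and is switched on for the
    whole sequence so that all models stay nested. Non-convergence at a step
    truncates the report there.
    """
    if facet not in ("methods", "situations"):
        raise ValueError("facet must be 'methods' or 'situations'")
    thresholds = thresholds or CHEN_THRESHOLDS
    fits: list[FitResult] = []
    steps: list[dict] = []
    levels_done: list[str] = []
    prev: FitResult | None = None
    for level in INVARIANCE_ORDER:
        opts = options.copy()
        opts.mean_structure = True
        opts.invariance_facet = facet
        opts.invariance_level = level
        graph = build_model(design, opts)
        try:
            fit = fit_model(data, graph, seed=seed)
        except ConvergenceError:
            return InvarianceReport(
                facet=facet,
                levels=levels_done,
                fits=fits,
                steps=steps,
                truncated_at=level.value,
                status=f"non-convergence at the {level.value} step",
            )
        if prev is not None and fit.df <= prev.df:
            # nothing was added at this level (all candidate constraints were
            # already in place); keep the fit but note it
            steps.append(
                {
                    "step": level.value,
                    "note": "no additional constraints at this level",
                    "chisq": fit.chisq,
                    "df": fit.df,
                }
            )
            fits.append(fit)
            levels_done.append(level.value)
            prev = fit
            continue
        row: dict = {
            "step": level.value,
            "chisq": fit.chisq,
            "df": fit.df,
            "cfi": fit.indices["cfi"],
            "rmsea": fit.indices["rmsea"],
            "srmr": fit.indices["srmr"],
        }
        if prev is not None:
            dchi, ddf, p = chisq_difference_test(fit, prev)
            dcfi = fit.indices["cfi"] - prev.indices["cfi"]
            drmsea = fit.indices["rmsea"] - prev.indices["rmsea"]
            dsrmr = fit.indices["srmr"] - prev.indices["srmr"]
            thr_step = level.value if level.value in thresholds else "metric"
            decision = chen_decision(
                dcfi, drmsea, dsrmr, thr_step, n=fit.n_used
            )
            row.update(
                {
                    "dchisq": dchi,
                    "ddf": ddf,
                    "p": p,
                    "dcfi": dcfi,
                    "drmsea": drmsea,
                    "dsrmr": dsrmr,
                    "decision": "invariant" if decision.invariant
                    else "non-invariant",
                    "cfi_flag": decision.cfi_criterion_exceeded,
                    "trace": decision.trace,
                }
            )
        steps.append(row)
        fits.append(fit)
        levels_done.append(level.value)
        prev = fit
    return InvarianceReport(
        facet=facet, levels=levels_done, fits=fits, steps=steps
    )
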
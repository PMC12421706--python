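"""Report assembly: JSON/text serialisation of fits and coefficients.

The text report is organised in three panels:
a model summary (estimator, free parameters, sample size, chi-square test),
fit indices with benchmark annotations, the parameter table with the
coefficient tables, and the generated model syntax.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .coefficients import CoefficientTable
from .estimation import FitResult, fit_indices
from .graph import ParamGraph
from .syntax import export_model_syntax

__all__ = ["fit_to_dict", "fit_from_dict_equal", "write_report", "render_report"]


def fit_to_dict(fit: FitResult) -> dict:
    """JSON-serializable summary of a fit."""
    return {
        "estimator": fit.estimator,
        "n_used": fit.n_used,
        "n_free": fit.n_free,
        "df": fit.df,
        "loglik": fit.loglik,
        "loglik_saturated": fit.loglik_saturated,
        "loglik_baseline": fit.loglik_baseline,
        "chisq": fit.chisq,
        "pvalue": fit.pvalue,
        "converged": fit.converged,
        "negative_variances": fit.negative_variances,
        "latent_cov_psd": fit.latent_cov_psd,
        "indices": {
            k: v for k, v in fit.indices.items() if not isinstance(v, dict)
        },
        "estimates": fit.estimates,
        "se": fit.se,
        "z": fit.zstat,
    }


def fit_from_dict_equal(fit: FitResult, payload: dict, tol=1e-10) -> bool:
    """Check that a serialized payload round-trips to the in-memory fit."""
    own = fit_to_dict(fit)

    def eq(a, b):
        if isinstance(a, dict) and isinstance(b, dict):
            return set(a) == set(b) and all(eq(a[k], b[k]) for k in a)
        if isinstance(a, float) and isinstance(b, float):
            if np.isnan(a) and np.isnan(b):
                return True
            return abs(a - b) <= tol * (1 + abs(a))
        return a == b

    return eq(own, payload)


def render_report(
    fit: FitResult,
    coeffs: CoefficientTable | None = None,
    graph: ParamGraph | None = None,
) -> str:
    graph = graph or fit.graph
    lines: list[str] = []
    lines.append("=" * 70)
    lines.append("Model Summary & Coefficients")
    lines.append("=" * 70)
    lines.append(f"Estimator:            {fit.estimator}")
    lines.append(f"Free parameters:      {fit.n_free}")
    lines.append(f"Sample size used:     {fit.n_used}")
    lines.append(
        f"Chi-square:           {fit.chisq:.3f} (df = {fit.df}, "
        f"p = {fit.pvalue:.4f})"
    )
    lines.append(f"Converged:            {fit.converged}")
    if fit.negative_variances:
        lines.append(
            "WARNING: negative variance estimates (inadmissible solution): "
            + ", ".join(fit.negative_variances)
        )
    if not fit.latent_cov_psd:
        lines.append(
            "WARNING: implied latent covariance matrix is not positive "
            "semidefinite"
        )
    if coeffs is not None:
        lines.append("")
        lines.append("Indicator coefficients (Con / Spe / method share / Rel):")
        lines.append(coeffs.indicator.to_string(index=False))
        if len(coeffs.trait):
            lines.append("")
            lines.append("Trait commonality across situations:")
            lines.append(coeffs.trait.to_string(index=False))
        if len(coeffs.trait_method):
            lines.append("")
            lines.append("Trait-method commonality across situations:")
            lines.append(coeffs.trait_method.to_string(index=False))
    lines.append("")
    lines.append("=" * 70)
    lines.append("Model Fit & Parameters")
    lines.append("=" * 70)
    indices = fit_indices(fit)
    bench = indices.pop("benchmarks")
    for key in (
        "chisq", "df", "pvalue", "chisq_df_ratio", "cfi", "tli",
        "rmsea", "rmsea_ci_lower", "rmsea_ci_upper", "srmr", "aic", "bic",
    ):
        note = ""
        if key == "chisq_df_ratio":
            note = "  [acceptable <= 3]" if bench["chisq_df_ratio<=3"] else "  [above 3]"
        elif key == "cfi":
            note = "  [acceptable >= 0.90]" if bench["cfi>=0.90"] else "  [below 0.90]"
        elif key == "tli":
            note = "  [acceptable >= 0.90]" if bench["tli>=0.90"] else "  [below 0.90]"
        elif key == "rmsea":
            note = "  [acceptable <= 0.08]" if bench["rmsea<=0.08"] else "  [above 0.08]"
        elif key == "srmr":
            note = "  [acceptable <= 0.10]" if bench["srmr<=0.10"] else "  [above 0.10]"
        lines.append(f"{key:<16}{indices[key]:>12.4f}{note}")
    lines.append("")
    lines.append("Parameter estimates:")
    lines.append(fit.parameter_table().to_string(index=False))
    lines.append("")
    lines.append("=" * 70)
    lines.append("Model Syntax")
    lines.append("=" * 70)
    lines.append(export_model_syntax(graph))
    return "\n".join(lines)


def write_report(
    fit: FitResult,
    coeffs: CoefficientTable | None,
    graph: ParamGraph | None,
    out: str | Path,
    stem: str = "model",
) -> dict[str, Path]:
    """Write syntax, fit JSON, coefficient CSV and text report to ``out``.

    Returns the mapping of artifact kind to path.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    graph = graph or fit.graph
    paths = {
        "syntax": out / f"{stem}_syntax.lav",
        "fit_json": out / f"{stem}_fit.json",
        "coefficients_csv": out / f"{stem}_coefficients.csv",
        "report_txt": out / f"{stem}_report.txt",
    }
    paths["syntax"].write_text(export_model_syntax(graph))
    with open(paths["fit_json"], "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=2)
    if coeffs is not None:
        coeffs.to_csv(paths["coefficients_csv"])
    else:
        paths.pop("coefficients_csv")
    paths["report_txt"].write_text(render_report(fit, coeffs, graph))
    return paths
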
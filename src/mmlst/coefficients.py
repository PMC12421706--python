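"""LST variance-decomposition and cross-situation generalizability
coefficients.

Per indicator, with model-implied variances:

    Con(Y_imts) = lambda_ims^2 Var(T_11s) / Var(Y_imts)
    Spe(Y_imts) = delta_ims^2 Var(O_11ts) / Var(Y_imts)
    Rel(Y_imts) = 1 - Var(eps_imts) / Var(Y_imts)

Consistency and specificity deliberately exclude method variance (the
trait-method and occasion-method shares), which is reported separately so
that Con + Spe + method share = Rel. Across situations, commonality is the
squared correlation of corresponding trait (or trait-method) factors,
Comm = Corr(F_1, F_s)^2, and situation specificity its complement 1 - Comm.
Both parametrizations (correlated factors or latent change scores) yield the
correlations through the implied latent covariance matrix, so the
coefficients are parametrization-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .builder import occasion_name, om_name, tm_name, trait_name
from .design import manifest_layout
from .estimation import FitResult

__all__ = [
    "CoefficientTable",
    "indicator_coefficients",
    "trait_commonality",
    "tm_commonality",
    "compute_coefficients",
]


class UndefinedCorrelationError(ValueError):
    """A commonality was requested for a factor with zero variance."""


def _random_theta(model, seed: int = 12345) -> np.ndarray:
    """A generic interior parameter point, used to detect structural zeros in
    the implied latent covariance (a modeled association is nonzero at a
    generic point; an unmodeled one is identically zero)."""
    rng = np.random.default_rng(seed)
    theta = np.empty(model.n_free)
    for k, role in enumerate(model.roles):
        if role == "variance":
            theta[k] = rng.uniform(0.5, 1.5)
        elif role == "covariance":
            theta[k] = rng.uniform(0.15, 0.35)
        elif role in ("loading", "regression"):
            theta[k] = rng.uniform(0.4, 0.9)
        else:
            theta[k] = rng.uniform(-0.5, 0.5)
    return theta


def _linked(model, ka: int, kb: int) -> bool:
    phi, _ = model.latent_moments(_random_theta(model))
    return abs(phi[ka, kb]) > 1e-12


def indicator_coefficients(
    fit: FitResult, graph=None
) -> pd.DataFrame:
    """Per-indicator consistency, specificity, method share and reliability.

    Any negative variance estimate entering a coefficient marks the row
    inadmissible (the number is still reported for diagnosis).
    """
    graph = graph or fit.graph
    model = fit.model
    lam, beta, psi, thet, nu, alpha = model.matrices(fit.theta)
    phi, _ = model.latent_moments(fit.theta)
    sigma = fit.implied.sigma
    design = graph.design
    rows = []
    for row, (i, m, t, s) in enumerate(manifest_layout(design)):
        var_y = sigma[row, row]
        kt = graph.latent_index(trait_name(s))
        ko = graph.latent_index(occasion_name(t, s))
        con = lam[row, kt] ** 2 * phi[kt, kt] / var_y
        spe = lam[row, ko] ** 2 * phi[ko, ko] / var_y
        method = 0.0
        inadmissible = phi[kt, kt] < 0 or phi[ko, ko] < 0 or var_y <= 0
        try:
            ktm = graph.latent_index(tm_name(i, m, s))
        except KeyError:
            ktm = None
        if ktm is not None and lam[row, ktm] != 0.0:
            method += lam[row, ktm] ** 2 * phi[ktm, ktm] / var_y
            inadmissible = inadmissible or phi[ktm, ktm] < 0
        try:
            kom = graph.latent_index(om_name(m, t, s))
        except KeyError:
            kom = None
        if kom is not None and lam[row, kom] != 0.0:
            method += lam[row, kom] ** 2 * phi[kom, kom] / var_y
            inadmissible = inadmissible or phi[kom, kom] < 0
        rel = 1.0 - thet[row] / var_y
        inadmissible = inadmissible or thet[row] < 0
        rows.append(
            {
                "variable": graph.manifest_names[row],
                "i": i,
                "m": m,
                "t": t,
                "s": s,
                "con": float(con),
                "spe": float(spe),
                "method_share": float(method),
                "rel": float(rel),
                "inadmissible": bool(inadmissible),
            }
        )
    return pd.DataFrame(rows)


def trait_commonality(fit: FitResult) -> pd.DataFrame:
    """Commonality and situation specificity of the trait factors.

    For each non-reference situation s, Comm(T_11s) = Corr(T_111, T_11s)^2
    and SitSpe = 1 - Comm. Under the latent change-score parametrization the
    correlation follows from Cov(T_1, T_s) = (1 + beta_1s) Var(T_1) and
    Var(T_s) = (1 + beta_1s)^2 Var(T_1) + Var(omega_s), which the implied
    latent covariance encodes. Situations whose traits have no modeled
    association are reported as unavailable.
    """
    graph = fit.graph
    model = fit.model
    phi, _ = model.latent_moments(fit.theta)
    k1 = graph.latent_index(trait_name(1))
    rows = []
    for s in range(2, graph.design.n_situations + 1):
        ks = graph.latent_index(trait_name(s))
        v1, vs = phi[k1, k1], phi[ks, ks]
        if v1 <= 0 or vs <= 0:
            raise UndefinedCorrelationError(
                f"trait variance non-positive for situation pair (1, {s}); "
                "commonality undefined"
            )
        if not _linked(model, k1, ks):
            rows.append(
                {"s": s, "corr": np.nan, "comm": np.nan, "sitspe": np.nan,
                 "available": False}
            )
            continue
        corr = phi[k1, ks] / np.sqrt(v1 * vs)
        comm = corr**2
        rows.append(
            {"s": s, "corr": float(corr), "comm": float(comm),
             "sitspe": float(1.0 - comm), "available": True}
        )
    return pd.DataFrame(rows)


def tm_commonality(fit: FitResult) -> pd.DataFrame:
    """Commonality of corresponding trait-method factors across situations.

    Pairs without a modeled association (no covariance set, structural
    regression or custom line linking them) are reported as unavailable
    rather than zero.
    """
    graph = fit.graph
    model = fit.model
    phi, _ = model.latent_moments(fit.theta)
    design = graph.design
    rows = []
    cells = [
        (i, m)
        for m in range(1, design.n_methods + 1)
        for i in range(1, design.n_indicators + 1)
        if (i, m) != (1, 1)
    ]
    for s in range(2, design.n_situations + 1):
        for (i, m) in cells:
            try:
                k1 = graph.latent_index(tm_name(i, m, 1))
                ks = graph.latent_index(tm_name(i, m, s))
            except KeyError:
                continue
            v1, vs = phi[k1, k1], phi[ks, ks]
            base = {"i": i, "m": m, "s": s}
            if v1 <= 0 or vs <= 0:
                raise UndefinedCorrelationError(
                    f"trait-method variance non-positive for (i={i}, m={m}, "
                    f"s={s}); commonality undefined"
                )
            if not _linked(model, k1, ks):
                rows.append(
                    {**base, "corr": np.nan, "comm": np.nan,
                     "sitspe": np.nan, "available": False}
                )
                continue
            corr = phi[k1, ks] / np.sqrt(v1 * vs)
            comm = corr**2
            rows.append(
                {**base, "corr": float(corr), "comm": float(comm),
                 "sitspe": float(1.0 - comm), "available": True}
            )
    return pd.DataFrame(rows)


@dataclass
class CoefficientTable:
    """All model coefficients: per-indicator shares and cross-situation
    commonalities."""

    indicator: pd.DataFrame
    trait: pd.DataFrame
    trait_method: pd.DataFrame

    def to_csv(self, path) -> None:
        frames = []
        ind = self.indicator.copy()
        ind.insert(0, "table", "indicator")
        frames.append(ind)
        if len(self.trait):
            tr = self.trait.copy()
            tr.insert(0, "table", "trait_commonality")
            frames.append(tr)
        if len(self.trait_method):
            tmf = self.trait_method.copy()
            tmf.insert(0, "table", "tm_commonality")
            frames.append(tmf)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def compute_coefficients(fit: FitResult) -> CoefficientTable:
    """Assemble the full coefficient table from a fitted model."""
    design = fit.graph.design
    if design.n_situations >= 2:
        trait = trait_commonality(fit)
        tm = tm_commonality(fit)
    else:
        trait = pd.DataFrame(
            columns=["s", "corr", "comm", "sitspe", "available"]
        )
        tm = pd.DataFrame(
            columns=["i", "m", "s", "corr", "comm", "sitspe", "available"]
        )
    return CoefficientTable(
        indicator=indicator_coefficients(fit),
        trait=trait,
        trait_method=tm,
    )
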
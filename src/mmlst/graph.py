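"""Symbolic parameter graph for linear latent-variable models.

A :class:`ParamGraph` holds the model in LISREL-style matrices with symbolic
entries: measurement loadings (manifest x latent), latent regressions
(latent x latent), latent covariances, error variances, manifest intercepts
and latent means. Each entry is either a fixed number or a reference to a
named :class:`Parameter`; two entries referencing the same label are
constrained equal and consume one free parameter.

The graph is purely symbolic. :meth:`ParamGraph.compile` freezes it into
index arrays that the estimation routines fill with a numeric parameter
vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignSpec, ModelOptions

__all__ = ["Parameter", "Latent", "ParamGraph", "CompiledModel"]

Ref = tuple  # ("fix", value) | ("par", label)


class UnderIdentifiedError(ValueError):
    """Model has more free parameters than modeled sample moments."""


@dataclass
class Parameter:
    """A free model parameter (possibly shared across several entries)."""

    label: str
    role: str  # loading, intercept, variance, covariance, regression, mean
    start: float = 0.0
    indices: tuple = ()


@dataclass
class Latent:
    """A latent variable node.

    ``kind`` is one of trait, occasion, trait_method, occasion_method,
    trait_difference, tm_difference. Index tuples are 1-based (i, m, t, s)
    components as applicable.
    """

    name: str
    kind: str
    indices: tuple = ()


def _is_par(ref: Ref) -> bool:
    return ref[0] == "par"


@dataclass
class ParamGraph:
    """Symbolic model: latents, entries, parameters, plus a change log."""

    design: DesignSpec
    options: ModelOptions
    manifest_names: list[str] = field(default_factory=list)
    latents: list[Latent] = field(default_factory=list)
    # entry dicts; rows index manifests, cols index latents
    lam: dict[tuple[int, int], Ref] = field(default_factory=dict)
    beta: dict[tuple[int, int], Ref] = field(default_factory=dict)
    psi: dict[tuple[int, int], Ref] = field(default_factory=dict)  # a <= b
    theta: dict[int, Ref] = field(default_factory=dict)
    nu: dict[int, Ref] = field(default_factory=dict)
    alpha: dict[int, Ref] = field(default_factory=dict)
    params: dict[str, Parameter] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    # ---------------------------------------------------------------- helpers
    @property
    def n_manifest(self) -> int:
        return len(self.manifest_names)

    @property
    def n_latent(self) -> int:
        return len(self.latents)

    @property
    def has_mean_structure(self) -> bool:
        """True when any mean-side entry (intercept or latent mean) exists."""
        return bool(self.nu) or bool(self.alpha)

    def latent_index(self, name: str) -> int:
        for k, lv in enumerate(self.latents):
            if lv.name == name:
                return k
        raise KeyError(f"unknown latent variable {name!r}")

    def latent_names(self) -> list[str]:
        return [lv.name for lv in self.latents]

    def manifest_index(self, name: str) -> int:
        try:
            return self.manifest_names.index(name)
        except ValueError:
            raise KeyError(f"unknown manifest variable {name!r}") from None

    def add_latent(self, latent: Latent) -> int:
        self.latents.append(latent)
        return len(self.latents) - 1

    def new_param(
        self, label: str, role: str, start: float = 0.0, indices: tuple = ()
    ) -> Ref:
        if label not in self.params:
            self.params[label] = Parameter(label, role, start, indices)
        return ("par", label)

    # ------------------------------------------------------------ constraints
    def _entry_dicts(self):
        return (self.lam, self.beta, self.psi, self.theta, self.nu, self.alpha)

    def referenced_labels(self) -> set[str]:
        out: set[str] = set()
        for d in self._entry_dicts():
            for ref in d.values():
                if _is_par(ref):
                    out.add(ref[1])
        return out

    def free_parameter_labels(self) -> list[str]:
        """Distinct referenced labels, in deterministic (creation) order."""
        referenced = self.referenced_labels()
        return [lab for lab in self.params if lab in referenced]

    @property
    def n_free(self) -> int:
        return len(self.free_parameter_labels())

    def fix(self, label: str, value: float) -> None:
        """Fix every entry carrying ``label`` to ``value``."""
        for d in self._entry_dicts():
            for key, ref in list(d.items()):
                if _is_par(ref) and ref[1] == label:
                    d[key] = ("fix", float(value))
        self.params.pop(label, None)

    def merge_labels(self, labels: list[str]) -> str | None:
        """Equality-constrain parameters by collapsing labels onto the first.

        Returns the canonical label, or None if fewer than two of the given
        labels exist as free parameters (nothing to merge).
        """
        present = [lab for lab in labels if lab in self.params]
        if len(present) < 2:
            return None
        canon = present[0]
        rest = set(present[1:])
        for d in self._entry_dicts():
            for key, ref in list(d.items()):
                if _is_par(ref) and ref[1] in rest:
                    d[key] = ("par", canon)
        for lab in rest:
            self.params.pop(lab, None)
        return canon

    def is_free_label(self, label: str) -> bool:
        return label in self.params

    # -------------------------------------------------------------- counting
    def degrees_of_freedom(self) -> int:
        """Modeled sample moments minus free parameters.

        Moments: p(p+1)/2 covariances, plus p means when the graph carries a
        mean structure. Raises :class:`UnderIdentifiedError` when negative.
        """
        p = self.n_manifest
        moments = p * (p + 1) // 2
        if self.has_mean_structure:
            moments += p
        df = moments - self.n_free
        if df < 0:
            raise UnderIdentifiedError(
                f"model has {self.n_free} free parameters but only "
                f"{moments} sample moments ({-df} in excess)"
            )
        return df

    # --------------------------------------------------------------- compile
    def compile(self) -> "CompiledModel":
        labels = self.free_parameter_labels()
        index = {lab: k for k, lab in enumerate(labels)}
        p, q = self.n_manifest, self.n_latent

        lam0 = np.zeros((p, q))
        beta0 = np.zeros((q, q))
        psi0 = np.zeros((q, q))
        theta0 = np.zeros(p)
        nu0 = np.zeros(p)
        alpha0 = np.zeros(q)

        fills: dict[str, list[tuple]] = {
            m: [] for m in ("lam", "beta", "psi", "theta", "nu", "alpha")
        }

        def handle(name, base, key, ref, symmetric=False):
            if ref[0] == "fix":
                if symmetric:
                    base[key] = ref[1]
                    base[key[::-1]] = ref[1]
                elif isinstance(key, tuple):
                    base[key] = ref[1]
                else:
                    base[key] = ref[1]
            else:
                fills[name].append((key, index[ref[1]]))

        for key, ref in self.lam.items():
            handle("lam", lam0, key, ref)
        for key, ref in self.beta.items():
            handle("beta", beta0, key, ref)
        for key, ref in self.psi.items():
            handle("psi", psi0, key, ref, symmetric=True)
        for key, ref in self.theta.items():
            handle("theta", theta0, key, ref)
        for key, ref in self.nu.items():
            handle("nu", nu0, key, ref)
        for key, ref in self.alpha.items():
            handle("alpha", alpha0, key, ref)

        starts = np.array([self.params[lab].start for lab in labels])
        roles = [self.params[lab].role for lab in labels]
        return CompiledModel(
            graph=self,
            labels=labels,
            roles=roles,
            starts=starts,
            lam0=lam0,
            beta0=beta0,
            psi0=psi0,
            theta0=theta0,
            nu0=nu0,
            alpha0=alpha0,
            fills=fills,
            meanstructure=self.has_mean_structure,
        )


@dataclass
class CompiledModel:
    """Frozen numeric view of a :class:`ParamGraph`.

    ``matrices(theta)`` fills the model matrices for a parameter vector in
    the order of ``labels``; ``moments(theta)`` returns the implied manifest
    covariance (and mean vector when a mean structure is present).
    """

    graph: ParamGraph
    labels: list[str]
    roles: list[str]
    starts: np.ndarray
    lam0: np.ndarray
    beta0: np.ndarray
    psi0: np.ndarray
    theta0: np.ndarray
    nu0: np.ndarray
    alpha0: np.ndarray
    fills: dict[str, list[tuple]]
    meanstructure: bool

    def __post_init__(self) -> None:
        # precompute fill index arrays for speed
        self._idx = {}
        for name, entries in self.fills.items():
            if not entries:
                self._idx[name] = None
                continue
            keys = [e[0] for e in entries]
            tidx = np.array([e[1] for e in entries], dtype=int)
            if isinstance(keys[0], tuple):
                rows = np.array([k[0] for k in keys], dtype=int)
                cols = np.array([k[1] for k in keys], dtype=int)
                self._idx[name] = (rows, cols, tidx)
            else:
                pos = np.array(keys, dtype=int)
                self._idx[name] = (pos, tidx)

    @property
    def n_free(self) -> int:
        return len(self.labels)

    def matrices(self, theta: np.ndarray):
        """Return (Lam, B, Psi, Theta_diag, nu, alpha) at ``theta``."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(
                f"theta has length {theta.size}, expected {self.n_free}"
            )
        lam = self.lam0.copy()
        beta = self.beta0.copy()
        psi = self.psi0.copy()
        thet = self.theta0.copy()
        nu = self.nu0.copy()
        alpha = self.alpha0.copy()
        if self._idx["lam"] is not None:
            r, c, t = self._idx["lam"]
            lam[r, c] = theta[t]
        if self._idx["beta"] is not None:
            r, c, t = self._idx["beta"]
            beta[r, c] = theta[t]
        if self._idx["psi"] is not None:
            r, c, t = self._idx["psi"]
            psi[r, c] = theta[t]
            psi[c, r] = theta[t]
        if self._idx["theta"] is not None:
            pos, t = self._idx["theta"]
            thet[pos] = theta[t]
        if self._idx["nu"] is not None:
            pos, t = self._idx["nu"]
            nu[pos] = theta[t]
        if self._idx["alpha"] is not None:
            pos, t = self._idx["alpha"]
            alpha[pos] = theta[t]
        return lam, beta, psi, thet, nu, alpha

    def reduced_form(self, theta: np.ndarray):
        """Return (Lam, G, Psi, Theta, nu, alpha) with G = (I - B)^{-1}."""
        lam, beta, psi, thet, nu, alpha = self.matrices(theta)
        q = beta.shape[0]
        eye = np.eye(q)
        try:
            g = np.linalg.solve(eye - beta, eye)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "latent regression structure is cyclic: (I - B) is singular"
            ) from exc
        return lam, g, psi, thet, nu, alpha

    def latent_moments(self, theta: np.ndarray):
        """Implied latent covariance Phi = G Psi G' and latent means G alpha."""
        lam, g, psi, thet, nu, alpha = self.reduced_form(theta)
        phi = g @ psi @ g.T
        mu_lat = g @ alpha
        return phi, mu_lat

    def moments(self, theta: np.ndarray):
        """Implied manifest covariance Sigma (and mean mu if modeled)."""
        lam, g, psi, thet, nu, alpha = self.reduced_form(theta)
        lg = lam @ g
        sigma = lg @ psi @ lg.T
        sigma[np.diag_indices_from(sigma)] += thet
        mu = nu + lg @ alpha if self.meanstructure else None
        return sigma, mu

    def start_vector(self) -> np.ndarray:
        return self.starts.copy()
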
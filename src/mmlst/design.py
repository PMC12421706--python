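"""Measurement designs for multimethod latent state-trait (MM-LST-RF) studies.

A design crosses I indicators x M methods x T occasions x S fixed situations,
yielding I*M*T*S manifest variables per subject. Columns of a wide dataset are
ordered with the fixed situation varying slowest, then occasion, then method,
then indicator -- i.e. the first block of columns is situation 1, within it the
first sub-block is occasion 1, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "DesignSpec",
    "ModelOptions",
    "Structural",
    "Equivalence",
    "InvarianceLevel",
    "make_design",
    "manifest_layout",
    "default_variable_name",
]

#: Upper bound on each design dimension (a sanity limit; real studies are
#: far smaller and the model grows quadratically in manifest variables).
MAX_DIMENSION = 25


class InvalidDesignError(ValueError):
    """Raised for impossible design dimensions."""


class OptionConflictError(ValueError):
    """Raised for mutually exclusive model options."""


class Structural(str, Enum):
    """Which latent change-score regressions to include."""

    MEASUREMENT_ONLY = "measurement_only"
    TRAIT_INTERACTIONS = "trait_interactions"
    TRAIT_METHOD_INTERACTIONS = "trait_method_interactions"
    BOTH = "both"


class Equivalence(str, Enum):
    """Within-factor equality assumptions on measurement parameters.

    Ordered from least to most restrictive: congeneric factors place only
    identification constraints; essential equivalence equates loadings (which
    the unit reference loading then fixes at one); equivalence additionally
    equates intercepts (fixing them at zero); essential parallelity equates
    loadings and error variances but leaves intercepts free; parallelity
    equates loadings, intercepts and error variances.
    """

    CONGENERIC = "congeneric"
    ESSENTIAL_EQUIVALENCE = "essential_equivalence"
    EQUIVALENCE = "equivalence"
    ESSENTIAL_PARALLELITY = "essential_parallelity"
    PARALLELITY = "parallelity"

    @property
    def equal_loadings(self) -> bool:
        return self is not Equivalence.CONGENERIC

    @property
    def equal_intercepts(self) -> bool:
        return self in (Equivalence.EQUIVALENCE, Equivalence.PARALLELITY)

    @property
    def equal_error_variances(self) -> bool:
        return self in (
            Equivalence.ESSENTIAL_PARALLELITY,
            Equivalence.PARALLELITY,
        )


class InvarianceLevel(str, Enum):
    """Measurement-invariance levels across a facet (methods or situations)."""

    CONFIGURAL = "configural"
    METRIC = "metric"
    SCALAR = "scalar"
    RESIDUAL = "residual"


INVARIANCE_ORDER = [
    InvarianceLevel.CONFIGURAL,
    InvarianceLevel.METRIC,
    InvarianceLevel.SCALAR,
    InvarianceLevel.RESIDUAL,
]


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of a multimethod multi-situation longitudinal study.

    Parameters
    ----------
    n_indicators, n_methods, n_occasions, n_situations
        Dimension counts I, M, T, S. The indicator count is per method and
        assumed equal across methods.
    indicator_names, method_names, occasion_names, situation_names
        Optional labels, purely cosmetic; model math uses 1-based indices.
    """

    n_indicators: int
    n_methods: int
    n_occasions: int
    n_situations: int
    indicator_names: tuple[str, ...] = ()
    method_names: tuple[str, ...] = ()
    occasion_names: tuple[str, ...] = ()
    situation_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        dims = {
            "n_indicators": self.n_indicators,
            "n_methods": self.n_methods,
            "n_occasions": self.n_occasions,
            "n_situations": self.n_situations,
        }
        for name, value in dims.items():
            if not isinstance(value, int) or value < 1:
                raise InvalidDesignError(
                    f"{name} must be a positive integer, got {value!r}"
                )
            if value > MAX_DIMENSION:
                raise InvalidDesignError(
                    f"{name}={value} exceeds the supported maximum of "
                    f"{MAX_DIMENSION}"
                )
        for attr, n in (
            ("indicator_names", self.n_indicators),
            ("method_names", self.n_methods),
            ("occasion_names", self.n_occasions),
            ("situation_names", self.n_situations),
        ):
            labels = getattr(self, attr)
            if labels and len(labels) != n:
                raise InvalidDesignError(
                    f"{attr} has {len(labels)} entries, expected {n}"
                )

    @property
    def n_manifest(self) -> int:
        """Total number of manifest variables I*M*T*S."""
        return (
            self.n_indicators
            * self.n_methods
            * self.n_occasions
            * self.n_situations
        )

    def variable_names(self) -> list[str]:
        """Default manifest names in column order (``S{s}T{t}M{m}I{i}``)."""
        return [default_variable_name(*idx) for idx in manifest_layout(self)]

    def supports_full_model(self) -> bool:
        """True when the full MM-LST-RF pathways (M>=2, S>=2) apply."""
        return self.n_methods >= 2 and self.n_situations >= 2


def default_variable_name(i: int, m: int, t: int, s: int) -> str:
    return f"S{s}T{t}M{m}I{i}"


def make_design(
    n_indicators: int,
    n_methods: int,
    n_occasions: int,
    n_situations: int,
    *,
    indicator_names: Sequence[str] = (),
    method_names: Sequence[str] = (),
    occasion_names: Sequence[str] = (),
    situation_names: Sequence[str] = (),
) -> DesignSpec:
    """Create a :class:`DesignSpec` from dimension counts.

    Reduced designs with ``n_methods == 1`` (LST-RF) or ``n_situations == 1``
    (MM-LST) are accepted; full MM-LST-RF use requires at least two
    indicators, methods, occasions and situations.
    """
    return DesignSpec(
        n_indicators=n_indicators,
        n_methods=n_methods,
        n_occasions=n_occasions,
        n_situations=n_situations,
        indicator_names=tuple(indicator_names),
        method_names=tuple(method_names),
        occasion_names=tuple(occasion_names),
        situation_names=tuple(situation_names),
    )


def manifest_layout(design: DesignSpec) -> list[tuple[int, int, int, int]]:
    """Ordered (i, m, t, s) tuples for each manifest column (1-based).

    The fixed situation varies slowest, then occasion, then method, with the
    indicator fastest, matching the wide-format column convention.
    """
    return [
        (i, m, t, s)
        for s in range(1, design.n_situations + 1)
        for t in range(1, design.n_occasions + 1)
        for m in range(1, design.n_methods + 1)
        for i in range(1, design.n_indicators + 1)
    ]


@dataclass
class ModelOptions:
    """Specification choices for an MM-LST-RF model.

    Defaults mirror the accompanying estimation tool: no structural
    regressions, all latent variables uncorrelated, occasion-method factors
    included, no mean structure, time invariance only, trait factors parallel
    and all other factor families essentially equivalent, listwise-complete
    maximum likelihood.
    """

    structural: Structural = Structural.MEASUREMENT_ONLY
    cov_trait: bool = False
    cov_trait_method: bool = False
    cov_occasion: bool = False
    cov_occasion_method: bool = False
    include_om_factors: bool = True
    mean_structure: bool = False
    invariance_facet: str | None = None  # "methods", "situations", "both"
    invariance_level: InvarianceLevel = InvarianceLevel.CONFIGURAL
    equivalence_trait: Equivalence = Equivalence.PARALLELITY
    equivalence_occasion: Equivalence = Equivalence.ESSENTIAL_EQUIVALENCE
    equivalence_om: Equivalence = Equivalence.ESSENTIAL_EQUIVALENCE
    extra_lines: list[str] = field(default_factory=list)
    missing: str = "listwise"  # or "fiml"

    def __post_init__(self) -> None:
        self.structural = Structural(self.structural)
        self.invariance_level = InvarianceLevel(self.invariance_level)
        self.equivalence_trait = Equivalence(self.equivalence_trait)
        self.equivalence_occasion = Equivalence(self.equivalence_occasion)
        self.equivalence_om = Equivalence(self.equivalence_om)
        if self.missing not in ("listwise", "fiml"):
            raise OptionConflictError(
                f"missing must be 'listwise' or 'fiml', got {self.missing!r}"
            )
        if self.invariance_facet not in (None, "methods", "situations", "both"):
            raise OptionConflictError(
                "invariance_facet must be one of None, 'methods', "
                f"'situations', 'both'; got {self.invariance_facet!r}"
            )
        trait_structural = self.structural in (
            Structural.TRAIT_INTERACTIONS,
            Structural.BOTH,
        )
        if trait_structural and self.cov_trait:
            raise OptionConflictError(
                "cov_trait is incompatible with trait interaction "
                "regressions: the latent change-score regression replaces "
                "the trait covariance"
            )
        tm_structural = self.structural in (
            Structural.TRAIT_METHOD_INTERACTIONS,
            Structural.BOTH,
        )
        if tm_structural and self.cov_trait_method:
            raise OptionConflictError(
                "cov_trait_method is incompatible with trait-method "
                "interaction regressions"
            )

    def copy(self) -> "ModelOptions":
        return ModelOptions(
            structural=self.structural,
            cov_trait=self.cov_trait,
            cov_trait_method=self.cov_trait_method,
            cov_occasion=self.cov_occasion,
            cov_occasion_method=self.cov_occasion_method,
            include_om_factors=self.include_om_factors,
            mean_structure=self.mean_structure,
            invariance_facet=self.invariance_facet,
            invariance_level=self.invariance_level,
            equivalence_trait=self.equivalence_trait,
            equivalence_occasion=self.equivalence_occasion,
            equivalence_om=self.equivalence_om,
            extra_lines=list(self.extra_lines),
            missing=self.missing,
        )
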
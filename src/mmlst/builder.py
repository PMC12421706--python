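"""Construction of MM-LST-RF parameter graphs.

The measurement model follows the reference-indicator convention: within each
fixed situation the indicator (i=1, m=1) defines the metric and origin of the
trait factor T_s and the occasion factors O_ts (unit loadings, zero
intercept). Every other manifest loads on the trait and occasion factor of
its cell with free loadings, on its trait-method factor TM_ims with a loading
fixed at one, and (optionally) on the occasion-method factor OM_mts of its
method-occasion cell. Loadings and intercepts carry no occasion index: scalar
invariance across occasions is built in.

Person-by-situation and method-by-situation interactions use the latent
change-score parametrization: the non-reference trait is the sum of the
reference trait and a latent difference variable, which is regressed on the
reference trait.
"""

from __future__ import annotations

import itertools

from .design import (
    DesignSpec,
    Equivalence,
    InvarianceLevel,
    ModelOptions,
    OptionConflictError,
    Structural,
    default_variable_name,
    manifest_layout,
)
from .graph import Latent, ParamGraph

__all__ = [
    "build_measurement_model",
    "build_model",
    "apply_equivalence",
    "apply_invariance",
    "add_trait_structural",
    "add_tm_structural",
    "add_covariance_sets",
    "add_custom_lines",
    "trait_name",
    "occasion_name",
    "tm_name",
    "om_name",
    "tdiff_name",
    "tmdiff_name",
]

# latent naming -------------------------------------------------------------


def trait_name(s: int) -> str:
    return f"T_S{s}"


def occasion_name(t: int, s: int) -> str:
    return f"O_T{t}S{s}"


def tm_name(i: int, m: int, s: int) -> str:
    return f"TM_I{i}M{m}S{s}"


def om_name(m: int, t: int, s: int) -> str:
    return f"OM_M{m}T{t}S{s}"


def tdiff_name(s: int) -> str:
    return f"TDIFF_S{s}"


def tmdiff_name(i: int, m: int, s: int) -> str:
    return f"TMDIFF_I{i}M{m}S{s}"


def _la(i, m, s):
    return f"la_I{i}M{m}S{s}"


def _de(i, m, s):
    return f"de_I{i}M{m}S{s}"


def _ga(i, m, s):
    return f"ga_I{i}M{m}S{s}"


def _al(i, m, s):
    return f"al_I{i}M{m}S{s}"


def _ve(i, m, t, s):
    return "ve_" + default_variable_name(i, m, t, s)


def _nonreference_cells(design: DesignSpec):
    """(i, m) pairs other than the reference indicator (1, 1)."""
    return [
        (i, m)
        for m in range(1, design.n_methods + 1)
        for i in range(1, design.n_indicators + 1)
        if (i, m) != (1, 1)
    ]


def _method_indicators(design: DesignSpec, m: int) -> list[int]:
    """Non-reference indicators measured by method ``m``."""
    if m == 1:
        return list(range(2, design.n_indicators + 1))
    return list(range(1, design.n_indicators + 1))


def _has_method_factors(design: DesignSpec) -> bool:
    # Reduced single-method designs are plain LST-RF models without
    # trait-method or occasion-method factors.
    return design.n_methods >= 2


# measurement model ---------------------------------------------------------


def build_measurement_model(
    design: DesignSpec, options: ModelOptions
) -> ParamGraph:
    """Build the base (configural, congeneric) MM-LST-RF measurement graph.

    Contains per situation: one trait factor, T occasion factors, I*M - 1
    trait-method factors and (when included) one occasion-method factor per
    method-occasion cell. Identification constraints are applied; equivalence
    and invariance constraints are added by the dedicated operations.
    """
    g = ParamGraph(design=design, options=options.copy())
    g.manifest_names = design.variable_names()
    S, T, M, I = (
        design.n_situations,
        design.n_occasions,
        design.n_methods,
        design.n_indicators,
    )
    method_factors = _has_method_factors(design)
    include_om = method_factors and options.include_om_factors

    for s in range(1, S + 1):
        k = g.add_latent(Latent(trait_name(s), "trait", (s,)))
        g.psi[(k, k)] = g.new_param(f"vT_S{s}", "variance", 1.0, (s,))
        if options.mean_structure:
            g.alpha[k] = g.new_param(f"mT_S{s}", "mean", 0.0, (s,))
    for s in range(1, S + 1):
        for t in range(1, T + 1):
            k = g.add_latent(Latent(occasion_name(t, s), "occasion", (t, s)))
            g.psi[(k, k)] = g.new_param(
                f"vO_T{t}S{s}", "variance", 0.3, (t, s)
            )
    if method_factors:
        for s in range(1, S + 1):
            for (i, m) in _nonreference_cells(design):
                k = g.add_latent(
                    Latent(tm_name(i, m, s), "trait_method", (i, m, s))
                )
                g.psi[(k, k)] = g.new_param(
                    f"vTM_I{i}M{m}S{s}", "variance", 0.5, (i, m, s)
                )
    if include_om:
        for s in range(1, S + 1):
            for t in range(1, T + 1):
                for m in range(1, M + 1):
                    if not _method_indicators(design, m):
                        continue
                    k = g.add_latent(
                        Latent(om_name(m, t, s), "occasion_method", (m, t, s))
                    )
                    g.psi[(k, k)] = g.new_param(
                        f"vOM_M{m}T{t}S{s}", "variance", 0.2, (m, t, s)
                    )

    layout = manifest_layout(design)
    for row, (i, m, t, s) in enumerate(layout):
        kt = g.latent_index(trait_name(s))
        ko = g.latent_index(occasion_name(t, s))
        is_reference = (i, m) == (1, 1)
        if is_reference:
            g.lam[(row, kt)] = ("fix", 1.0)
            g.lam[(row, ko)] = ("fix", 1.0)
            if options.mean_structure:
                g.nu[row] = ("fix", 0.0)
        else:
            g.lam[(row, kt)] = g.new_param(
                _la(i, m, s), "loading", 1.0, (i, m, s)
            )
            g.lam[(row, ko)] = g.new_param(
                _de(i, m, s), "loading", 1.0, (i, m, s)
            )
            if method_factors:
                g.lam[(row, g.latent_index(tm_name(i, m, s)))] = ("fix", 1.0)
            if include_om:
                kom = g.latent_index(om_name(m, t, s))
                anchor = _method_indicators(design, m)[0]
                if i == anchor:
                    g.lam[(row, kom)] = ("fix", 1.0)
                else:
                    g.lam[(row, kom)] = g.new_param(
                        _ga(i, m, s), "loading", 1.0, (i, m, s)
                    )
            if options.mean_structure:
                g.nu[row] = g.new_param(
                    _al(i, m, s), "intercept", 0.0, (i, m, s)
                )
        g.theta[row] = g.new_param(_ve(i, m, t, s), "variance", 0.5, (i, m, t, s))
    return g


# equivalence ---------------------------------------------------------------

_FAMILIES = ("trait", "occasion", "occasion_method")


def apply_equivalence(
    graph: ParamGraph, family: str, level: Equivalence
) -> ParamGraph:
    """Impose a within-factor equivalence level on one factor family.

    Equal loadings become fixed unit loadings (the reference loading is
    already one); the trait family's equal intercepts are fixed at zero;
    (essential) parallelity equates error variances among the indicators of
    each factor. Intercept-bearing levels requested for the residual families
    (occasion, occasion-method) reduce to their loading/error implications,
    with a log entry, because those factors have zero means.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown factor family {family!r}")
    level = Equivalence(level)
    design = graph.design
    S, T, M, I = (
        design.n_situations,
        design.n_occasions,
        design.n_methods,
        design.n_indicators,
    )
    cells = _nonreference_cells(design)

    if family == "trait":
        if level.equal_loadings:
            for s in range(1, S + 1):
                for (i, m) in cells:
                    if graph.is_free_label(_la(i, m, s)):
                        graph.fix(_la(i, m, s), 1.0)
        if level.equal_intercepts:
            for s in range(1, S + 1):
                for (i, m) in cells:
                    if graph.is_free_label(_al(i, m, s)):
                        graph.fix(_al(i, m, s), 0.0)
        if level.equal_error_variances:
            for s in range(1, S + 1):
                for t in range(1, T + 1):
                    graph.merge_labels(
                        [_ve(i, m, t, s) for m in range(1, M + 1)
                         for i in range(1, I + 1)]
                    )
    elif family == "occasion":
        if level.equal_intercepts:
            graph.log.append(
                "occasion factors are residuals with zero means; "
                f"{level.value} reduced to its loading/error implications"
            )
        if level.equal_loadings:
            for s in range(1, S + 1):
                for (i, m) in cells:
                    if graph.is_free_label(_de(i, m, s)):
                        graph.fix(_de(i, m, s), 1.0)
        if level.equal_error_variances:
            for s in range(1, S + 1):
                for t in range(1, T + 1):
                    graph.merge_labels(
                        [_ve(i, m, t, s) for m in range(1, M + 1)
                         for i in range(1, I + 1)]
                    )
    else:  # occasion_method
        if level.equal_intercepts:
            graph.log.append(
                "occasion-method factors are residuals with zero means; "
                f"{level.value} reduced to its loading/error implications"
            )
        if level.equal_loadings:
            for s in range(1, S + 1):
                for (i, m) in cells:
                    if graph.is_free_label(_ga(i, m, s)):
                        graph.fix(_ga(i, m, s), 1.0)
        if level.equal_error_variances:
            for s in range(1, S + 1):
                for t in range(1, T + 1):
                    for m in range(1, M + 1):
                        inds = _method_indicators(design, m)
                        graph.merge_labels([_ve(i, m, t, s) for i in inds])
    return graph


# measurement invariance ----------------------------------------------------


def apply_invariance(
    graph: ParamGraph, facet: str, level: InvarianceLevel
) -> ParamGraph:
    """Add cross-facet equality constraints at an invariance level.

    ``facet`` is "methods", "situations" or "both". Configural adds nothing;
    metric equates loadings across the facet, scalar additionally intercepts,
    residual additionally error variances. Trait means (and difference-score
    intercepts) remain free across situations so that latent comparisons stay
    possible. Groups containing a fixed member (e.g. the reference
    indicator's unit loading) are skipped and logged.
    """
    level = InvarianceLevel(level)
    if facet == "both":
        apply_invariance(graph, "methods", level)
        return apply_invariance(graph, "situations", level)
    if facet not in ("methods", "situations"):
        raise ValueError(f"unknown invariance facet {facet!r}")
    if level is InvarianceLevel.CONFIGURAL:
        return graph

    design = graph.design
    S, T, M, I = (
        design.n_situations,
        design.n_occasions,
        design.n_methods,
        design.n_indicators,
    )

    def groups_over_facet(label_fn, index_sets):
        """Label groups formed by varying the facet index."""
        out = []
        for fixed in index_sets:
            out.append([label_fn(*fixed, v) for v in _facet_values()])
        return out

    def _facet_values():
        return range(1, (M if facet == "methods" else S) + 1)

    def merge_groups(groups, what):
        for labels in groups:
            existing = [lab for lab in labels if lab in graph.params]
            fixed = [
                lab for lab in labels
                if lab not in graph.params and _label_is_entry(graph, lab)
            ]
            if fixed:
                graph.log.append(
                    f"invariance ({facet}, {level.value}): skipped {what} "
                    f"group {labels} (contains fixed parameters)"
                )
                continue
            if len(existing) >= 2:
                graph.merge_labels(existing)
        return None

    if facet == "situations":
        cells = _nonreference_cells(design)
        lam_groups = [[_la(i, m, s) for s in range(1, S + 1)] for i, m in cells]
        de_groups = [[_de(i, m, s) for s in range(1, S + 1)] for i, m in cells]
        ga_groups = [[_ga(i, m, s) for s in range(1, S + 1)] for i, m in cells]
        al_groups = [[_al(i, m, s) for s in range(1, S + 1)] for i, m in cells]
        ve_groups = [
            [_ve(i, m, t, s) for s in range(1, S + 1)]
            for m in range(1, M + 1)
            for i in range(1, I + 1)
            for t in range(1, T + 1)
        ]
    else:  # methods
        lam_groups = [
            [_la(i, m, s) for m in range(1, M + 1)]
            for s in range(1, S + 1)
            for i in range(1, I + 1)
        ]
        de_groups = [
            [_de(i, m, s) for m in range(1, M + 1)]
            for s in range(1, S + 1)
            for i in range(1, I + 1)
        ]
        ga_groups = [
            [_ga(i, m, s) for m in range(1, M + 1)]
            for s in range(1, S + 1)
            for i in range(1, I + 1)
        ]
        al_groups = [
            [_al(i, m, s) for m in range(1, M + 1)]
            for s in range(1, S + 1)
            for i in range(1, I + 1)
        ]
        ve_groups = [
            [_ve(i, m, t, s) for m in range(1, M + 1)]
            for s in range(1, S + 1)
            for t in range(1, T + 1)
            for i in range(1, I + 1)
        ]

    merge_groups(lam_groups, "loading")
    merge_groups(de_groups, "loading")
    merge_groups(ga_groups, "loading")
    if level in (InvarianceLevel.SCALAR, InvarianceLevel.RESIDUAL):
        merge_groups(al_groups, "intercept")
    if level is InvarianceLevel.RESIDUAL:
        merge_groups(ve_groups, "error variance")
    return graph


def _label_is_entry(graph: ParamGraph, label: str) -> bool:
    """True when ``label`` names a parameter that was fixed (not absent)."""
    # After fixing, the label disappears; we conservatively treat the
    # reference cells' conventional labels as fixed entries.
    for token in ("la_", "de_", "ga_", "al_"):
        if label.startswith(token):
            body = label[len(token):]
            if body.startswith("I1M1"):
                return True
    # identification gamma of each method's anchor indicator
    if label.startswith("ga_"):
        try:
            i = int(label.split("I")[1].split("M")[0])
            m = int(label.split("M")[1].split("S")[0])
        except (IndexError, ValueError):
            return False
        anchor = 2 if m == 1 else 1
        return i == anchor
    return False


# structural (latent change score) parts ------------------------------------


def add_trait_structural(graph: ParamGraph) -> ParamGraph:
    """Reparametrize non-reference traits as reference trait + difference.

    For each situation s != 1 the trait T_s becomes the sum T_1 + (T_s - T_1)
    and the latent difference is regressed on T_1 with slope b1_S{s} (and
    intercept b0_S{s} when a mean structure is present). The difference
    residual is uncorrelated with the reference trait.
    """
    design = graph.design
    if design.n_situations < 2:
        graph.log.append("trait structural requested with S=1: no-op")
        return graph
    for s in range(2, design.n_situations + 1):
        kt = graph.latent_index(trait_name(s))
        k1 = graph.latent_index(trait_name(1))
        kd = graph.add_latent(
            Latent(tdiff_name(s), "trait_difference", (s,))
        )
        graph.fix(f"vT_S{s}", 0.0)
        graph.psi[(kt, kt)] = ("fix", 0.0)
        graph.beta[(kt, k1)] = ("fix", 1.0)
        graph.beta[(kt, kd)] = ("fix", 1.0)
        graph.psi[(kd, kd)] = graph.new_param(
            f"vW_S{s}", "variance", 0.5, (s,)
        )
        graph.beta[(kd, k1)] = graph.new_param(
            f"b1_S{s}", "regression", 0.0, (s,)
        )
        if graph.options.mean_structure:
            if f"mT_S{s}" in graph.params:
                # the difference intercept replaces the situation trait mean
                graph.fix(f"mT_S{s}", 0.0)
                graph.alpha.pop(graph.latent_index(trait_name(s)), None)
            graph.alpha[kd] = graph.new_param(
                f"b0_S{s}", "mean", 0.0, (s,)
            )
    return graph


def add_tm_structural(graph: ParamGraph) -> ParamGraph:
    """Latent change-score structure for trait-method factors across
    situations: TM_ims = TM_im1 + (TM_ims - TM_im1), the difference regressed
    on TM_im1 with no intercept (trait-method factors are zero-mean
    residuals)."""
    design = graph.design
    if design.n_situations < 2:
        graph.log.append("trait-method structural requested with S=1: no-op")
        return graph
    if not _has_method_factors(design):
        graph.log.append(
            "trait-method structural requested without method factors: no-op"
        )
        return graph
    for s in range(2, design.n_situations + 1):
        for (i, m) in _nonreference_cells(design):
            kt = graph.latent_index(tm_name(i, m, s))
            k1 = graph.latent_index(tm_name(i, m, 1))
            kd = graph.add_latent(
                Latent(tmdiff_name(i, m, s), "tm_difference", (i, m, s))
            )
            graph.fix(f"vTM_I{i}M{m}S{s}", 0.0)
            graph.psi[(kt, kt)] = ("fix", 0.0)
            graph.beta[(kt, k1)] = ("fix", 1.0)
            graph.beta[(kt, kd)] = ("fix", 1.0)
            graph.psi[(kd, kd)] = graph.new_param(
                f"vWTM_I{i}M{m}S{s}", "variance", 0.3, (i, m, s)
            )
            graph.beta[(kd, k1)] = graph.new_param(
                f"b1TM_I{i}M{m}S{s}", "regression", 0.0, (i, m, s)
            )
    return graph


# covariance sets -----------------------------------------------------------


def _cov_label(a: str, b: str) -> str:
    return f"cv_{a}__{b}"


def _add_cov(graph: ParamGraph, name_a: str, name_b: str) -> None:
    ka, kb = graph.latent_index(name_a), graph.latent_index(name_b)
    if ka > kb:
        ka, kb = kb, ka
        name_a, name_b = name_b, name_a
    graph.psi[(ka, kb)] = graph.new_param(
        _cov_label(name_a, name_b), "covariance", 0.0
    )


def add_covariance_sets(graph: ParamGraph, options: ModelOptions) -> ParamGraph:
    """Add the optional latent covariance sets.

    Trait and trait-method factors covary with all factors of the same kind;
    occasion and occasion-method factors only with their same-occasion (and
    same-method) counterparts in other fixed situations. Occasion-method
    factors never covary within a situation.
    """
    design = graph.design
    S, T, M = design.n_situations, design.n_occasions, design.n_methods
    if options.cov_trait:
        names = [lv.name for lv in graph.latents if lv.kind == "trait"]
        for a, b in itertools.combinations(names, 2):
            _add_cov(graph, a, b)
    if options.cov_trait_method:
        names = [lv.name for lv in graph.latents if lv.kind == "trait_method"]
        if not names:
            graph.log.append("cov_trait_method requested without TM factors")
        for a, b in itertools.combinations(names, 2):
            _add_cov(graph, a, b)
    if options.cov_occasion:
        for t in range(1, T + 1):
            for sa, sb in itertools.combinations(range(1, S + 1), 2):
                _add_cov(graph, occasion_name(t, sa), occasion_name(t, sb))
        if S < 2:
            graph.log.append("cov_occasion requested with a single situation")
    if options.cov_occasion_method:
        om_names = {
            lv.indices: lv.name
            for lv in graph.latents
            if lv.kind == "occasion_method"
        }
        if not om_names:
            graph.log.append("cov_occasion_method requested without OM factors")
        for m in range(1, M + 1):
            for t in range(1, T + 1):
                for sa, sb in itertools.combinations(range(1, S + 1), 2):
                    a, b = om_names.get((m, t, sa)), om_names.get((m, t, sb))
                    if a and b:
                        _add_cov(graph, a, b)
    return graph


# custom syntax lines -------------------------------------------------------


def add_custom_lines(graph: ParamGraph, lines: list[str]) -> ParamGraph:
    """Apply user constraint lines (restricted lavaan-dialect grammar).

    Supported per line: covariances ``A ~~ B``, regressions ``A ~ B``,
    intercepts/means ``A ~ 1``, with optional numeric (fix) or label
    (equality) premultipliers. Manual entries override conflicting prior
    specifications; overrides are logged.
    """
    from .syntax import apply_custom_line  # local import to avoid cycle

    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        apply_custom_line(graph, line)
    return graph


# orchestration -------------------------------------------------------------


def build_model(design: DesignSpec, options: ModelOptions) -> ParamGraph:
    """Build the full symbolic model for a design and option set.

    Order: measurement model, equivalence assumptions, measurement
    invariance, structural change-score parts, covariance sets, custom lines
    (which override everything before them).
    """
    graph = build_measurement_model(design, options)
    apply_equivalence(graph, "trait", options.equivalence_trait)
    apply_equivalence(graph, "occasion", options.equivalence_occasion)
    if options.include_om_factors and _has_method_factors(design):
        apply_equivalence(graph, "occasion_method", options.equivalence_om)
    if options.invariance_facet:
        apply_invariance(graph, options.invariance_facet, options.invariance_level)
    if options.structural in (Structural.TRAIT_INTERACTIONS, Structural.BOTH):
        add_trait_structural(graph)
    if options.structural in (
        Structural.TRAIT_METHOD_INTERACTIONS,
        Structural.BOTH,
    ):
        add_tm_structural(graph)
    add_covariance_sets(graph, options)
    if options.extra_lines:
        add_custom_lines(graph, options.extra_lines)
    graph.degrees_of_freedom()  # raises if under-identified
    return graph
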
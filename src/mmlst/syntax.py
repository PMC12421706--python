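"""Model-description text in the lavaan operator dialect.

Export writes the full symbolic model with the operators ``=~`` (measured
by), ``~~`` ((co)variance), ``~`` (regression), ``~ 1`` (intercept/mean).
Fixed values appear as numeric premultipliers (``1*y``), free parameters as
label premultipliers (``la_I2M1S1*y``), so equality constraints are shared
labels and re-parsing the text recovers the free-parameter count.

The same restricted grammar backs user-supplied custom constraint lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .graph import ParamGraph

__all__ = [
    "export_model_syntax",
    "parse_model_syntax",
    "count_free_parameters",
    "apply_custom_line",
    "SyntaxParseError",
]


class SyntaxParseError(ValueError):
    """A model-syntax line could not be parsed or names an unknown variable."""


_LABEL_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


def _ref_text(ref) -> str:
    if ref[0] == "fix":
        v = ref[1]
        return f"{v:g}"
    return ref[1]


def export_model_syntax(graph: ParamGraph) -> str:
    """Serialize a :class:`ParamGraph` to model-description text."""
    lines: list[str] = []
    lnames = graph.latent_names()
    mnames = graph.manifest_names

    # measurement lines, one per latent with loadings
    for col, name in enumerate(lnames):
        terms = [
            f"{_ref_text(ref)}*{mnames[row]}"
            for (row, c), ref in sorted(graph.lam.items())
            if c == col
        ]
        if terms:
            lines.append(f"{name} =~ " + " + ".join(terms))
    # latent regressions, one line per dependent latent
    deps = sorted({r for (r, c) in graph.beta})
    for r in deps:
        terms = [
            f"{_ref_text(ref)}*{lnames[c]}"
            for (rr, c), ref in sorted(graph.beta.items())
            if rr == r
        ]
        lines.append(f"{lnames[r]} ~ " + " + ".join(terms))
    # latent variances and covariances
    for (a, b), ref in sorted(graph.psi.items()):
        lines.append(f"{lnames[a]} ~~ {_ref_text(ref)}*{lnames[b]}")
    # error variances
    for row, ref in sorted(graph.theta.items()):
        lines.append(f"{mnames[row]} ~~ {_ref_text(ref)}*{mnames[row]}")
    # mean structure
    for row, ref in sorted(graph.nu.items()):
        lines.append(f"{mnames[row]} ~ {_ref_text(ref)}*1")
    for col, ref in sorted(graph.alpha.items()):
        lines.append(f"{lnames[col]} ~ {_ref_text(ref)}*1")
    return "\n".join(lines) + "\n"


@dataclass
class Statement:
    """One parsed model-syntax line: ``lhs op term1 + term2 + ...``"""

    op: str  # "=~", "~~", "~", "~1"
    lhs: str
    terms: list[tuple[object, str]]  # (None | float | label, variable or "1")


def _parse_term(tok: str) -> tuple[object, str]:
    tok = tok.strip()
    if "*" in tok:
        mult, name = tok.split("*", 1)
        mult, name = mult.strip(), name.strip()
        try:
            return float(mult), name
        except ValueError:
            if not _LABEL_RE.match(mult):
                raise SyntaxParseError(f"bad premultiplier {mult!r} in {tok!r}")
            return mult, name
    return None, tok


def parse_model_syntax(text: str) -> list[Statement]:
    """Parse model-description text into statements (no graph resolution)."""
    out: list[Statement] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        out.append(parse_line(line))
    return out


def parse_line(line: str) -> Statement:
    for op in ("=~", "~~", "~"):
        if op in line:
            lhs, rhs = line.split(op, 1)
            lhs = lhs.strip()
            if not lhs:
                raise SyntaxParseError(f"missing left-hand side: {line!r}")
            terms = [_parse_term(t) for t in rhs.split("+")]
            if op == "~" and len(terms) == 1 and terms[0][1] == "1":
                return Statement("~1", lhs, terms)
            if any(name == "1" for _, name in terms) and op != "~":
                raise SyntaxParseError(f"'1' only allowed with '~': {line!r}")
            return Statement(op, lhs, terms)
    raise SyntaxParseError(f"unsupported syntax line: {line!r}")


def count_free_parameters(text: str) -> int:
    """Free-parameter count implied by exported model text.

    Unlabeled terms are each one free parameter; label premultipliers are
    shared; numeric premultipliers are fixed.
    """
    labels: set[str] = set()
    anonymous = 0
    for stmt in parse_model_syntax(text):
        for mult, _name in stmt.terms:
            if mult is None:
                anonymous += 1
            elif isinstance(mult, str):
                labels.add(mult)
    return anonymous + len(labels)


# ------------------------------------------------------------- custom lines


def _resolve(graph: ParamGraph, name: str) -> tuple[str, int]:
    if name in graph.manifest_names:
        return "manifest", graph.manifest_index(name)
    for k, lv in enumerate(graph.latents):
        if lv.name == name:
            return "latent", k
    raise SyntaxParseError(
        f"unknown model variable {name!r} (neither a manifest nor a latent)"
    )


def _make_ref(graph: ParamGraph, mult, default_label: str, role: str):
    if isinstance(mult, float):
        return ("fix", mult)
    label = mult if isinstance(mult, str) else default_label
    return graph.new_param(label, role, 0.0)


def _log_override(graph: ParamGraph, where: str, key, line: str) -> None:
    graph.log.append(f"custom line overrides existing {where} entry {key}: {line}")


def apply_custom_line(graph: ParamGraph, line: str) -> None:
    """Apply one custom constraint line to the graph (overriding conflicts)."""
    stmt = parse_line(line)
    if stmt.op == "~1":
        kind, idx = _resolve(graph, stmt.lhs)
        mult = stmt.terms[0][0]
        target = graph.nu if kind == "manifest" else graph.alpha
        if idx in target:
            _log_override(graph, "mean", stmt.lhs, line)
        target[idx] = _make_ref(graph, mult, f"mn_{stmt.lhs}", "mean")
        return
    if stmt.op == "~~":
        kind_a, a = _resolve(graph, stmt.lhs)
        for mult, name in stmt.terms:
            kind_b, b = _resolve(graph, name)
            if kind_a == kind_b == "manifest":
                if a != b:
                    raise SyntaxParseError(
                        "residual covariances between manifest variables are "
                        f"not supported: {line!r}"
                    )
                if a in graph.theta:
                    _log_override(graph, "error variance", stmt.lhs, line)
                graph.theta[a] = _make_ref(
                    graph, mult, f"ve_{stmt.lhs}", "variance"
                )
                continue
            if "manifest" in (kind_a, kind_b):
                raise SyntaxParseError(
                    "covariances between a manifest and a latent variable are "
                    f"not supported: {line!r}"
                )
            ka, kb = min(a, b), max(a, b)
            if (ka, kb) in graph.psi:
                _log_override(graph, "latent (co)variance", (stmt.lhs, name), line)
            role = "variance" if ka == kb else "covariance"
            names = sorted([stmt.lhs, name]) if ka != kb else [stmt.lhs]
            default = (
                f"cv_{names[0]}__{names[1]}" if ka != kb else f"v_{stmt.lhs}"
            )
            graph.psi[(ka, kb)] = _make_ref(graph, mult, default, role)
        return
    if stmt.op == "~":
        kind_a, a = _resolve(graph, stmt.lhs)
        for mult, name in stmt.terms:
            if name == "1":
                target = graph.nu if kind_a == "manifest" else graph.alpha
                if a in target:
                    _log_override(graph, "mean", stmt.lhs, line)
                target[a] = _make_ref(graph, mult, f"mn_{stmt.lhs}", "mean")
                continue
            kind_b, b = _resolve(graph, name)
            if kind_b != "latent":
                raise SyntaxParseError(
                    f"regressions on manifest predictors are not supported: "
                    f"{line!r}"
                )
            if kind_a == "manifest":
                if (a, b) in graph.lam:
                    _log_override(graph, "loading", (stmt.lhs, name), line)
                graph.lam[(a, b)] = _make_ref(
                    graph, mult, f"lo_{stmt.lhs}__{name}", "loading"
                )
            else:
                if (a, b) in graph.beta:
                    _log_override(graph, "regression", (stmt.lhs, name), line)
                graph.beta[(a, b)] = _make_ref(
                    graph, mult, f"bt_{stmt.lhs}__{name}", "regression"
                )
        return
    if stmt.op == "=~":
        kind_a, a = _resolve(graph, stmt.lhs)
        if kind_a != "latent":
            raise SyntaxParseError(
                f"left of '=~' must be a latent variable: {line!r}"
            )
        for mult, name in stmt.terms:
            kind_b, b = _resolve(graph, name)
            if kind_b != "manifest":
                raise SyntaxParseError(
                    f"right of '=~' must name manifest variables: {line!r}"
                )
            if (b, a) in graph.lam:
                _log_override(graph, "loading", (name, stmt.lhs), line)
            graph.lam[(b, a)] = _make_ref(
                graph, mult, f"lo_{name}__{stmt.lhs}", "loading"
            )
        return
    raise SyntaxParseError(f"unsupported syntax line: {line!r}")
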
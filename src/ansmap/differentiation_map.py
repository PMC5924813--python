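"""Domain-level grading and rendering of the autonomic differentiation map.

Per-proxy test results are aggregated into one grade per (test group,
latent domain) cell:

* ``strongest`` (red): every member proxy of the domain is significant on
  both the density-equality (BA) and the trend (JT) test;
* ``medium_strong`` (dark pink): a strict majority of member proxies is
  significant on the BA test *and* a strict majority on the JT test;
* ``medium`` (light pink): a strict majority on exactly one of the two
  tests;
* ``none`` (white): not enough significant results.

A group's *differentiation profile* is the ordered list of its non-white
domains.  The significance diagram is the companion per-proxy view: a BA
flag, a JT direction arrow, and a shade for the joint p-value magnitude.

Rendering is deterministic text SVG (byte-identical for identical input
and style); PNG output goes through matplotlib.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .factor_domains import Domain, DomainStructure
from .nonparam_tests import TestResult

__all__ = [
    "MapGrade",
    "DifferentiationMap",
    "SignificanceDiagram",
    "grade_domain",
    "build_map",
    "build_diagram",
    "render_map",
    "render_diagram",
]

GRADE_COLORS = {
    "strongest": "red",
    "medium_strong": "dark_pink",
    "medium": "light_pink",
    "none": "white",
}
_SVG_FILL = {
    "red": "#d62728",
    "dark_pink": "#e377a2",
    "light_pink": "#f7c5d9",
    "white": "#ffffff",
}
_SHADE_FILL = {"strong": "#f2c200", "medium": "#f7dd66", "weak": "#fdf3c0", "none": "#ffffff"}


@dataclass(frozen=True)
class MapGrade:
    """Grade of one (group, domain) cell; level and color are in bijection."""

    level: Literal["strongest", "medium_strong", "medium", "none"]
    n_proxies: int
    n_ba: int
    n_jt: int
    n_joint: int

    @property
    def color(self) -> str:
        return GRADE_COLORS[self.level]


@dataclass
class DifferentiationMap:
    """Grid of MapGrades indexed by (test group, retained domain)."""

    grades: dict[tuple[str, str], MapGrade]
    groups: list[str]
    domains: list[str]
    majority_rule: str = "marginal"  # BA and JT majorities counted per test

    def profile(self, group: str) -> list[str]:
        """The group's differentiation profile: its non-white domains."""
        return [d for d in self.domains if self.grades[(group, d)].level != "none"]

    def to_dict(self) -> dict:
        return {
            "majority_rule": self.majority_rule,
            "domains": self.domains,
            "profiles": {g: self.profile(g) for g in self.groups},
            "grades": {
                f"{g}|{d}": {
                    "level": gr.level,
                    "color": gr.color,
                    "n_proxies": gr.n_proxies,
                    "n_ba": gr.n_ba,
                    "n_jt": gr.n_jt,
                    "n_joint": gr.n_joint,
                }
                for (g, d), gr in self.grades.items()
            },
        }


@dataclass
class SignificanceDiagram:
    """Per-(group, proxy) summaries of the BA/JT battery."""

    results: dict[tuple[str, str], TestResult]
    groups: list[str]
    proxies: list[str]


def grade_domain(domain: Domain, results: dict[str, TestResult],
                 alpha: float = 0.05,
                 counting: Literal["marginal", "joint"] = "marginal") -> MapGrade:
    """Grade one domain for one test group from its members' test results.

    ``results`` maps proxy name to the proxy's TestResult for this group;
    every member proxy must be present.  Majorities are strict (more than
    half the member proxies).  With the default ``marginal`` counting the
    BA and JT majorities are assessed separately per test; with ``joint``
    counting the majorities are assessed on the jointly significant
    (discriminant) proxies instead — the stricter reading of the grading
    rule (medium then means at least one discriminant proxy short of a
    majority).
    """
    missing = [p for p in domain.proxies if p not in results]
    if missing:
        raise KeyError(f"missing test results for domain member proxies: {missing}")
    n = len(domain.proxies)
    if n == 0:
        raise ValueError("cannot grade an empty domain")
    n_ba = sum(results[p].ba_p < alpha for p in domain.proxies)
    n_jt = sum(
        min(results[p].jt_p_increasing, results[p].jt_p_decreasing) < alpha
        for p in domain.proxies
    )
    n_joint = sum(results[p].discriminant for p in domain.proxies)
    half = n / 2.0
    if counting == "joint":
        if n_joint == n:
            level = "strongest"
        elif n_joint > half:
            level = "medium_strong"
        elif n_joint > 0:
            level = "medium"
        else:
            level = "none"
    else:
        if n_joint == n:
            level = "strongest"
        elif n_ba > half and n_jt > half:
            level = "medium_strong"
        elif (n_ba > half) != (n_jt > half):
            level = "medium"
        else:
            level = "none"
    return MapGrade(level=level, n_proxies=n, n_ba=n_ba, n_jt=n_jt, n_joint=n_joint)


def build_map(domains: DomainStructure, all_results: list[TestResult],
              alpha: float = 0.05,
              counting: Literal["marginal", "joint"] = "marginal") -> DifferentiationMap:
    """One MapGrade per (test group, retained domain).

    Excluded proxies never contribute.  Raises if any (group, member proxy)
    pair lacks a test result.
    """
    groups = sorted({r.group for r in all_results})
    if not groups:
        raise ValueError("no test results supplied")
    by_group: dict[str, dict[str, TestResult]] = {g: {} for g in groups}
    for r in all_results:
        by_group[r.group][r.proxy] = r
    grades = {}
    for g in groups:
        for dom in domains.domains:
            grades[(g, dom.name)] = grade_domain(dom, by_group[g], alpha=alpha,
                                                 counting=counting)
    return DifferentiationMap(
        grades=grades, groups=groups, domains=[d.name for d in domains.domains],
        majority_rule=counting,
    )


def build_diagram(all_results: list[TestResult]) -> SignificanceDiagram:
    groups = sorted({r.group for r in all_results})
    proxies = []
    for r in all_results:
        if r.proxy not in proxies:
            proxies.append(r.proxy)
    return SignificanceDiagram(
        results={(r.group, r.proxy): r for r in all_results},
        groups=groups,
        proxies=proxies,
    )


def _svg_header(width: int, height: int) -> list[str]:
    return [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}" font-family="Helvetica, sans-serif">',
    ]


def _cell(x, y, w, h, fill, stroke="#888888") -> str:
    return (f'<rect x="{x}" y="{y}" width="{w}" height="{h}" '
            f'fill="{fill}" stroke="{stroke}"/>')


def _text(x, y, s, size=12, anchor="middle", style="") -> str:
    return (f'<text x="{x}" y="{y}" font-size="{size}" text-anchor="{anchor}"{style}>'
            f"{s}</text>")


def render_map(dmap: DifferentiationMap, path: str, cell_w: int = 110,
               cell_h: int = 36) -> None:
    """Write the differentiation map as a deterministic SVG (or PNG).

    Rows are test groups, columns the retained domains; fill encodes the
    grade.  SVG output is byte-identical for identical input; ``.png``
    paths are rendered through matplotlib instead.
    """
    if str(path).lower().endswith(".png"):
        _render_map_png(dmap, path, cell_w, cell_h)
        return
    left, top = 130, 40
    width = left + cell_w * len(dmap.domains) + 20
    height = top + cell_h * (len(dmap.groups) + 2) + 40
    out = _svg_header(width, height)
    for j, d in enumerate(dmap.domains):
        out.append(_text(left + j * cell_w + cell_w / 2, top - 10, d, size=13))
    for i, g in enumerate(dmap.groups):
        y = top + i * cell_h
        out.append(_text(left - 8, y + cell_h / 2 + 4, g, anchor="end"))
        for j, d in enumerate(dmap.domains):
            grade = dmap.grades[(g, d)]
            out.append(_cell(left + j * cell_w, y, cell_w, cell_h,
                             _SVG_FILL[grade.color]))
    ly = top + cell_h * len(dmap.groups) + 24
    out.append(_text(left, ly, "strongest / medium-strong / medium / none:",
                     anchor="start", size=11))
    for k, level in enumerate(("strongest", "medium_strong", "medium", "none")):
        out.append(_cell(left + 260 + k * 30, ly - 12, 24, 14,
                         _SVG_FILL[GRADE_COLORS[level]]))
    out.append("</svg>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


def render_diagram(diagram: SignificanceDiagram, path: str, cell_w: int = 52,
                   cell_h: int = 26) -> None:
    """Write the significance diagram as a deterministic SVG (or PNG).

    Each (group, proxy) cell shows the BA flag (a ≠ sign), the JT direction
    arrow (▲ higher / ▽ lower than the reference) and a background shade
    for the joint-significance magnitude; blank means not significant.
    """
    if str(path).lower().endswith(".png"):
        _render_diagram_png(diagram, path, cell_w, cell_h)
        return
    left, top = 110, 60
    width = left + cell_w * len(diagram.groups) * 2 + 20
    height = top + cell_h * len(diagram.proxies) + 30
    out = _svg_header(width, height)
    for gi, g in enumerate(diagram.groups):
        x = left + gi * 2 * cell_w
        out.append(_text(x + cell_w, top - 34, g, size=11))
        out.append(_text(x + cell_w / 2, top - 10, "BA", size=10))
        out.append(_text(x + 3 * cell_w / 2, top - 10, "JT", size=10))
    for pi, proxy in enumerate(diagram.proxies):
        y = top + pi * cell_h
        out.append(_text(left - 8, y + cell_h / 2 + 4, proxy, size=11, anchor="end"))
        for gi, g in enumerate(diagram.groups):
            r = diagram.results.get((g, proxy))
            x = left + gi * 2 * cell_w
            fill = _SHADE_FILL[r.shade] if r is not None else "#ffffff"
            out.append(_cell(x, y, cell_w, cell_h, fill))
            out.append(_cell(x + cell_w, y, cell_w, cell_h, fill))
            if r is None:
                continue
            if r.ba_p < 0.05:
                out.append(_text(x + cell_w / 2, y + cell_h / 2 + 5, "&#8800;", size=14))
            if r.direction == "higher":
                out.append(_text(x + 3 * cell_w / 2, y + cell_h / 2 + 5, "&#9650;", size=12))
            elif r.direction == "lower":
                out.append(_text(x + 3 * cell_w / 2, y + cell_h / 2 + 5, "&#9661;", size=12))
    out.append(_text(left, height - 8,
                     "shade: joint p &#8804; 0.001 / 0.01 / 0.05; blank = not significant",
                     size=10, anchor="start"))
    out.append("</svg>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


def _render_map_png(dmap, path, cell_w, cell_h):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.4 + 1.3 * len(dmap.domains),
                                    0.8 + 0.4 * len(dmap.groups)))
    for i, g in enumerate(dmap.groups):
        for j, d in enumerate(dmap.domains):
            color = _SVG_FILL[dmap.grades[(g, d)].color]
            ax.add_patch(plt.Rectangle((j, len(dmap.groups) - 1 - i), 1, 1,
                                       facecolor=color, edgecolor="gray"))
    ax.set_xticks([j + 0.5 for j in range(len(dmap.domains))], dmap.domains)
    ax.set_yticks([len(dmap.groups) - 0.5 - i for i in range(len(dmap.groups))],
                  dmap.groups)
    ax.set_xlim(0, len(dmap.domains))
    ax.set_ylim(0, len(dmap.groups))
    ax.set_title("ANS differentiation map")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _render_diagram_png(diagram, path, cell_w, cell_h):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ng, np_ = len(diagram.groups), len(diagram.proxies)
    fig, ax = plt.subplots(figsize=(1.5 + 0.9 * ng, 1.0 + 0.28 * np_))
    for pi, proxy in enumerate(diagram.proxies):
        for gi, g in enumerate(diagram.groups):
            r = diagram.results.get((g, proxy))
            fill = _SHADE_FILL[r.shade] if r is not None else "#ffffff"
            ax.add_patch(plt.Rectangle((gi, np_ - 1 - pi), 1, 1,
                                       facecolor=fill, edgecolor="gray"))
            if r is None:
                continue
            marks = ("≠" if r.ba_p < 0.05 else "") + (
                "▲" if r.direction == "higher" else "▽" if r.direction == "lower" else "")
            if marks:
                ax.text(gi + 0.5, np_ - 0.5 - pi, marks, ha="center", va="center")
    ax.set_xticks([i + 0.5 for i in range(ng)], diagram.groups, rotation=45)
    ax.set_yticks([np_ - 0.5 - i for i in range(np_)], diagram.proxies)
    ax.set_xlim(0, ng)
    ax.set_ylim(0, np_)
    ax.set_title("Significance diagram")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
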
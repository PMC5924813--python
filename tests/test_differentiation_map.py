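"""Domain grading, map construction, and deterministic rendering."""

import numpy as np
import pandas as pd
import pytest

from ansmap.differentiation_map import (
    build_diagram,
    build_map,
    grade_domain,
    render_diagram,
    render_map,
)
from ansmap.factor_domains import Domain, DomainStructure, LoadingMatrix, retain_and_assign
from ansmap.nonparam_tests import joint_rule
from ansmap.synthetic_cohort import DEFAULT_LOADINGS


def result(proxy, group="G", ba=0.5, jt=0.5):
    """Build a TestResult through the joint rule from raw p-values."""
    return joint_rule(ba, jt_p_inc=0.99, jt_p_dec=jt, proxy=proxy, group=group)


def make_results(proxies, ba_sig, jt_sig, group="G"):
    out = {}
    for i, p in enumerate(proxies):
        out[p] = result(p, group,
                        ba=0.01 if i < ba_sig else 0.5,
                        jt=0.01 if i < jt_sig else 0.5)
    return out


DOMAIN4 = Domain("Oscillatory", {f"p{i}": 0.8 for i in range(4)}, 0.4)
PROXIES4 = [f"p{i}" for i in range(4)]


class TestGradeDomain:
    @pytest.mark.parametrize("ba,jt,level", [
        (4, 4, "strongest"),
        (3, 3, "medium_strong"),
        (3, 2, "medium"),      # BA majority only
        (2, 3, "medium"),      # JT majority only
        (2, 2, "none"),        # exactly half is not a strict majority
        (0, 0, "none"),
    ])
    def test_majority_rules(self, ba, jt, level):
        res = make_results(PROXIES4, ba, jt)
        grade = grade_domain(DOMAIN4, res)
        assert grade.level == level
        assert grade.color == {"strongest": "red", "medium_strong": "dark_pink",
                               "medium": "light_pink", "none": "white"}[level]

    def test_strongest_needs_joint_significance(self):
        # all 4 significant on BA and on JT but on different proxies -> not all joint
        res = {
            "p0": result("p0", ba=0.01, jt=0.01),
            "p1": result("p1", ba=0.01, jt=0.01),
            "p2": result("p2", ba=0.01, jt=0.5),
            "p3": result("p3", ba=0.5, jt=0.01),
        }
        grade = grade_domain(DOMAIN4, res)
        assert grade.n_ba == 3 and grade.n_jt == 3 and grade.n_joint == 2
        assert grade.level == "medium_strong"

    def test_two_proxy_domain_majority_is_both(self):
        dom = Domain("Pulse", {"HR": 0.9, "RR_Mean": -0.9}, 0.12)
        res = make_results(["HR", "RR_Mean"], 1, 1)
        assert grade_domain(dom, res).level == "none"  # 1/2 is not a majority
        res = make_results(["HR", "RR_Mean"], 2, 2)
        assert grade_domain(dom, res).level == "strongest"

    def test_counts_invariant(self):
        res = make_results(PROXIES4, 3, 2)
        g = grade_domain(DOMAIN4, res)
        assert 0 <= g.n_joint <= min(g.n_ba, g.n_jt) <= g.n_proxies

    def test_joint_counting_variant(self):
        """Under joint counting, grades follow the count of jointly
        significant proxies only."""
        res = {
            "p0": result("p0", ba=0.01, jt=0.01),
            "p1": result("p1", ba=0.01, jt=0.5),   # BA only
            "p2": result("p2", ba=0.5, jt=0.01),   # JT only
            "p3": result("p3", ba=0.5, jt=0.5),
        }
        assert grade_domain(DOMAIN4, res, counting="joint").level == "medium"
        assert grade_domain(DOMAIN4, res, counting="marginal").level == "none"
        res_all = make_results(PROXIES4, 4, 4)
        assert grade_domain(DOMAIN4, res_all, counting="joint").level == "strongest"

    def test_missing_result_raises(self):
        res = make_results(PROXIES4[:3], 3, 3)
        with pytest.raises(KeyError):
            grade_domain(DOMAIN4, res)

    def test_monotone_in_significance(self):
        """Flipping one proxy to significant never lowers the grade."""
        order = {"none": 0, "medium": 1, "medium_strong": 2, "strongest": 3}
        for ba in range(4):
            for jt in range(4):
                g0 = grade_domain(DOMAIN4, make_results(PROXIES4, ba, jt))
                g1 = grade_domain(DOMAIN4, make_results(PROXIES4, ba + 1, jt))
                g2 = grade_domain(DOMAIN4, make_results(PROXIES4, ba, jt + 1))
                assert order[g1.level] >= order[g0.level]
                assert order[g2.level] >= order[g0.level]


class TestBuildMap:
    @pytest.fixture
    def structure(self):
        lm = LoadingMatrix(DEFAULT_LOADINGS.to_numpy(), list(DEFAULT_LOADINGS.index))
        return retain_and_assign(lm, salience=0.5)

    def test_null_results_all_white(self, structure):
        results = [result(p, "G") for p in DEFAULT_LOADINGS.index]
        dmap = build_map(structure, results)
        assert all(g.level == "none" for g in dmap.grades.values())
        assert dmap.profile("G") == []

    def test_excluded_proxies_never_contribute(self, structure):
        """Significance in the excluded proxies leaves the map untouched."""
        base = [result(p, "G") for p in DEFAULT_LOADINGS.index]
        hot = [result(p, "G", ba=0.001, jt=0.001)
               if p in ("RR_HFHz", "RR_LFHz", "SAP_LFa") else result(p, "G")
               for p in DEFAULT_LOADINGS.index]
        m1, m2 = build_map(structure, base), build_map(structure, hot)
        assert {k: g.level for k, g in m1.grades.items()} == \
               {k: g.level for k, g in m2.grades.items()}

    def test_profile_lists_nonwhite_domains(self, structure):
        results = [
            result(p, "G", ba=0.001, jt=0.001)
            if p in ("SAP", "DAP", "SAP_Mean") else result(p, "G")
            for p in DEFAULT_LOADINGS.index
        ]
        dmap = build_map(structure, results)
        assert dmap.profile("G") == ["Pressure"]
        assert dmap.grades[("G", "Pressure")].level == "strongest"

    def test_missing_group_proxy_pair(self, structure):
        results = [result("SAP", "G", 0.01, 0.01)]
        with pytest.raises(KeyError):
            build_map(structure, results)


class TestRendering:
    @pytest.fixture
    def small_map(self):
        dom = DomainStructure(
            domains=[Domain("Pressure", {"SAP": 0.9, "DAP": 0.8, "SAP_Mean": 0.9}, 0.4)],
            excluded=[], salience=0.5)
        results = [result(p, "G", 0.001, 0.001) for p in ("SAP", "DAP", "SAP_Mean")]
        return build_map(dom, results), build_diagram(results)

    def test_svg_deterministic(self, small_map, tmp_path):
        dmap, diagram = small_map
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        render_map(dmap, p1)
        render_map(dmap, p2)
        assert p1.read_bytes() == p2.read_bytes()
        d1, d2 = tmp_path / "d1.svg", tmp_path / "d2.svg"
        render_diagram(diagram, d1)
        render_diagram(diagram, d2)
        assert d1.read_bytes() == d2.read_bytes()

    def test_empty_grid_renders(self, tmp_path):
        dom = DomainStructure(domains=[Domain("Pulse", {"HR": 0.9}, 0.2)],
                              excluded=[], salience=0.5)
        results = [result("HR", "G")]  # nothing significant
        dmap = build_map(dom, results)
        out = tmp_path / "blank.svg"
        render_map(dmap, out)
        content = out.read_text()
        assert content.count('fill="#ffffff"') >= 1

    def test_one_significant_cell_shaded(self, small_map, tmp_path):
        _, diagram = small_map
        out = tmp_path / "diag.svg"
        render_diagram(diagram, out)
        text = out.read_text()
        assert "#8800" in text  # the BA inequality glyph
        assert text.count(_strong_fill()) == 6  # 3 proxies x (BA + JT) cells

    def test_png_output(self, small_map, tmp_path):
        dmap, diagram = small_map
        render_map(dmap, str(tmp_path / "m.png"))
        render_diagram(diagram, str(tmp_path / "d.png"))
        assert (tmp_path / "m.png").stat().st_size > 0
        assert (tmp_path / "d.png").stat().st_size > 0


def _strong_fill():
    from ansmap.differentiation_map import _SHADE_FILL

    return f'fill="{_SHADE_FILL["strong"]}"'
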
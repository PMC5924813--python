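"""End-to-end orchestration: adjust -> test -> domains -> map.

A single configured, seeded run executes the whole analysis in order —
the preliminary age/gender adjustment, the per-proxy two-test battery
against the reference group, the latent-domain extraction, and the
differentiation-map grading — writing every stage artifact plus a run
manifest with content digests so reruns can be verified byte-for-byte
(images' metadata excluded; SVG output is itself deterministic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_adjust import DEFAULT_AGE_BINS, AgeClass, adjust_proxies
from .differentiation_map import build_diagram, build_map, render_diagram, render_map
from .errors import StageError
from .factor_domains import extract_domains
from .io import read_proxy_table, write_proxy_table
from .nonparam_tests import compare_groups
from .synthetic_cohort import CohortConfig, generate_cohort

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("ansmap")

DEFAULT_CONFIG = {
    "reference": "Normal",
    "alpha": 0.05,
    "n_perm": 1000,
    "seed": 0,
    "n_factors": 4,
    "salience": 0.5,
    "factor_input": "raw",   # factor analysis on original proxies; "adjusted" optional
    "age_bins": [[18, 34], [35, 50], [51, 75]],
    "out_dir": "ansmap_run",
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _age_bins(cfg) -> tuple[AgeClass, ...]:
    bins = cfg.get("age_bins")
    if not bins:
        return DEFAULT_AGE_BINS
    labels = ["young", "middle", "older"]
    return tuple(
        AgeClass(labels[i] if i < 3 else f"class{i}", lo, hi)
        for i, (lo, hi) in enumerate(bins)
    )


def run_pipeline(config: dict) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk).

    ``config`` extends :data:`DEFAULT_CONFIG` and must provide the input —
    either ``proxies_csv`` (a cohort proxy table) or ``synthetic: {...}``
    (keyword arguments for the synthetic cohort generator).  Artifacts:
    ``adjusted.csv``, ``results.json``, ``domains.json``, ``map.svg``,
    ``diagram.svg``, ``profiles.json``, ``manifest.json`` in ``out_dir``.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    reference = cfg["reference"]
    if not reference:
        raise StageError("config: no reference group label given")
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_times: dict[str, float] = {}

    def timed(stage):
        def deco(fn):
            def wrapped(*a, **k):
                t0 = time.time()
                try:
                    r = fn(*a, **k)
                except Exception as exc:
                    raise StageError(f"stage {stage!r} failed: {exc}") from exc
                stage_times[stage] = round(time.time() - t0, 3)
                log.info("stage %s done in %.2fs", stage, stage_times[stage])
                return r
            return wrapped
        return deco

    @timed("input")
    def load_input() -> pd.DataFrame:
        if "proxies_csv" in cfg:
            return read_proxy_table(cfg["proxies_csv"])
        if "synthetic" in cfg:
            syn = dict(cfg["synthetic"])
            syn.setdefault("seed", cfg["seed"])
            return generate_cohort(CohortConfig(**{k: v for k, v in syn.items()
                                                   if k != "seed"}), seed=syn["seed"])
        raise ValueError("config needs 'proxies_csv' or 'synthetic'")

    table = load_input()
    if reference not in set(table["group"]):
        raise StageError(f"config: reference group {reference!r} not present in the input")

    @timed("adjust")
    def stage_adjust():
        adj = adjust_proxies(table, age_bins=_age_bins(cfg))
        write_proxy_table(adj.table, out_dir / "adjusted.csv")
        (out_dir / "adjust_audit.json").write_text(
            json.dumps(adj.audit(), indent=2) + "\n")
        return adj

    adj = stage_adjust()

    @timed("test")
    def stage_test():
        results = compare_groups(
            adj.table, reference=reference, alpha=cfg["alpha"],
            n_perm=cfg["n_perm"], seed=cfg["seed"],
        )
        payload = [dataclasses.asdict(r) for r in results]
        (out_dir / "results.json").write_text(json.dumps(payload, indent=2) + "\n")
        return results

    results = stage_test()

    @timed("domains")
    def stage_domains():
        source = adj.table if cfg["factor_input"] == "adjusted" else table
        struct = extract_domains(source, n_factors=cfg["n_factors"],
                                 salience=cfg["salience"])
        (out_dir / "domains.json").write_text(
            json.dumps(struct.to_dict(), indent=2) + "\n")
        return struct

    struct = stage_domains()

    @timed("map")
    def stage_map():
        dmap = build_map(struct, results, alpha=cfg["alpha"])
        diagram = build_diagram(results)
        render_map(dmap, out_dir / "map.svg")
        render_diagram(diagram, out_dir / "diagram.svg")
        profiles = {g: dmap.profile(g) for g in dmap.groups}
        (out_dir / "profiles.json").write_text(
            json.dumps({"reference": reference, "profiles": profiles,
                        "map": dmap.to_dict()}, indent=2) + "\n")
        return dmap

    stage_map()

    artifacts = ["adjusted.csv", "results.json", "domains.json",
                 "map.svg", "diagram.svg", "profiles.json"]
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "seed": cfg["seed"],
        "stage_seconds": stage_times,
        "total_seconds": round(time.time() - t_start, 3),
        "digests": {name: _digest(out_dir / name) for name in artifacts},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
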